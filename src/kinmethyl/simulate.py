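"""Synthetic closed-colony pedigrees and mammalian-array-like methylomes.

The generator emulates the study system end to end: a closed, randomly bred
rodent colony with recorded pedigrees, and a conserved-CpG methylation array
profiled on a cohort of 96 animals (47 females, 49 males) aged 1.3-33 months.
CpG beta values are drawn from a Beta distribution around a logit-linear
mean,

    logit(mu_ij) = b0_j + s_j * Age_i + r_j * m_i * Relatedness_i + g_j * Male_i

with planted CpG classes (age "clock" CpGs, relatedness CpGs with a
configurable hypermethylation bias and male-sensitivity multiplier m_i, sex
CpGs, and nulls), X-chromosome depletion and one enriched chromosome for the
relatedness class, one dense 2-Mb cluster, and an age-dependent dispersion
drift that raises methylome entropy with age.  Ground-truth labels for every
planted CpG are returned so downstream discovery can be scored.

All randomness flows from a single integer seed; the same seed reproduces
the dataset bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .pedigree import Pedigree, build_pedigree, relatedness_scores

CHROMOSOMES = [str(c) for c in range(1, 24)] + ["X"]
CHROM_LENGTH_BP = 100_000_000  # uniform synthetic chromosome length


@dataclass
class SimConfig:
    """Parameters of the colony and methylome simulation.

    Effect sizes are on the logit scale; relatedness is on the percent
    relationship scale (offspring of full sibs = 50) unless
    ``relatedness_scale`` says otherwise.
    """

    # colony
    n_founders: int = 20
    n_generations: int = 6
    n_pairs_per_generation: int = 15
    litter_mean: float = 3.0          # litter size = 1 + Poisson(litter_mean)
    kin_mating_boost: float = 0.1     # probability a breeding pair is drawn as full sibs
    # cohort
    n_samples: int = 96
    n_female: int = 47
    n_male: int = 49
    age_range_months: tuple = (1.3, 33.0)
    relatedness_scale: str = "percent"
    # array
    n_cpgs: int = 5000
    n_clock_cpgs: int = 350
    n_relatedness_cpgs: int = 250
    n_sex_cpgs: int = 150
    n_cluster_cpgs: int = 40          # subset of the relatedness CpGs
    island_fraction: float = 0.163
    # planted effects (logit scale)
    age_slope_range: tuple = (0.02, 0.08)   # per month, random sign
    effect_size: float = 0.02               # per percent-relatedness unit
    hyper_fraction: float = 0.8             # P(relatedness effect is positive)
    male_multiplier: float = 2.0            # relatedness effects magnified in males
    sex_effect: float = 0.8                 # offset magnitude for sex CpGs
    clock_overlap_fraction: float = 0.5     # relatedness CpGs that also track age
    # noise
    beta_precision: float = 30.0
    drift_per_month: float = 0.02           # dispersion growth with age (entropy drift)
    missing_rate: float = 0.01              # MCAR mask emulating probe masking
    # genomic placement of relatedness CpGs
    x_depletion: float = 0.15
    enriched_chrom: str = "4"
    enrichment_factor: float = 2.5
    cluster_chrom: str = "7"
    cluster_window: tuple = (60_000_000, 62_000_000)
    seed: int = 0
    #: seed of the array itself (CpG placement, baselines, planted effects);
    #: kept separate from ``seed`` so different cohorts profiled on the
    #: "same" array share CpG biology, as real cohorts on one platform do
    array_seed: int = 777

    def __post_init__(self):
        if self.n_founders < 4:
            raise ValueError("n_founders must be >= 4")
        if self.n_female + self.n_male != self.n_samples:
            raise ValueError("n_female + n_male must equal n_samples")
        for frac in (self.hyper_fraction, self.missing_rate, self.island_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.n_relatedness_cpgs + self.n_clock_cpgs + self.n_sex_cpgs > self.n_cpgs:
            raise ValueError("planted CpG classes exceed n_cpgs")
        if self.n_cluster_cpgs > self.n_relatedness_cpgs:
            raise ValueError("n_cluster_cpgs must be <= n_relatedness_cpgs")

    def null(self) -> "SimConfig":
        """A copy describing the exchangeable global null: no
        relatedness-dependent CpGs and iid (age-independent) Beta noise.

        The age-drift dispersion is switched off because it makes errors
        heteroskedastic across samples; the homoskedastic LRT's extreme
        tail then inflates (a property of the test, not of the planted
        effects), which would confound a type-I calibration check.
        """
        return replace(
            self, n_relatedness_cpgs=0, n_cluster_cpgs=0, drift_per_month=0.0
        )


@dataclass
class MethylomeDataset:
    """Beta matrix (CpG x sample) plus CpG annotation, sample metadata, truth.

    ``beta`` rows are indexed by CpG id and columns by sample id; values lie
    in [0, 1] with NaN for masked probes.  ``annotation`` has columns
    chrom, pos_bp (1-based), island (0/1), gene.  ``metadata`` has columns
    sex ('F'/'M'), age_months, relatedness.  ``truth`` labels each CpG with
    its planted class and effect (empty for user-supplied data).
    """

    beta: pd.DataFrame
    annotation: pd.DataFrame
    metadata: pd.DataFrame
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        if list(self.beta.columns) != list(self.metadata.index):
            raise ValueError("beta columns and metadata rows disagree")
        if list(self.beta.index) != list(self.annotation.index):
            raise ValueError("beta rows and annotation rows disagree")

    @property
    def n_cpgs(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]


# ---------------------------------------------------------------------------
# colony


def simulate_colony(config: SimConfig):
    """Simulate a closed, randomly bred colony and sample a study cohort.

    Breeding pairs are formed at random from the two preceding generations
    (rotational pairing in a closed colony); a small fraction of pairs are
    full-sib matings, which keeps the cohort's parental-relatedness gradient
    wide, from unrelated-founder offspring (score 0) up to and beyond the
    full-sib level.  The cohort is sampled across all offspring generations
    with the configured sex composition; ages at sampling are uniform over
    the configured range, independent of pedigree depth.

    Returns ``(pedigree, metadata)`` where metadata has one row per cohort
    animal: sex, age_months, relatedness (parental score), generation.
    """
    rng = np.random.default_rng([config.seed, 0])
    records = []
    generations = []  # list of lists of (id, sex)
    litters = []      # list of lists of ids (full sibs), with generation tag

    founders = []
    for k in range(config.n_founders):
        sex = "M" if k % 2 == 0 else "F"
        ident = f"G0_{k:03d}"
        founders.append((ident, sex))
        records.append(
            {"id": ident, "sire": None, "dam": None, "sex": sex,
             "birth_index": len(records)}
        )
    generations.append(founders)

    for g in range(1, config.n_generations + 1):
        pool = list(generations[-1]) + (list(generations[-2]) if g >= 2 else [])
        males = [i for i, s in pool if s == "M"]
        females = [i for i, s in pool if s == "F"]
        if not males or not females:
            raise ValueError("breeding pool lacks one sex")
        recent_litters = [
            lit for gen_tag, lit in litters if gen_tag >= g - 2 and len(lit) >= 2
        ]
        offspring = []
        for p in range(config.n_pairs_per_generation):
            sire = dam = None
            if recent_litters and rng.random() < config.kin_mating_boost:
                lit = recent_litters[rng.integers(len(recent_litters))]
                lm = [i for i in lit if i in set(males)]
                lf = [i for i in lit if i in set(females)]
                if lm and lf:
                    sire = lm[rng.integers(len(lm))]
                    dam = lf[rng.integers(len(lf))]
            if sire is None or dam is None:
                sire = males[rng.integers(len(males))]
                dam = females[rng.integers(len(females))]
            litter_size = 1 + rng.poisson(config.litter_mean)
            lit_ids = []
            for c in range(litter_size):
                sex = "M" if rng.random() < 0.5 else "F"
                ident = f"G{g}_{p:02d}{c:02d}"
                offspring.append((ident, sex))
                lit_ids.append(ident)
                records.append(
                    {"id": ident, "sire": sire, "dam": dam, "sex": sex,
                     "birth_index": len(records)}
                )
            litters.append((g, lit_ids))
        generations.append(offspring)

    ped = build_pedigree(records)

    candidates = [(i, s) for gen in generations[1:] for i, s in gen]
    cand_m = [i for i, s in candidates if s == "M"]
    cand_f = [i for i, s in candidates if s == "F"]
    if len(cand_m) < config.n_male or len(cand_f) < config.n_female:
        raise ValueError(
            "colony too small for the requested cohort sex composition"
        )
    chosen_m = list(rng.choice(cand_m, size=config.n_male, replace=False))
    chosen_f = list(rng.choice(cand_f, size=config.n_female, replace=False))
    cohort = sorted(chosen_m + chosen_f)
    scores = relatedness_scores(ped, cohort, scale=config.relatedness_scale)
    lo, hi = config.age_range_months
    ages = np.round(rng.uniform(lo, hi, size=len(cohort)), 1)
    sex_of = dict(ped.table[["id", "sex"]].itertuples(index=False))
    meta = pd.DataFrame(
        {
            "sex": [sex_of[i] for i in cohort],
            "age_months": ages,
            "relatedness": scores.values,
            "generation": [int(i.split("_")[0][1:]) for i in cohort],
        },
        index=pd.Index(cohort, name="id"),
    )
    return ped, meta


# ---------------------------------------------------------------------------
# methylome


def simulate_methylome(metadata: pd.DataFrame, config: SimConfig) -> MethylomeDataset:
    """Generate a planted-effect beta matrix for a cohort.

    See the module docstring for the mean model.  The Beta-noise
    concentration for sample i is ``beta_precision / (1 + drift_per_month *
    age_i)``, so older animals have noisier (higher-entropy) methylomes.
    """
    if len(metadata) == 0:
        raise ValueError("cohort has zero samples")
    # CpG-level structure comes from the array seed; per-cohort measurement
    # noise and masking come from the cohort seed
    rng = np.random.default_rng([config.array_seed, 2])
    rng_noise = np.random.default_rng([config.seed, 1])
    m, n = config.n_cpgs, len(metadata)
    n_rel, n_clk, n_sex = (
        config.n_relatedness_cpgs, config.n_clock_cpgs, config.n_sex_cpgs,
    )

    cls = np.array(["null"] * m, dtype=object)
    cls[:n_clk] = "clock"
    cls[n_clk:n_clk + n_rel] = "relatedness"
    cls[n_clk + n_rel:n_clk + n_rel + n_sex] = "sex"
    is_cluster = np.zeros(m, dtype=bool)
    is_cluster[n_clk + n_rel - config.n_cluster_cpgs:n_clk + n_rel] = True

    # chromosome placement: uniform background; relatedness CpGs depleted on
    # X and enriched on one autosome; cluster CpGs packed into one 2-Mb window
    chrom = np.array(
        [CHROMOSOMES[k] for k in rng.integers(0, len(CHROMOSOMES), m)],
        dtype=object,
    )
    w = np.ones(len(CHROMOSOMES))
    w[CHROMOSOMES.index("X")] = config.x_depletion
    w[CHROMOSOMES.index(config.enriched_chrom)] = config.enrichment_factor
    w /= w.sum()
    rel_idx = np.where((cls == "relatedness") & ~is_cluster)[0]
    chrom[rel_idx] = [
        CHROMOSOMES[k] for k in rng.choice(len(CHROMOSOMES), len(rel_idx), p=w)
    ]
    pos = rng.integers(1, CHROM_LENGTH_BP, m)
    clu_idx = np.where(is_cluster)[0]
    chrom[clu_idx] = config.cluster_chrom
    pos[clu_idx] = rng.integers(
        config.cluster_window[0] + 1, config.cluster_window[1], len(clu_idx)
    )
    island = (rng.random(m) < config.island_fraction).astype(int)
    genes = np.array(
        [f"G{c}W{p // 2_000_000:02d}" for c, p in zip(chrom, pos)], dtype=object
    )

    baseline = np.clip(rng.normal(0.0, 1.2, m), -3.0, 3.0)
    age_slope = np.zeros(m)
    clk = cls == "clock"
    age_slope[clk] = rng.uniform(*config.age_slope_range, clk.sum()) * rng.choice(
        [-1.0, 1.0], clk.sum()
    )
    rel_all = np.where(cls == "relatedness")[0]
    rel_effect = np.zeros(m)
    sign = np.where(rng.random(len(rel_all)) < config.hyper_fraction, 1.0, -1.0)
    rel_effect[rel_all] = sign * config.effect_size * rng.uniform(
        0.7, 1.3, len(rel_all)
    )
    # a fraction of relatedness CpGs also track age, with the age slope
    # opposing the relatedness effect: relatedness pushes these CpGs toward
    # their "young" methylation state, so an age predictor trained on an
    # independent cohort reads related offspring as epigenetically younger
    n_overlap = int(round(config.clock_overlap_fraction * len(rel_all)))
    overlap = rel_all[:n_overlap]
    age_slope[overlap] = -np.sign(rel_effect[overlap]) * rng.uniform(
        *config.age_slope_range, n_overlap
    )
    sex_effect = np.zeros(m)
    sx = cls == "sex"
    sex_effect[sx] = config.sex_effect * rng.uniform(0.7, 1.3, sx.sum()) * rng.choice(
        [-1.0, 1.0], sx.sum()
    )

    age = metadata["age_months"].to_numpy(float)
    male = (metadata["sex"].to_numpy() == "M").astype(float)
    rel = metadata["relatedness"].to_numpy(float)
    rel = np.where(np.isnan(rel), 0.0, rel)
    rel_mult = 1.0 + (config.male_multiplier - 1.0) * male

    eta = (
        baseline[:, None]
        + age_slope[:, None] * (age[None, :] - age.mean())
        + rel_effect[:, None] * (rel[None, :] * rel_mult[None, :])
        + sex_effect[:, None] * male[None, :]
    )
    mu = expit(np.clip(eta, -6.0, 6.0))
    nu = config.beta_precision / (1.0 + config.drift_per_month * age)
    beta = rng_noise.beta(mu * nu[None, :], (1.0 - mu) * nu[None, :])
    if config.missing_rate > 0:
        beta[rng_noise.random(beta.shape) < config.missing_rate] = np.nan

    order = rng.permutation(m)
    cpg_ids = pd.Index([f"cg{k:06d}" for k in range(m)], name="cpg")
    dataset = MethylomeDataset(
        beta=pd.DataFrame(beta[order], index=cpg_ids, columns=metadata.index),
        annotation=pd.DataFrame(
            {"chrom": chrom[order], "pos_bp": pos[order],
             "island": island[order], "gene": genes[order]},
            index=cpg_ids,
        ),
        metadata=metadata.copy(),
        truth=pd.DataFrame(
            {
                "cls": cls[order],
                "planted_sign": np.sign(rel_effect[order]).astype(int),
                "rel_effect": rel_effect[order],
                "age_slope": age_slope[order],
                "is_cluster": is_cluster[order].astype(int),
            },
            index=cpg_ids,
        ),
    )
    return dataset


def simulate_dataset(config: SimConfig):
    """Colony + methylome in one call; returns (pedigree, dataset)."""
    ped, meta = simulate_colony(config)
    return ped, simulate_methylome(meta, config)


# ---------------------------------------------------------------------------
# focused planted scenarios (used for parameter-recovery checks)


def simulate_relatedness_values(n: int, rng) -> np.ndarray:
    """Parental relatedness scores resembling a closed colony (percent scale):
    a point mass at 0 (outbred matings) plus a right-skewed positive tail."""
    zero = rng.random(n) < 0.3
    values = rng.gamma(2.0, 8.0, n).clip(max=60.0)
    values[zero] = 0.0
    return values


def simulate_eaa_scenario(
    n: int = 96,
    slope: float = -0.0015,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Cohort with a planted linear relatedness -> EAA effect.

    Defaults mirror the magnitude regime of the study system: a slope of
    -0.0015 per percent-relatedness unit against residual noise chosen so
    the association is detectable but not overwhelming at n = 96.
    """
    rng = np.random.default_rng(seed)
    rel = simulate_relatedness_values(n, rng)
    age = rng.uniform(1.3, 33.0, n)
    sex = rng.permutation(np.array(["F"] * (n // 2) + ["M"] * (n - n // 2)))
    eaa = slope * (rel - rel.mean()) + rng.normal(0.0, noise_sd, n)
    return pd.DataFrame(
        {"age_months": age, "sex": sex, "relatedness": rel, "eaa": eaa},
        index=pd.Index([f"S{k:03d}" for k in range(n)], name="id"),
    )


def simulate_signature_scenario(
    n: int = 96,
    n_true: int = 5,
    n_noise: int = 300,
    noise_variance_fraction: float = 0.05,
    seed: int = 0,
):
    """Candidate CpG panel whose response is a sparse linear signal.

    ``n_true`` CpGs carry the signal; residual noise is calibrated to the
    requested fraction of the response variance, so an ideal sparse
    regression attains R^2 of about 1 - noise_variance_fraction.  Returns
    ``(beta_panel, response, true_cpg_ids)``.
    """
    rng = np.random.default_rng(seed)
    m = n_true + n_noise
    X = rng.beta(4.0, 4.0, (m, n))
    w = rng.uniform(40.0, 80.0, n_true) * rng.choice([-1.0, 1.0], n_true)
    signal = X[:n_true].T @ w
    noise_sd = np.sqrt(
        noise_variance_fraction / (1.0 - noise_variance_fraction)
    ) * signal.std()
    y = signal + rng.normal(0.0, noise_sd, n)
    cpgs = pd.Index([f"cg{k:05d}" for k in range(m)], name="cpg")
    samples = pd.Index([f"S{k:03d}" for k in range(n)], name="id")
    beta = pd.DataFrame(X, index=cpgs, columns=samples)
    return beta, pd.Series(y, index=samples), list(cpgs[:n_true])


def simulate_mediation_scenario(
    n: int = 96,
    a: float = -0.05,
    b: float = 0.02,
    direct: float = -0.001,
    mediator_noise_sd: float = 0.6,
    outcome_noise_sd: float = 0.03,
    seed: int = 0,
) -> pd.DataFrame:
    """Treatment/mediator/outcome triple with a planted indirect path.

    M = a*T + e1, Y = direct*T + b*M + e2 (age and sex included as inert
    covariates).  The planted ACME is a*b and the total effect direct + a*b;
    the defaults put half of the total effect through the mediator.
    """
    rng = np.random.default_rng(seed)
    rel = simulate_relatedness_values(n, rng)
    age = rng.uniform(1.3, 33.0, n)
    sex = rng.permutation(np.array(["F"] * (n // 2) + ["M"] * (n - n // 2)))
    mediator = a * rel + rng.normal(0.0, mediator_noise_sd, n)
    outcome = direct * rel + b * mediator + rng.normal(0.0, outcome_noise_sd, n)
    return pd.DataFrame(
        {
            "age_months": age,
            "sex": sex,
            "relatedness": rel,
            "mediator": mediator,
            "outcome": outcome,
        },
        index=pd.Index([f"S{k:03d}" for k in range(n)], name="id"),
    )


# ---------------------------------------------------------------------------
# dataset I/O (plain TSV directory)

_FILES = ("beta.tsv", "annotation.tsv", "metadata.tsv", "truth.tsv")


def write_dataset(dataset: MethylomeDataset, directory) -> None:
    """Write a dataset directory (beta/annotation/metadata/truth TSVs)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dataset.beta.to_csv(directory / "beta.tsv", sep="\t", float_format="%.8g")
    dataset.annotation.to_csv(directory / "annotation.tsv", sep="\t")
    dataset.metadata.to_csv(
        directory / "metadata.tsv", sep="\t", float_format="%.8g"
    )
    if len(dataset.truth):
        dataset.truth.to_csv(
            directory / "truth.tsv", sep="\t", float_format="%.8g"
        )


def read_dataset(directory) -> MethylomeDataset:
    """Read a dataset directory written by :func:`write_dataset`.

    Raises ``ValueError`` if the beta matrix and metadata disagree on the
    sample set.
    """
    directory = Path(directory)
    beta = pd.read_csv(directory / "beta.tsv", sep="\t", index_col=0)
    beta.index.name = "cpg"
    annotation = pd.read_csv(directory / "annotation.tsv", sep="\t", index_col=0)
    metadata = pd.read_csv(directory / "metadata.tsv", sep="\t", index_col=0)
    metadata.index = metadata.index.astype(str)
    beta.columns = beta.columns.astype(str)
    if set(beta.columns) != set(metadata.index):
        raise ValueError("sample ids in beta.tsv and metadata.tsv differ")
    metadata = metadata.loc[beta.columns]
    truth_path = directory / "truth.tsv"
    truth = (
        pd.read_csv(truth_path, sep="\t", index_col=0)
        if truth_path.exists()
        else pd.DataFrame()
    )
    return MethylomeDataset(beta, annotation, metadata, truth)


def config_to_json(config: SimConfig, path) -> None:
    Path(path).write_text(json.dumps(asdict(config), indent=2, default=list))


def config_from_json(path) -> SimConfig:
    raw = json.loads(Path(path).read_text())
    for key in ("age_range_months", "age_slope_range", "cluster_window"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return SimConfig(**raw)
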