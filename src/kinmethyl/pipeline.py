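"""End-to-end orchestration: simulate -> kinship -> EWAS -> clock/EAA ->
entropy -> PCA/mediation -> enrichment -> signature.

A single :class:`PipelineConfig` (YAML/JSON serializable) drives every
stage; all randomness is seeded, every output is a plain-text table or JSON
document written with fixed float formatting, and a run manifest records
stage parameters, seeds and SHA-256 hashes of every output file so reruns
can be checked for bit-identity.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clock import age_table, regress_eaa_on_relatedness, train_clock
from .entropy import dataset_entropy, entropy_associations
from .enrichment import (
    chromosome_enrichment, map_genes, window_enrichment, windows_to_bed,
)
from .ewas import direction_counts, island_fraction, run_ewas
from .mediation import mediate, mediation_sensitivity, sex_stratified_mediation
from .pca import pc_associations, run_pca
from .pedigree import cohort_relatedness_matrix, kinship_matrix, write_kinship
from .signature import build_signature
from .simulate import (
    MethylomeDataset, SimConfig, read_dataset, simulate_colony,
    simulate_methylome, write_dataset,
)

log = logging.getLogger("kinmethyl")

_FLOAT_FMT = "%.8g"


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run."""

    out_dir: str = "out"
    dataset_dir: str | None = None        # use an existing dataset instead of simulating
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0
    fdr_ewas: float = 0.1
    fdr_signature: float = 0.05
    window_bp: int = 2_000_000
    n_pca_components: int = 10
    mediators: tuple = ("PC1", "PC2")
    n_boot: int = 10_000
    stages: tuple = (
        "simulate", "kinship", "ewas", "clock", "entropy", "pca_mediation",
        "enrichment", "signature",
    )

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        Path(path).write_text(yaml.safe_dump(raw, default_flow_style=None))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "sim" in raw and isinstance(raw["sim"], dict):
            sim = dict(raw["sim"])
            for key in ("age_range_months", "age_slope_range", "cluster_window"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            raw["sim"] = SimConfig(**sim)
        for key in ("mediators", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def _write_json(obj, path: Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o).__name__)

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every enabled stage in dependency order; return the manifest.

    Reruns with an identical config write bit-identical outputs.  A stage
    failure aborts with the stage name; outputs written so far remain.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "config": json.loads(json.dumps(asdict(config), default=list)),
        "stages": {},
        "files": {},
    }
    stages = set(config.stages)

    def record(stage, started, **extra):
        manifest["stages"][stage] = {
            "elapsed_s": round(time.time() - started, 3), **extra,
        }

    ped = dataset = None
    ewas_tbl = None
    ages = None
    pca_res = None

    # --- simulate / load -------------------------------------------------
    stage = "simulate"
    started = time.time()
    try:
        if config.dataset_dir is not None:
            dataset = read_dataset(config.dataset_dir)
            manifest["inputs"] = {
                p.name: _sha256(p)
                for p in sorted(Path(config.dataset_dir).glob("*.tsv"))
            }
            record(stage, started, source=str(config.dataset_dir))
        else:
            if "simulate" not in stages:
                raise ValueError("no dataset_dir and simulate stage disabled")
            sim = config.sim
            ped, meta = simulate_colony(sim)
            dataset = simulate_methylome(meta, sim)
            ddir = out / "simdata"
            write_dataset(dataset, ddir)
            ped.table.to_csv(ddir / "pedigree.tsv", sep="\t", index=False)
            record(stage, started, n_cpgs=dataset.n_cpgs,
                   n_samples=dataset.n_samples)
        log.info("dataset: %d CpGs x %d samples", dataset.n_cpgs,
                 dataset.n_samples)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # --- kinship ----------------------------------------------------------
    if "kinship" in stages and ped is not None:
        stage, started = "kinship", time.time()
        try:
            kdir = out / "kinship"
            kdir.mkdir(exist_ok=True)
            kin = kinship_matrix(ped)
            write_kinship(kin, kdir / "phi.tsv")
            matrix, summary = cohort_relatedness_matrix(
                ped, list(dataset.metadata.index), seed=config.seed,
            )
            _write_tsv(matrix, kdir / "cohort_phi_ordered.tsv")
            _write_json(summary, kdir / "cohort_clustering.json")
            record(stage, started, **summary)
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    # --- ewas -------------------------------------------------------------
    if "ewas" in stages:
        stage, started = "ewas", time.time()
        try:
            ewas_tbl = run_ewas(dataset)
            _write_tsv(ewas_tbl, out / "ewas.tsv")
            sex_tables = {}
            for sex in ("F", "M"):
                try:
                    sex_tables[sex] = run_ewas(dataset, sex_subset=sex)
                    _write_tsv(sex_tables[sex], out / f"ewas_{sex}.tsv")
                except ValueError:
                    pass
            counts = direction_counts(
                ewas_tbl, q_thresh=config.fdr_ewas, sex_tables=sex_tables
            )
            islands = island_fraction(
                ewas_tbl, dataset.annotation, q_thresh=config.fdr_ewas
            )
            _write_json(
                {"direction_counts": counts, "island_fraction": islands},
                out / "ewas_summary.json",
            )
            record(stage, started, n_significant=int(
                (ewas_tbl["q"] < config.fdr_ewas).sum()
            ))
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    # --- clock / EAA -------------------------------------------------------
    if "clock" in stages:
        stage, started = "clock", time.time()
        try:
            if config.dataset_dir is None:
                # train the clock on an independently simulated reference
                # cohort (same generator, different colony), mirroring the
                # real workflow where the age predictor comes from other
                # animals; relatedness-driven shifts in the study cohort can
                # then genuinely bias its predictions
                from dataclasses import replace as _replace

                ref_cfg = _replace(config.sim, seed=config.sim.seed + 10_007)
                _, ref_meta = simulate_colony(ref_cfg)
                ref_ds = simulate_methylome(ref_meta, ref_cfg)
                clock = train_clock(ref_ds, seed=config.seed)
            else:
                clock = train_clock(dataset, seed=config.seed)
            ages = age_table(dataset, clock=clock)
            _write_tsv(ages, out / "ages.tsv")
            meta = dataset.metadata
            usable = meta.index[~meta["relatedness"].isna()]
            report = regress_eaa_on_relatedness(
                ages.loc[usable, "eaa"],
                meta.loc[usable, "relatedness"],
                age=meta.loc[usable, "age_months"],
                sex=meta.loc[usable, "sex"],
            )
            payload = report.to_dict()
            from .clock import lifespan_relatedness_correlation

            lifespan = lifespan_relatedness_correlation(meta)
            if lifespan is not None:
                payload["lifespan_relatedness"] = lifespan
            payload["clock"] = {
                "oof_pearson_r": clock.cv_summary["oof_pearson_r"],
                "n_nonzero": clock.cv_summary["n_nonzero"],
                "alpha": clock.alpha,
            }
            _write_json(payload, out / "eaa_report.json")
            record(stage, started, beta_ols=report.beta_ols,
                   oof_r=clock.cv_summary["oof_pearson_r"])
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    # --- entropy ------------------------------------------------------------
    if "entropy" in stages:
        stage, started = "entropy", time.time()
        try:
            ent = dataset_entropy(dataset)
            _write_tsv(ent, out / "entropy.tsv")
            meta = dataset.metadata
            assoc = entropy_associations(
                ent["entropy"],
                meta["age_months"],
                relatedness=meta["relatedness"].fillna(0.0),
                eaa=None if ages is None else ages["eaa"],
                sex=meta["sex"],
            )
            _write_json(assoc, out / "entropy_associations.json")
            record(stage, started, age_r2=assoc["age_r2"])
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    # --- pca + mediation ----------------------------------------------------
    if "pca_mediation" in stages:
        stage, started = "pca_mediation", time.time()
        try:
            if ages is None:
                raise ValueError("pca_mediation requires the clock stage")
            pca_res = run_pca(dataset, n_components=config.n_pca_components)
            _write_tsv(pca_res.scores, out / "pca_scores.tsv")
            meta = dataset.metadata
            usable = meta.index[~meta["relatedness"].isna()]
            preds = pd.DataFrame(
                {
                    "relatedness": meta.loc[usable, "relatedness"],
                    "sex": meta.loc[usable, "sex"],
                    "eaa": ages.loc[usable, "eaa"],
                }
            )
            assoc = pc_associations(
                PcaSubset(pca_res, usable), preds,
            )
            _write_tsv(assoc["per_pc"].set_index("pc"), out / "pc_assoc.tsv")
            _write_tsv(
                assoc["joint"].set_index("predictor"), out / "pc_manova.tsv"
            )
            med_out = []
            covs = meta.loc[usable, ["age_months", "sex"]]
            for j, med in enumerate(config.mediators):
                res = mediate(
                    meta.loc[usable, "relatedness"].to_numpy(float),
                    pca_res.scores.loc[usable, med].to_numpy(float),
                    ages.loc[usable, "eaa"].to_numpy(float),
                    covariates=covs,
                    n_boot=config.n_boot,
                    seed=config.seed + j,
                    mediator_name=med,
                )
                sens = mediation_sensitivity(
                    meta.loc[usable, "relatedness"].to_numpy(float),
                    pca_res.scores.loc[usable, med].to_numpy(float),
                    ages.loc[usable, "eaa"].to_numpy(float),
                    covariates=covs,
                )
                d = res.to_dict()
                d["sensitivity_rho_zero"] = sens.attrs["rho_zero"]
                med_out.append(d)
            strat = sex_stratified_mediation(
                meta.loc[usable],
                pca_res.scores.loc[usable, list(config.mediators)],
                ages.loc[usable, "eaa"],
                n_boot=config.n_boot,
                seed=config.seed,
            )
            _write_json(med_out, out / "mediation.json")
            if len(strat):
                _write_tsv(strat.set_index(["sex", "mediator"]),
                           out / "mediation_by_sex.tsv")
            record(stage, started,
                   variance_explained=pca_res.variance_explained[:3].sum())
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    # --- enrichment ---------------------------------------------------------
    if "enrichment" in stages:
        stage, started = "enrichment", time.time()
        try:
            if ewas_tbl is None:
                raise ValueError("enrichment requires the ewas stage")
            edir = out / "enrich"
            edir.mkdir(exist_ok=True)
            chrom = chromosome_enrichment(
                ewas_tbl, dataset.annotation, q_thresh=config.fdr_ewas
            )
            _write_tsv(chrom.set_index("chrom"), edir / "chrom_enrichment.tsv")
            windows = window_enrichment(
                ewas_tbl, dataset.annotation, window_bp=config.window_bp,
                sig_q=config.fdr_signature,
            )
            if len(windows):
                _write_tsv(windows, edir / "windows.tsv")
                windows_to_bed(windows, edir / "windows.bed")
                genes = map_genes(windows)
                if len(genes):
                    _write_tsv(genes.set_index("gene"), edir / "window_genes.tsv")
            record(stage, started, n_windows=len(windows))
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    # --- signature ------------------------------------------------------------
    if "signature" in stages:
        stage, started = "signature", time.time()
        try:
            if ewas_tbl is None:
                raise ValueError("signature requires the ewas stage")
            sdir = out / "sig"
            sdir.mkdir(exist_ok=True)
            model = build_signature(
                dataset, ewas_tbl, q_thresh=config.fdr_signature,
                seed=config.seed,
            )
            _write_json(model.to_dict(), sdir / "signature.json")
            _write_tsv(model.observed_vs_predicted, sdir / "predictions.tsv")
            record(stage, started, rmse=model.rmse, r2=model.r2,
                   n_cpgs=len(model.cpg_ids))
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["files"][str(path.relative_to(out))] = _sha256(path)
    _write_json(manifest, out / "manifest.json")
    return manifest


class PcaSubset:
    """View of a PcaResult restricted to a sample subset (scores only)."""

    def __init__(self, pca_res, samples):
        self.scores = pca_res.scores.loc[samples]
        self.variance_explained = pca_res.variance_explained
        self.loadings = pca_res.loadings
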