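"""Pedigree parsing, kinship coefficients, and parental-relatedness scores.

The kinship coefficient phi(i, j) is the probability that an allele drawn at
random from individual i is identical by descent (IBD) with an allele drawn
at random from j.  For a pedigree with founders assumed non-inbred and
mutually unrelated, phi satisfies the classical recursion

    phi(i, i) = 1/2 * (1 + phi(f_i, m_i))
    phi(i, j) = 1/2 * (phi(f_i, j) + phi(m_i, j))    (j not a descendant of i)

where f_i, m_i are i's sire and dam and phi involving an unknown (founder)
parent is 0.  Processing individuals in topological order makes the second
rule valid for every earlier individual j.

An individual's *parental relatedness score* is the kinship between its sire
and dam, rescaled: the default ``percent`` scale is the relationship
coefficient of the parents in percent, 2 * phi(sire, dam) * 100, so offspring
of full sibs score 50 and offspring of unrelated founders score 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

#: sentinel strings accepted for an unknown parent in input tables
UNKNOWN_PARENT = {"0", "NA", "", "nan", "None", "."}

#: multiplicative factors applied to phi(sire, dam) for each score scale
RELATEDNESS_SCALES = {"phi": 1.0, "2phi": 2.0, "percent": 200.0}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, duplicates...)."""


@dataclass
class Pedigree:
    """A topologically sorted pedigree.

    Attributes
    ----------
    table : pandas.DataFrame
        One row per individual, columns ``id, sire, dam, sex, birth_index``,
        sorted so every parent precedes its offspring.  Unknown parents are
        ``None``.  ``half_founder`` flags individuals with exactly one known
        parent: they are treated as founders for kinship purposes.
    """

    table: pd.DataFrame
    _pos: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self._pos = {i: k for k, i in enumerate(self.table["id"])}

    def __len__(self):
        return len(self.table)

    @property
    def ids(self) -> list:
        return list(self.table["id"])

    def position(self, individual_id) -> int:
        return self._pos[individual_id]

    def parents(self, individual_id):
        """Return (sire, dam) as stored (None = unknown/ignored)."""
        row = self.table.iloc[self._pos[individual_id]]
        return row["sire"], row["dam"]


def _normalize_parent(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    value = str(value).strip()
    return None if value in UNKNOWN_PARENT else value


def build_pedigree(records) -> Pedigree:
    """Build a validated, topologically sorted :class:`Pedigree`.

    Parameters
    ----------
    records : DataFrame or iterable of mappings
        Must provide ``id, sire, dam, sex`` and optionally ``birth_index``
        (or ``birthdate``, used only for deterministic tie-breaking).

    Raises
    ------
    PedigreeError
        On duplicated ids, a parent-graph cycle (the cycle is named in the
        message), a referenced parent that does not exist, or a parent whose
        recorded sex contradicts its role.
    """
    df = pd.DataFrame(records).copy()
    required = {"id", "sire", "dam", "sex"}
    missing = required - set(df.columns)
    if missing:
        raise PedigreeError(f"missing pedigree columns: {sorted(missing)}")
    df["id"] = df["id"].astype(str).str.strip()
    dup = df["id"][df["id"].duplicated()]
    if len(dup):
        raise PedigreeError(f"duplicated individual ids: {sorted(set(dup))}")
    df["sire"] = [_normalize_parent(v) for v in df["sire"]]
    df["dam"] = [_normalize_parent(v) for v in df["dam"]]
    df["sex"] = [
        s if (s := str(v).strip().upper()[:1]) in {"M", "F"} else "U"
        for v in df["sex"]
    ]
    if "birth_index" not in df.columns:
        if "birthdate" in df.columns:
            order = pd.to_datetime(df["birthdate"], errors="coerce")
            df["birth_index"] = order.rank(method="first").fillna(0).astype(int)
        else:
            df["birth_index"] = range(len(df))

    known = set(df["id"])
    sex_of = dict(zip(df["id"], df["sex"]))
    for col, role, ok in (("sire", "sire", "M"), ("dam", "dam", "F")):
        for child, parent in zip(df["id"], df[col]):
            if parent is None:
                continue
            if parent not in known:
                raise PedigreeError(
                    f"{role} {parent!r} of {child!r} is not in the pedigree"
                )
            if sex_of[parent] not in (ok, "U"):
                raise PedigreeError(
                    f"{role} {parent!r} of {child!r} has sex {sex_of[parent]}"
                )

    graph = nx.DiGraph()
    graph.add_nodes_from(df["id"])
    for child, sire, dam in zip(df["id"], df["sire"], df["dam"]):
        for parent in (sire, dam):
            if parent is not None:
                graph.add_edge(parent, child)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = " -> ".join(str(a) for a, _ in nx.find_cycle(graph))
        raise PedigreeError(f"cycle in parent graph: {cycle}")

    # deterministic topological order: ties broken by birth_index then id
    birth = dict(zip(df["id"], df["birth_index"]))
    order = list(
        nx.lexicographical_topological_sort(graph, key=lambda v: (birth[v], v))
    )
    df = df.set_index("id").loc[order].reset_index()
    # exactly one known parent: treated as a founder for kinship, flagged
    df["half_founder"] = [
        (s is None) != (d is None) for s, d in zip(df["sire"], df["dam"])
    ]
    return Pedigree(df)


@dataclass
class KinshipMatrix:
    """Symmetric kinship coefficients for every individual in a pedigree."""

    ids: list
    phi: np.ndarray

    def __getitem__(self, pair):
        i, j = pair
        pos = {ident: k for k, ident in enumerate(self.ids)}
        return self.phi[pos[i], pos[j]]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.phi, index=self.ids, columns=self.ids)

    def inbreeding(self) -> pd.Series:
        """F_i = 2 * phi(i, i) - 1."""
        return pd.Series(2.0 * np.diag(self.phi) - 1.0, index=self.ids)


def kinship_matrix(ped: Pedigree) -> KinshipMatrix:
    """Compute the full kinship matrix by the tabular recursion.

    Founders (and individuals with any unknown parent) are taken non-inbred
    and unrelated to all earlier individuals except through recorded links.
    Deterministic: depends only on the pedigree structure.
    """
    n = len(ped)
    tbl = ped.table
    phi = np.zeros((n, n))
    sire_pos = np.full(n, -1)
    dam_pos = np.full(n, -1)
    for k, (s, d, half) in enumerate(
        zip(tbl["sire"], tbl["dam"], tbl["half_founder"])
    ):
        if half or s is None or d is None:
            continue  # founder-equivalent
        sire_pos[k] = ped.position(s)
        dam_pos[k] = ped.position(d)
    for i in range(n):
        f, m = sire_pos[i], dam_pos[i]
        if f >= 0:
            phi[i, i] = 0.5 * (1.0 + phi[f, m])
            row = 0.5 * (phi[f, :i] + phi[m, :i])
        else:
            phi[i, i] = 0.5
            row = np.zeros(i)
        phi[i, :i] = row
        phi[:i, i] = row
    return KinshipMatrix(ped.ids, phi)


def parental_relatedness(
    ped: Pedigree,
    individual_id,
    scale: str = "percent",
    kin: KinshipMatrix | None = None,
) -> float:
    """Relatedness score of one individual: scaled kinship of its parents.

    Returns NaN for founders and half-founders (score undefined); callers
    should exclude such animals from downstream models.
    """
    if scale not in RELATEDNESS_SCALES:
        raise ValueError(f"unknown scale {scale!r}")
    sire, dam = ped.parents(individual_id)
    row = ped.table.iloc[ped.position(individual_id)]
    if sire is None or dam is None or row["half_founder"]:
        return float("nan")
    if kin is None:
        kin = kinship_matrix(ped)
    return RELATEDNESS_SCALES[scale] * kin.phi[ped.position(sire), ped.position(dam)]


def relatedness_scores(ped: Pedigree, ids=None, scale: str = "percent") -> pd.Series:
    """Parental relatedness for many individuals (one shared kinship pass)."""
    kin = kinship_matrix(ped)
    ids = ped.ids if ids is None else list(ids)
    return pd.Series(
        [parental_relatedness(ped, i, scale, kin) for i in ids], index=ids
    )


def cohort_relatedness_matrix(
    ped: Pedigree,
    cohort_ids,
    scale: str = "percent",
    n_permutations: int = 1000,
    seed: int = 0,
):
    """Pairwise kinship among a cohort, ordered by ascending parental relatedness.

    Returns ``(matrix, summary)`` where *matrix* is a DataFrame of pairwise
    phi in the stated order and *summary* quantifies whether animals with
    similar parental relatedness are themselves more related: the Pearson
    correlation between |rank_i - rank_j| of parental relatedness and
    phi(i, j) over distinct pairs, with a permutation p-value (labels of the
    ordering shuffled).  Near-zero correlation supports the claim that the
    parental-relatedness gradient does not come with cohort substructure.
    """
    cohort_ids = list(cohort_ids)
    if not cohort_ids:
        raise ValueError("empty cohort")
    missing = [i for i in cohort_ids if i not in ped._pos]
    if missing:
        raise PedigreeError(f"cohort ids not in pedigree: {missing}")
    kin = kinship_matrix(ped)
    scores = pd.Series(
        [parental_relatedness(ped, i, scale, kin) for i in cohort_ids],
        index=cohort_ids,
    )
    order = scores.sort_values(kind="mergesort", na_position="first").index
    pos = [ped.position(i) for i in order]
    sub = kin.phi[np.ix_(pos, pos)]
    matrix = pd.DataFrame(sub, index=order, columns=order)

    n = len(order)
    summary = {"n": n, "correlation": 0.0, "perm_p": 1.0}
    if n >= 3:
        iu = np.triu_indices(n, k=1)
        ranks = np.arange(n, dtype=float)
        rank_dist = np.abs(ranks[:, None] - ranks[None, :])[iu]
        phis = sub[iu]
        if np.std(phis) > 0 and np.std(rank_dist) > 0:
            obs = float(np.corrcoef(rank_dist, phis)[0, 1])
            rng = np.random.default_rng(seed)
            count = 0
            for _ in range(n_permutations):
                perm = rng.permutation(n)
                pd_ = np.abs(
                    perm[:, None].astype(float) - perm[None, :].astype(float)
                )[iu]
                if abs(np.corrcoef(pd_, phis)[0, 1]) >= abs(obs) - 1e-12:
                    count += 1
            summary = {
                "n": n,
                "correlation": obs,
                "perm_p": (count + 1) / (n_permutations + 1),
            }
    return matrix, summary


def gene_drop_kinship(
    ped: Pedigree,
    n_reps: int = 100_000,
    seed: int = 0,
    pairs=None,
) -> pd.DataFrame:
    """Monte-Carlo kinship estimates by gene dropping.

    Founders receive two unique alleles each; every other individual inherits
    one allele chosen at random from each parent.  phi(i, j) is estimated as
    the mean over replicates of the probability that a random allele of i
    equals a random allele of j, i.e. the mean of
    (1/4) * sum over the 4 allele pairings of IBD indicators.  This is a
    simulation-based estimator used as an independent cross-check of the
    exact recursion.

    Returns a DataFrame with columns ``id1, id2, phi_hat, se`` for the
    requested pairs (default: all unordered pairs including self-pairs).
    """
    rng = np.random.default_rng(seed)
    n = len(ped)
    tbl = ped.table
    sire_pos = np.full(n, -1)
    dam_pos = np.full(n, -1)
    for k, (s, d, half) in enumerate(
        zip(tbl["sire"], tbl["dam"], tbl["half_founder"])
    ):
        if half or s is None or d is None:
            continue
        sire_pos[k] = ped.position(s)
        dam_pos[k] = ped.position(d)

    a1 = np.zeros((n, n_reps), dtype=np.int32)
    a2 = np.zeros((n, n_reps), dtype=np.int32)
    next_allele = 0
    for i in range(n):
        f, m = sire_pos[i], dam_pos[i]
        if f < 0:
            a1[i] = 2 * next_allele
            a2[i] = 2 * next_allele + 1
            next_allele += 1
        else:
            pick_f = rng.integers(0, 2, n_reps)
            pick_m = rng.integers(0, 2, n_reps)
            a1[i] = np.where(pick_f == 0, a1[f], a2[f])
            a2[i] = np.where(pick_m == 0, a1[m], a2[m])

    if pairs is None:
        pairs = [
            (ped.ids[i], ped.ids[j]) for i in range(n) for j in range(i, n)
        ]
    rows = []
    for id1, id2 in pairs:
        i, j = ped.position(id1), ped.position(id2)
        if i == j:
            ibd = 0.25 * (2.0 + 2.0 * (a1[i] == a2[i]))
        else:
            ibd = 0.25 * (
                (a1[i] == a1[j]).astype(float)
                + (a1[i] == a2[j])
                + (a2[i] == a1[j])
                + (a2[i] == a2[j])
            )
        est = float(ibd.mean())
        rows.append(
            {
                "id1": id1,
                "id2": id2,
                "phi_hat": est,
                "se": float(ibd.std(ddof=1) / np.sqrt(n_reps)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# I/O


def read_pedigree(path) -> Pedigree:
    """Read a pedigree TSV (columns id, sire, dam, sex[, birthdate])."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return build_pedigree(df)


def write_kinship(kin: KinshipMatrix, path) -> None:
    kin.to_frame().to_csv(path, sep="\t", float_format="%.10g")
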