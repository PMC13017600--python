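"""Genomic enrichment of relatedness-associated CpGs.

Two resolutions:

* per chromosome — a 2x2 contingency table (significant/non-significant x
  on/off the chromosome) tested with a two-sided Fisher exact test, BH
  adjusted across chromosomes, with expected counts under a uniform spread
  of significant CpGs over the assayed background;
* per 2-Mb window — non-overlapping tiling of each chromosome; the number
  of significant CpGs among those assayed in a window is tested against the
  genome-wide rate with an upper-tail hypergeometric test, BH adjusted over
  windows containing at least one assayed CpG; genes annotated to the
  significant CpGs in enriched windows are reported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .ewas import bh_adjust


def _tested(table: pd.DataFrame) -> pd.DataFrame:
    return table[table["status"].isin(["ok", "degenerate"])]


def expected_counts(annotation: pd.DataFrame, k_sig_total: int) -> pd.Series:
    """Expected significant CpGs per chromosome if spread uniformly:
    expected_c = K * assayed_c / N.  Sums exactly to K."""
    assayed = annotation["chrom"].value_counts()
    return k_sig_total * assayed / assayed.sum()


def chromosome_enrichment(
    ewas_table: pd.DataFrame,
    annotation: pd.DataFrame,
    q_thresh: float = 0.1,
) -> pd.DataFrame:
    """Per-chromosome Fisher enrichment/depletion of significant CpGs.

    Chromosomes with zero assayed CpGs are absent from the output.  With no
    significant CpGs anywhere, every row is flagged (p = 1).
    """
    tested = _tested(ewas_table)
    chrom = annotation.loc[tested.index, "chrom"]
    sig = (tested["q"] < q_thresh).to_numpy()
    k_total = int(sig.sum())
    n_total = len(tested)
    expected = expected_counts(annotation.loc[tested.index], k_total)
    rows = []
    for c in sorted(chrom.unique(), key=str):
        on = (chrom == c).to_numpy()
        sig_on = int((sig & on).sum())
        nonsig_on = int((~sig & on).sum())
        sig_off = k_total - sig_on
        nonsig_off = (n_total - k_total) - nonsig_on
        table = [[sig_on, nonsig_on], [sig_off, nonsig_off]]
        if k_total == 0:
            oratio, p = np.nan, 1.0
        else:
            oratio, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append(
            {
                "chrom": c,
                "sig_on": sig_on,
                "nonsig_on": nonsig_on,
                "sig_off": sig_off,
                "nonsig_off": nonsig_off,
                "expected_sig": float(expected.get(c, 0.0)),
                "odds_ratio": float(oratio),
                "fisher_p": float(p),
                "flagged": k_total == 0,
            }
        )
    out = pd.DataFrame(rows)
    out["q_bh"] = bh_adjust(out["fisher_p"])
    with np.errstate(invalid="ignore"):
        out["direction"] = np.where(
            out["sig_on"] > out["expected_sig"], "enriched", "depleted"
        )
    return out


def window_enrichment(
    ewas_table: pd.DataFrame,
    annotation: pd.DataFrame,
    window_bp: int = 2_000_000,
    sig_q: float = 0.05,
    step_bp: int | None = None,
) -> pd.DataFrame:
    """Per-window hypergeometric enrichment of significant CpGs.

    Windows are 0-based half-open ``[start, start + window_bp)`` tiles
    (``step_bp`` defaults to ``window_bp``; a smaller step gives true
    sliding windows).  For a window with n assayed CpGs of which k are
    significant, given K significant among N genome-wide,
    p = P[X >= k], X ~ Hypergeom(N, K, n).  BH is computed across windows
    with >= 1 assayed CpG.  Genes of the significant CpGs inside each
    window are listed.
    """
    if window_bp <= 0:
        raise ValueError("window width must be positive")
    step = window_bp if step_bp is None else int(step_bp)
    if step <= 0:
        raise ValueError("window step must be positive")
    tested = _tested(ewas_table)
    ann = annotation.loc[tested.index]
    sig = (tested["q"] < sig_q).to_numpy()
    N = len(tested)
    K = int(sig.sum())
    rows = []
    for c in sorted(ann["chrom"].unique(), key=str):
        on = (ann["chrom"] == c).to_numpy()
        pos = ann.loc[on, "pos_bp"].to_numpy(dtype=np.int64) - 1  # to 0-based
        sig_c = sig[on]
        genes_c = ann.loc[on, "gene"].to_numpy()
        cpgs_c = ann.index[on].to_numpy()
        if pos.size == 0:
            continue
        max_pos = int(pos.max())
        start = 0
        while start <= max_pos:
            in_win = (pos >= start) & (pos < start + window_bp)
            n_w = int(in_win.sum())
            if n_w > 0:
                k_w = int(sig_c[in_win].sum())
                p = float(stats.hypergeom.sf(k_w - 1, N, K, n_w)) if k_w > 0 else 1.0
                sig_genes = sorted(set(genes_c[in_win & sig_c]))
                rows.append(
                    {
                        "chrom": c,
                        "start": start,
                        "end": start + window_bp,
                        "k_sig": k_w,
                        "n_assayed": n_w,
                        "K_sig_total": K,
                        "N_total": N,
                        "hypergeom_p": min(p, 1.0),
                        "genes": ",".join(sig_genes),
                        "cpgs": ",".join(sorted(cpgs_c[in_win & sig_c])),
                    }
                )
            start += step
    out = pd.DataFrame(rows)
    if len(out):
        out["q_bh"] = bh_adjust(out["hypergeom_p"])
    return out


def map_genes(windows: pd.DataFrame, q_thresh: float = 0.05) -> pd.DataFrame:
    """Genes driving significantly enriched windows (one row per gene)."""
    sig = windows[windows.get("q_bh", pd.Series(dtype=float)) < q_thresh]
    rows = []
    for _, row in sig.iterrows():
        for gene in filter(None, str(row["genes"]).split(",")):
            rows.append(
                {
                    "gene": gene,
                    "chrom": row["chrom"],
                    "window_start": row["start"],
                    "window_end": row["end"],
                    "window_q": row["q_bh"],
                }
            )
    return pd.DataFrame(rows)


def windows_to_bed(windows: pd.DataFrame, path) -> None:
    """Write windows as BED4 (chrom, start, end, q-value)."""
    bed = windows[["chrom", "start", "end", "q_bh"]].copy()
    bed.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")
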