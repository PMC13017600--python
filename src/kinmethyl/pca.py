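"""PCA of the beta matrix and per-PC association models.

Scores are computed from the column-centered sample x CpG matrix (missing
betas imputed by the CpG mean).  Component signs are fixed by making each
component's largest-magnitude loading positive, so downstream effect signs
are reproducible.  Per-PC associations are simple linear models
PCk ~ predictor; the joint test for (PC1, PC2) ~ predictor uses MANOVA's
Pillai trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.decomposition import PCA

from .clock import _impute_cpg_means


@dataclass
class PcaResult:
    scores: pd.DataFrame             # samples x components ("PC1", ...)
    variance_explained: np.ndarray   # fractions, nonincreasing
    loadings: pd.DataFrame           # CpGs x components

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def run_pca(dataset, n_components: int = 10) -> PcaResult:
    """Column-centered PCA of samples over CpG features."""
    X = _impute_cpg_means(dataset.beta.to_numpy(dtype=float).T)
    n, m = X.shape
    if n_components > min(n, m):
        raise ValueError("n_components exceeds matrix rank bound")
    pca = PCA(n_components=n_components, svd_solver="randomized", random_state=0)
    scores = pca.fit_transform(X)
    loadings = pca.components_.T  # m x k
    # deterministic sign: largest-|loading| entry positive per component
    for k in range(n_components):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=dataset.beta.columns, columns=cols),
        variance_explained=pca.explained_variance_ratio_.copy(),
        loadings=pd.DataFrame(loadings, index=dataset.beta.index, columns=cols),
    )


def _pillai_manova(Y: np.ndarray, x: np.ndarray):
    """Pillai trace and approximate F for the one-predictor MANOVA Y ~ x."""
    n, p = Y.shape
    X = np.column_stack([np.ones(n), x])
    q = 1  # hypothesis df (single predictor)
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    E = resid.T @ resid
    Yc = Y - Y.mean(axis=0)
    T = Yc.T @ Yc
    H = T - E
    eigvals = np.linalg.eigvals(np.linalg.solve(E + H, H)).real
    pillai = float(np.sum(eigvals))
    s = min(p, q)
    m_ = (abs(p - q) - 1) / 2.0
    n_ = (n - X.shape[1] - p - 1) / 2.0
    df1 = s * (2 * m_ + s + 1)
    df2 = s * (2 * n_ + s + 1)
    f_stat = (pillai / (s - pillai)) * (df2 / df1) if s > pillai else np.inf
    p_value = float(stats.f.sf(f_stat, df1, df2))
    return pillai, f_stat, (df1, df2), p_value


def pc_associations(
    pca: PcaResult,
    predictors: pd.DataFrame,
    joint_components=("PC1", "PC2"),
) -> dict:
    """Per-PC linear-model p-values plus a joint MANOVA test per predictor.

    ``predictors`` is a samples x predictors frame aligned with the scores
    (sex columns may be 'F'/'M' strings).  Returns ``{"per_pc": DataFrame,
    "joint": DataFrame}``.
    """
    scores = pca.scores
    rows = []
    joint_rows = []
    for name in predictors.columns:
        v = predictors[name]
        if v.dtype == object:
            x = np.asarray(
                [1.0 if str(s).upper().startswith("M") else 0.0 for s in v]
            )
        else:
            x = v.to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(f"predictor {name!r} is constant")
        n = len(x)
        X = np.column_stack([np.ones(n), x])
        for pc in scores.columns:
            fit = sm.OLS(scores[pc].to_numpy(), X).fit()
            rows.append(
                {
                    "pc": pc,
                    "predictor": name,
                    "coef": float(fit.params[1]),
                    "p": float(fit.pvalues[1]),
                    "r2": float(fit.rsquared),
                }
            )
        Y = scores.loc[:, list(joint_components)].to_numpy()
        pillai, f_stat, dfs, p_value = _pillai_manova(Y, x)
        joint_rows.append(
            {
                "predictor": name,
                "components": "+".join(joint_components),
                "pillai": pillai,
                "f": f_stat,
                "df1": dfs[0],
                "df2": dfs[1],
                "p": p_value,
            }
        )
    return {"per_pc": pd.DataFrame(rows), "joint": pd.DataFrame(joint_rows)}
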