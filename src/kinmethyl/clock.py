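"""Surrogate epigenetic clock, corrected age, EAA, and its relatedness regression.

The clock is a penalized linear regression of chronological age on CpG beta
values (elastic net, l1_ratio 0.5, penalty chosen by internal cross
validation) — a stand-in from the same model family as published mammalian
methylation clocks, trained here on the data at hand.  Externally computed
DNAmAge columns are accepted anywhere a predicted age is needed.

Derived per-sample quantities:

* ``corrected_age = DNAmAge * (mean chronological age / mean DNAmAge)`` —
  a cohort-level rescaling so predicted and chronological means match;
* ``residual_age = corrected_age - chronological age``;
* ``EAA`` — residuals of OLS DNAmAge ~ age + sex; by construction EAA is
  orthogonal to age and to the sex indicator.

The relatedness association of EAA is estimated by OLS with conventional and
HC3 heteroskedasticity-consistent standard errors, by Huber M-estimation,
and summarized through the added-variable (partial regression) construction
with a leave-one-out slope distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold


def _impute_cpg_means(X: np.ndarray) -> np.ndarray:
    X = X.copy()
    means = np.nanmean(X, axis=0)
    means = np.where(np.isnan(means), 0.5, means)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = means[nan_c]
    return X


@dataclass
class ClockModel:
    """Fitted surrogate clock: sparse linear map from betas to age (months)."""

    cpg_ids: list
    intercept: float
    coefficients: np.ndarray
    alpha: float
    cv_summary: dict = field(default_factory=dict)
    training_means: np.ndarray | None = None

    @property
    def selected_cpgs(self) -> list:
        return [c for c, w in zip(self.cpg_ids, self.coefficients) if w != 0]

    def predict(self, beta: pd.DataFrame) -> pd.Series:
        """Predict DNAmAge for each sample (beta: CpG x sample)."""
        X = beta.reindex(self.cpg_ids).to_numpy(dtype=float).T
        means = (
            self.training_means
            if self.training_means is not None
            else np.full(len(self.cpg_ids), 0.5)
        )
        nan_r, nan_c = np.where(np.isnan(X))
        X[nan_r, nan_c] = means[nan_c]
        return pd.Series(
            self.intercept + X @ self.coefficients, index=beta.columns,
            name="dnam_age",
        )


def train_clock(dataset, seed: int = 0, folds: int = 5) -> ClockModel:
    """Train the surrogate clock and return it with out-of-fold predictions.

    The elastic-net penalty is chosen by ``folds``-fold cross-validation on
    the full cohort; out-of-fold predictions (stored in
    ``cv_summary['oof_prediction']``) then come from refitting the chosen
    penalty within each fold, giving an honest view of clock accuracy.
    """
    ages = dataset.metadata["age_months"].to_numpy(float)
    n = len(ages)
    if n < 30:
        raise ValueError("need >= 30 aged samples to train the clock")
    if folds > n:
        raise ValueError("more folds than samples")
    if np.ptp(ages) == 0:
        raise ValueError("all chronological ages equal; clock is degenerate")
    X = _impute_cpg_means(dataset.beta.to_numpy(dtype=float).T)
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    enet = ElasticNetCV(
        l1_ratio=0.5, alphas=25, cv=cv, max_iter=5000, random_state=seed
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        enet.fit(X, ages)
    oof = np.empty(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for train, test in cv.split(X):
            fold_model = ElasticNet(
                alpha=enet.alpha_, l1_ratio=0.5, max_iter=5000,
                random_state=seed,
            )
            fold_model.fit(X[train], ages[train])
            oof[test] = fold_model.predict(X[test])
    r = float(np.corrcoef(ages, oof)[0, 1])
    model = ClockModel(
        cpg_ids=list(dataset.beta.index),
        intercept=float(enet.intercept_),
        coefficients=enet.coef_.copy(),
        alpha=float(enet.alpha_),
        cv_summary={
            "folds": folds,
            "oof_pearson_r": r,
            "oof_prediction": pd.Series(oof, index=dataset.metadata.index),
            "n_nonzero": int(np.count_nonzero(enet.coef_)),
        },
        training_means=np.nanmean(X, axis=0),
    )
    return model


def corrected_age(dnam_ages, chron_ages) -> np.ndarray:
    """CorrectedAge = DNAmAge * (AvAge / AvDNAmAge).

    Rescales predicted ages so the cohort mean matches the chronological
    mean exactly.
    """
    dnam = np.asarray(dnam_ages, dtype=float)
    chron = np.asarray(chron_ages, dtype=float)
    if dnam.mean() == 0:
        raise ValueError("mean DNAmAge is zero; corrected age undefined")
    return dnam * (chron.mean() / dnam.mean())


def compute_eaa(dnam_ages, chron_ages, sex) -> np.ndarray:
    """EAA: residuals of OLS DNAmAge ~ chronological age + sex."""
    dnam = np.asarray(dnam_ages, dtype=float)
    chron = np.asarray(chron_ages, dtype=float)
    male = np.asarray(
        [1.0 if str(s).upper().startswith("M") else 0.0 for s in np.asarray(sex)]
    )
    if len(dnam) <= 3:
        raise ValueError("need more than 3 samples")
    X = np.column_stack([np.ones_like(chron), chron, male])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear age/sex design")
    coef, *_ = np.linalg.lstsq(X, dnam, rcond=None)
    return dnam - X @ coef


def age_table(dataset, clock: ClockModel | None = None, dnam_col: str | None = None,
              seed: int = 0) -> pd.DataFrame:
    """Per-sample age records: dnam_age, corrected_age, residual_age, eaa.

    DNAmAge comes from ``dnam_col`` in the metadata if given (externally
    computed ages), otherwise from the supplied or freshly trained clock.
    """
    meta = dataset.metadata
    if dnam_col is not None:
        dnam = meta[dnam_col].to_numpy(float)
    else:
        if clock is None:
            clock = train_clock(dataset, seed=seed)
        dnam = clock.predict(dataset.beta).to_numpy()
    chron = meta["age_months"].to_numpy(float)
    corr = corrected_age(dnam, chron)
    eaa = compute_eaa(dnam, chron, meta["sex"])
    return pd.DataFrame(
        {
            "chron_age": chron,
            "dnam_age": dnam,
            "corrected_age": corr,
            "residual_age": corr - chron,
            "eaa": eaa,
        },
        index=meta.index,
    )


def lifespan_relatedness_correlation(
    metadata: pd.DataFrame, lifespan_col: str = "predicted_lifespan"
) -> dict | None:
    """Pearson correlation of an externally predicted maximal lifespan with
    parental relatedness, when such a column is present.

    The lifespan predictor itself is not re-implemented; this only
    correlates a supplied column.  Returns None when the column is absent.
    """
    if lifespan_col not in metadata.columns:
        return None
    sub = metadata[[lifespan_col, "relatedness"]].dropna()
    if len(sub) < 3:
        return None
    from scipy import stats as _stats

    r, p = _stats.pearsonr(sub[lifespan_col], sub["relatedness"])
    return {"r": float(r), "p": float(p), "n": int(len(sub))}


@dataclass
class EaaRegressionReport:
    """Relatedness -> EAA association with robustness checks."""

    n: int
    beta_ols: float
    se_ols: float
    p_ols: float
    beta_hc3: float
    se_hc3: float
    p_hc3: float
    beta_robust: float
    se_robust: float
    p_robust: float
    partial_r2: float
    jackknife_median: float
    jackknife_iqr: tuple
    jackknife_betas: np.ndarray
    added_variable: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "beta_ols": self.beta_ols, "se_ols": self.se_ols, "p_ols": self.p_ols,
            "beta_hc3": self.beta_hc3, "se_hc3": self.se_hc3, "p_hc3": self.p_hc3,
            "beta_robust": self.beta_robust, "se_robust": self.se_robust,
            "p_robust": self.p_robust,
            "partial_r2": self.partial_r2,
            "jackknife_median": self.jackknife_median,
            "jackknife_iqr": list(self.jackknife_iqr),
        }


def _residualize(v, Z):
    coef, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ coef


def regress_eaa_on_relatedness(
    eaa, relatedness, age=None, sex=None
) -> EaaRegressionReport:
    """Regress EAA on relatedness with OLS, HC3, and Huber M-estimation.

    When age and sex are given they enter as covariates; the reported slope,
    partial R^2 and added-variable coordinates come from the equivalent
    double-residualization (residualize EAA and relatedness on age + sex,
    then regress residual on residual).  The jackknife re-estimates the OLS
    slope leaving each sample out in turn.
    """
    y = np.asarray(eaa, dtype=float)
    t = np.asarray(relatedness, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 samples")
    if np.ptp(t) == 0:
        raise ValueError("relatedness is constant")
    if age is not None and sex is not None:
        male = np.asarray(
            [1.0 if str(s).upper().startswith("M") else 0.0 for s in np.asarray(sex)]
        )
        X = np.column_stack([np.ones(n), np.asarray(age, float), male, t])
    else:
        X = np.column_stack([np.ones(n), t])
    Z = X[:, :-1]
    y_res = _residualize(y, Z)
    t_res = _residualize(t, Z)

    ols = sm.OLS(y, X).fit()
    hc3 = ols.get_robustcov_results(cov_type="HC3")
    rlm = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345)).fit(
        conv="coefs", tol=1e-8, maxiter=100
    )
    k = X.shape[1] - 1
    partial_r2 = float(np.corrcoef(y_res, t_res)[0, 1] ** 2)

    jack = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        mask = idx != i
        coef, *_ = np.linalg.lstsq(X[mask], y[mask], rcond=None)
        jack[i] = coef[-1]
    q1, q3 = np.percentile(jack, [25, 75])

    return EaaRegressionReport(
        n=n,
        beta_ols=float(ols.params[k]),
        se_ols=float(ols.bse[k]),
        p_ols=float(ols.pvalues[k]),
        beta_hc3=float(np.asarray(hc3.params)[k]),
        se_hc3=float(np.asarray(hc3.bse)[k]),
        p_hc3=float(np.asarray(hc3.pvalues)[k]),
        beta_robust=float(rlm.params[k]),
        se_robust=float(rlm.bse[k]),
        p_robust=float(rlm.pvalues[k]),
        partial_r2=partial_r2,
        jackknife_median=float(np.median(jack)),
        jackknife_iqr=(float(q1), float(q3)),
        jackknife_betas=jack,
        added_variable=pd.DataFrame(
            {"relatedness_residual": t_res, "eaa_residual": y_res}
        ),
    )
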