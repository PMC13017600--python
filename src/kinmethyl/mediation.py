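"""Linear causal mediation with nonparametric bootstrap and sensitivity.

For treatment T (parental relatedness), mediator M (a methylome PC score)
and outcome Y (EAA), with covariates X (age, sex), two linear models are
fitted:

    mediator:  M = a*T + X*alpha + e1
    outcome:   Y = c'*T + b*M + X*gamma + e2

Point estimates are the product-of-coefficients decomposition: ACME = a*b
(indirect), ADE = c' (direct), total = c' + a*b, proportion mediated =
ACME/total.  Uncertainty comes from nonparametric case resampling of the
full two-model fit with percentile confidence intervals; the bootstrap
p-value is 2*min(frac <= 0, frac >= 0).

Sensitivity to unmeasured mediator-outcome confounding follows the linear
structural-equation result: if rho is the correlation between e1 and e2,

    ACME(rho) = a * (s2/s1) * (r12 - rho * sqrt((1 - r12^2) / (1 - rho^2)))

where s1, s2 are the residual SDs and r12 the residual correlation from
regressing M and Y each on T and X only.  ACME(0) equals the unadjusted
estimate and ACME crosses zero exactly at rho = r12.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ewas import bh_adjust


@dataclass
class MediationResult:
    mediator: str
    n: int
    n_boot: int
    seed: int
    acme: dict
    ade: dict
    total: dict
    prop_mediated: dict
    stratum: str = "all"
    coefficients: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "mediator": self.mediator,
            "stratum": self.stratum,
            "n": self.n,
            "n_boot": self.n_boot,
            "seed": self.seed,
            "acme": self.acme,
            "ade": self.ade,
            "total": self.total,
            "prop_mediated": self.prop_mediated,
            "coefficients": self.coefficients,
        }


def _encode_sex(sex) -> np.ndarray:
    return np.asarray(
        [1.0 if str(s).upper().startswith("M") else 0.0 for s in np.asarray(sex)]
    )


def _fit_two_models(t, m, y, Z):
    """Return (a, b, direct) from the mediator and outcome models."""
    Xm = np.column_stack([np.ones_like(t), t, Z]) if Z is not None else \
        np.column_stack([np.ones_like(t), t])
    Xy = np.column_stack([Xm[:, :2], m[:, None], Xm[:, 2:]])
    am, *_ = np.linalg.lstsq(Xm, m, rcond=None)
    ay, *_ = np.linalg.lstsq(Xy, y, rcond=None)
    return am[1], ay[2], ay[1]


def _summary(boot: np.ndarray, estimate: float) -> dict:
    boot = boot[~np.isnan(boot)]
    if boot.size == 0:
        return {"estimate": estimate, "ci_low": np.nan, "ci_high": np.nan,
                "p": np.nan}
    lo, hi = np.percentile(boot, [2.5, 97.5])
    p = 2.0 * min((boot <= 0).mean(), (boot >= 0).mean())
    return {
        "estimate": float(estimate),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "p": float(min(p, 1.0)),
    }


def mediate(
    treatment,
    mediator,
    outcome,
    covariates: pd.DataFrame | None = None,
    n_boot: int = 10_000,
    seed: int = 0,
    mediator_name: str = "mediator",
    stratum: str = "all",
) -> MediationResult:
    """Estimate ACME, ADE, total effect and proportion mediated.

    ``covariates`` may include a 'sex' column of 'F'/'M' strings; numeric
    columns pass through.  The bootstrap resamples cases (rows) and refits
    both models; it is fully vectorized over replicates.
    """
    t = np.asarray(treatment, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n = t.size
    if np.ptp(t) == 0:
        raise ValueError("treatment is constant")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives unstable percentile intervals")
    Z = None
    if covariates is not None and covariates.shape[1] > 0:
        cols = []
        for name in covariates.columns:
            col = covariates[name]
            cols.append(
                _encode_sex(col) if col.dtype == object else col.to_numpy(float)
            )
        Z = np.column_stack(cols)

    a, b, direct = _fit_two_models(t, m, y, Z)
    acme = a * b
    total = direct + acme

    # vectorized case-resampling bootstrap: batched normal equations
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    Xm = np.column_stack([np.ones(n), t]) if Z is None else \
        np.column_stack([np.ones(n), t, Z])
    Xy = np.column_stack([Xm[:, :2], m[:, None], Xm[:, 2:]])

    def batched_coef(X, resp, coef_index):
        Xb = X[idx]                       # n_boot x n x p
        yb = resp[idx]                    # n_boot x n
        XtX = np.einsum("bni,bnj->bij", Xb, Xb)
        Xty = np.einsum("bni,bn->bi", Xb, yb)
        sol = np.linalg.solve(XtX, Xty[..., None])[..., 0]
        return sol[:, coef_index]

    with np.errstate(all="ignore"):
        a_b = batched_coef(Xm, m, 1)
        Xyb = Xy[idx]
        yb = y[idx]
        XtX = np.einsum("bni,bnj->bij", Xyb, Xyb)
        Xty = np.einsum("bni,bn->bi", Xyb, yb)
        sol = np.linalg.solve(XtX, Xty[..., None])[..., 0]
        b_b = sol[:, 2]
        direct_b = sol[:, 1]
    acme_b = a_b * b_b
    total_b = direct_b + acme_b
    with np.errstate(all="ignore"):
        prop_b = np.where(total_b != 0, acme_b / total_b, np.nan)

    return MediationResult(
        mediator=mediator_name,
        stratum=stratum,
        n=n,
        n_boot=n_boot,
        seed=seed,
        acme=_summary(acme_b, acme),
        ade=_summary(direct_b, direct),
        total=_summary(total_b, total),
        prop_mediated=_summary(
            prop_b, acme / total if total != 0 else np.nan
        ),
        coefficients={"a": float(a), "b": float(b), "direct": float(direct)},
    )


def mediation_sensitivity(
    treatment, mediator, outcome, covariates: pd.DataFrame | None = None,
    rho_grid=None,
) -> pd.DataFrame:
    """ACME as a function of the mediator-outcome error correlation rho.

    Returns a DataFrame with columns ``rho, acme`` over the grid (default
    -0.9..0.9 in steps of 0.05) with attribute ``rho_zero`` (the crossing
    point, equal to the residual correlation r12) in ``.attrs``.
    """
    if rho_grid is None:
        rho_grid = np.round(np.arange(-0.9, 0.9001, 0.05), 10)
    rho_grid = np.asarray(rho_grid, dtype=float)
    if np.any(np.abs(rho_grid) >= 1):
        raise ValueError("|rho| must be < 1")
    t = np.asarray(treatment, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n = t.size
    X = np.column_stack([np.ones(n), t])
    if covariates is not None and covariates.shape[1] > 0:
        cols = []
        for name in covariates.columns:
            col = covariates[name]
            cols.append(
                _encode_sex(col) if col.dtype == object else col.to_numpy(float)
            )
        X = np.column_stack([X, np.column_stack(cols)])
    coef_m, *_ = np.linalg.lstsq(X, m, rcond=None)
    coef_y, *_ = np.linalg.lstsq(X, y, rcond=None)
    a = coef_m[1]
    e1 = m - X @ coef_m
    e2 = y - X @ coef_y
    s1 = e1.std(ddof=X.shape[1])
    s2 = e2.std(ddof=X.shape[1])
    r12 = float(np.corrcoef(e1, e2)[0, 1])
    acme = a * (s2 / s1) * (
        r12 - rho_grid * np.sqrt((1.0 - r12**2) / (1.0 - rho_grid**2))
    )
    out = pd.DataFrame({"rho": rho_grid, "acme": acme})
    out.attrs["rho_zero"] = r12
    out.attrs["acme_at_zero"] = float(a * (s2 / s1) * r12)
    return out


def sex_stratified_mediation(
    metadata: pd.DataFrame,
    mediators: pd.DataFrame,
    outcome: pd.Series,
    treatment_col: str = "relatedness",
    n_boot: int = 10_000,
    seed: int = 0,
    min_per_sex: int = 20,
) -> pd.DataFrame:
    """Run mediation separately per sex for each mediator column.

    Returns a tidy frame (one row per sex x mediator) with estimates, CIs,
    bootstrap p-values and BH q-values computed within each sex.  Strata
    with fewer than ``min_per_sex`` samples are skipped with a warning.
    """
    rows = []
    for k, sex in enumerate(["F", "M"]):
        members = metadata.index[metadata["sex"] == sex]
        if len(members) < min_per_sex:
            warnings.warn(f"sex {sex}: only {len(members)} samples; skipped")
            continue
        sub = metadata.loc[members]
        covs = sub[["age_months"]]
        for j, med in enumerate(mediators.columns):
            res = mediate(
                sub[treatment_col].to_numpy(float),
                mediators.loc[members, med].to_numpy(float),
                outcome.loc[members].to_numpy(float),
                covariates=covs,
                n_boot=n_boot,
                seed=seed + 1000 * k + j,
                mediator_name=med,
                stratum=sex,
            )
            rows.append(
                {
                    "sex": sex,
                    "mediator": med,
                    "n": res.n,
                    "acme": res.acme["estimate"],
                    "acme_ci_low": res.acme["ci_low"],
                    "acme_ci_high": res.acme["ci_high"],
                    "acme_p": res.acme["p"],
                    "ade": res.ade["estimate"],
                    "ade_p": res.ade["p"],
                    "total": res.total["estimate"],
                    "total_p": res.total["p"],
                    "prop_mediated": res.prop_mediated["estimate"],
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out["acme_q"] = np.nan
        for sex in out["sex"].unique():
            mask = out["sex"] == sex
            out.loc[mask, "acme_q"] = bh_adjust(out.loc[mask, "acme_p"])
    return out
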