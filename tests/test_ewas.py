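"""LRT differential methylation: brute-force oracle, BH, invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from kinmethyl import (
    bh_adjust, direction_counts, fit_cpg_lrt, island_fraction, run_ewas,
)
from kinmethyl.simulate import MethylomeDataset


def _gaussian_loglik_oracle(X, y):
    """Max Gaussian log-likelihood of a linear model by explicit normal
    equations and the variance MLE (independent of the tested code path)."""
    coef = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ coef
    n = len(y)
    s2 = float(resid @ resid) / n
    return -0.5 * n * (np.log(2 * np.pi * s2) + 1.0), coef


class TestFitCpgLrt:
    def setup_method(self):
        rng = np.random.default_rng(42)
        self.n = 24
        self.age = rng.uniform(1, 33, self.n)
        self.sex = np.where(rng.random(self.n) < 0.5, "M", "F")
        self.rel = rng.gamma(2, 8, self.n)

    def test_perfect_linear_fit_floors_p(self):
        y = 0.2 + 0.004 * self.rel
        res = fit_cpg_lrt(y, self.age, self.sex, self.rel)
        assert res["p"] < 1e-12
        assert res["beta3_hat"] == pytest.approx(0.004, rel=1e-6)

    def test_lrt_matches_brute_force_loglik_oracle(self):
        """6-sample worked example: the LRT equals twice the difference of
        independently maximized Gaussian log-likelihoods."""
        age = np.array([2.0, 5.0, 9.0, 14.0, 21.0, 30.0])
        sex = np.array(["F", "M", "F", "M", "F", "M"])
        rel = np.array([0.0, 0.0, 12.5, 25.0, 25.0, 50.0])
        y = np.array([0.31, 0.35, 0.42, 0.38, 0.45, 0.52])
        male = (sex == "M").astype(float)
        Xf = np.column_stack([np.ones(6), age, male, rel])
        ll_full, coef = _gaussian_loglik_oracle(Xf, y)
        ll_red, _ = _gaussian_loglik_oracle(Xf[:, :3], y)
        res = fit_cpg_lrt(y, age, sex, rel, min_samples=6)
        assert res["lrt_stat"] == pytest.approx(2 * (ll_full - ll_red), rel=1e-9)
        assert res["beta3_hat"] == pytest.approx(coef[3], rel=1e-9)

    def test_constant_beta_vector_is_degenerate(self):
        res = fit_cpg_lrt(np.full(self.n, 0.4), self.age, self.sex, self.rel)
        assert res["status"] == "degenerate"
        assert res["p"] == 1.0 and res["beta3_hat"] == 0.0

    def test_below_min_samples_skipped(self):
        y = np.full(self.n, np.nan)
        y[:5] = 0.5
        res = fit_cpg_lrt(y, self.age, self.sex, self.rel)
        assert res["status"] == "skipped" and np.isnan(res["p"])

    def test_p_invariant_to_age_rescaling_and_sex_swap(self):
        rng = np.random.default_rng(0)
        y = 0.4 + 0.002 * self.rel + rng.normal(0, 0.03, self.n)
        base = fit_cpg_lrt(y, self.age, self.sex, self.rel)
        scaled = fit_cpg_lrt(y, 12 * self.age + 7, self.sex, self.rel)
        swapped_sex = np.where(self.sex == "M", "F", "M")
        swapped = fit_cpg_lrt(y, self.age, swapped_sex, self.rel)
        assert base["p"] == pytest.approx(scaled["p"], rel=1e-9)
        assert base["p"] == pytest.approx(swapped["p"], rel=1e-9)

    def test_null_type_one_error_calibrated(self):
        """Rejection rate at p < 0.05 within 3 binomial SE under the null."""
        rng = np.random.default_rng(123)
        n, m = 96, 2000
        age = rng.uniform(1.3, 33, n)
        sex = np.where(rng.random(n) < 0.5, "M", "F")
        rel = rng.gamma(2, 8, n)
        hits = 0
        for _ in range(m):
            y = 0.5 + 0.003 * age + rng.normal(0, 0.05, n)
            if fit_cpg_lrt(y, age, sex, rel)["p"] < 0.05:
                hits += 1
        rate = hits / m
        assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / m)


class TestBhAdjust:
    def test_step_up_by_hand(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_and_single(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_nan_passthrough(self):
        q = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(q[1])
        # m counts only the non-NaN entries
        assert q[0] == pytest.approx(0.02)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([-0.1, 0.5])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=200))
    def test_matches_reference_step_up(self, pvals):
        ours = bh_adjust(pvals)
        ref = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(ours, ref, atol=1e-12)


class TestRunEwas:
    def test_planted_recovery_and_q_monotone(self, default_dataset,
                                             default_ewas):
        _, ds = default_dataset
        tbl = default_ewas
        planted = ds.truth["cls"] == "relatedness"
        sig = tbl["q"] < 0.1
        sens = float((sig & planted).sum()) / planted.sum()
        assert sens >= 0.85
        ok = tbl[tbl["status"] == "ok"].sort_values("p")
        assert (np.diff(ok["q"].to_numpy()) >= -1e-12).all()
        assert (tbl["q"].dropna() >= tbl["p"].dropna() - 1e-12).all()

    def test_single_cpg_dataset_q_equals_p(self):
        rng = np.random.default_rng(1)
        n = 20
        meta = pd.DataFrame(
            {
                "sex": np.where(rng.random(n) < 0.5, "M", "F"),
                "age_months": rng.uniform(1, 33, n),
                "relatedness": rng.gamma(2, 8, n),
            },
            index=pd.Index([f"s{k}" for k in range(n)], name="id"),
        )
        ds = MethylomeDataset(
            beta=pd.DataFrame(
                rng.beta(5, 5, (1, n)),
                index=pd.Index(["cg1"], name="cpg"), columns=meta.index,
            ),
            annotation=pd.DataFrame(
                {"chrom": ["1"], "pos_bp": [5], "island": [0], "gene": ["g"]},
                index=pd.Index(["cg1"], name="cpg"),
            ),
            metadata=meta,
        )
        tbl = run_ewas(ds)
        assert tbl["q"].iloc[0] == pytest.approx(tbl["p"].iloc[0])

    def test_sex_stratified_male_excess(self, default_dataset):
        """Male relatedness effects are magnified, so the male-stratified
        run finds more significant CpGs than the female run."""
        _, ds = default_dataset
        tm = run_ewas(ds, sex_subset="M")
        tf = run_ewas(ds, sex_subset="F")
        assert (tm["q"] < 0.1).sum() > (tf["q"] < 0.1).sum()

    def test_missingness_respected(self, default_dataset, default_ewas):
        _, ds = default_dataset
        has_nan = ds.beta.isna().sum(axis=1)
        some = has_nan[has_nan > 0].index[0]
        assert default_ewas.loc[some, "n_used"] == 96 - has_nan[some]


class TestSummaries:
    def test_direction_counts_recover_hyper_bias(self, default_dataset,
                                                 default_ewas):
        _, ds = default_dataset
        counts = direction_counts(default_ewas, q_thresh=0.1)
        hyper, hypo = counts["all"]["hyper"], counts["all"]["hypo"]
        frac = hyper / (hyper + hypo)
        assert abs(frac - 0.8) <= 3 * np.sqrt(0.8 * 0.2 / (hyper + hypo))

    def test_direction_counts_empty(self, default_ewas):
        tight = default_ewas.copy()
        tight["q"] = 1.0
        counts = direction_counts(tight, q_thresh=0.1)
        assert counts["all"]["hyper"] == 0 and counts["all"]["hypo"] == 0

    def test_island_fraction_all_islands(self, default_ewas, default_dataset):
        _, ds = default_dataset
        ann = ds.annotation.copy()
        ann["island"] = 1
        res = island_fraction(default_ewas, ann, q_thresh=0.1)
        assert res["sig_outside_fraction"] == 0.0

    def test_island_fraction_everything_significant(self, default_ewas,
                                                    default_dataset):
        _, ds = default_dataset
        all_sig = default_ewas.copy()
        all_sig["q"] = 0.0
        res = island_fraction(all_sig, ds.annotation, q_thresh=0.1)
        assert res["sig_outside_fraction"] == pytest.approx(
            res["background_outside_fraction"]
        )
        assert res["fisher_p"] == pytest.approx(1.0)

    def test_island_fraction_no_significant_flagged(self, default_ewas,
                                                    default_dataset):
        _, ds = default_dataset
        none_sig = default_ewas.copy()
        none_sig["q"] = 1.0
        res = island_fraction(none_sig, ds.annotation, q_thresh=0.1)
        assert not res["defined"] and np.isnan(res["sig_outside_fraction"])
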