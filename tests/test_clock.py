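"""Surrogate clock, corrected age, EAA, and the relatedness regression."""

import numpy as np
import pytest
from scipy import stats

from kinmethyl import (
    compute_eaa, corrected_age, lifespan_relatedness_correlation,
    regress_eaa_on_relatedness, train_clock,
)
from kinmethyl.clock import age_table
from kinmethyl.simulate import simulate_eaa_scenario


class TestCorrectedAge:
    def test_equal_means_leave_ages_unchanged(self):
        dnam = np.array([5.0, 10.0, 15.0])
        assert np.allclose(corrected_age(dnam, dnam[::-1]), dnam)

    def test_rescaling_by_mean_ratio(self):
        # mean chron 30, mean dnam 15 -> ratio 2
        out = corrected_age([10.0, 20.0], [25.0, 35.0])
        assert np.allclose(out, [20.0, 40.0])

    def test_single_sample_matches_chronological(self):
        assert corrected_age([7.0], [12.0])[0] == pytest.approx(12.0)

    def test_corrected_mean_equals_chronological_mean(self):
        rng = np.random.default_rng(0)
        dnam = rng.uniform(1, 30, 50)
        chron = rng.uniform(1, 33, 50)
        assert corrected_age(dnam, chron).mean() == pytest.approx(chron.mean())

    def test_zero_mean_dnam_error(self):
        with pytest.raises(ValueError):
            corrected_age([0.0, 0.0], [5.0, 6.0])


class TestComputeEaa:
    def test_exact_linear_dnam_gives_zero_eaa(self):
        rng = np.random.default_rng(1)
        chron = rng.uniform(1, 33, 30)
        sex = np.where(rng.random(30) < 0.5, "M", "F")
        male = (sex == "M").astype(float)
        dnam = 3.0 + 0.9 * chron - 1.2 * male
        assert np.allclose(compute_eaa(dnam, chron, sex), 0.0, atol=1e-10)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(2)
        chron = rng.uniform(1, 33, 40)
        sex = np.where(rng.random(40) < 0.5, "M", "F")
        dnam = chron + rng.normal(0, 3, 40)
        eaa = compute_eaa(dnam, chron, sex)
        male = (sex == "M").astype(float)
        assert abs(eaa.sum()) < 1e-8
        assert abs(eaa @ chron) < 1e-7
        assert abs(eaa @ male) < 1e-8

    def test_constant_shift_invariance(self):
        rng = np.random.default_rng(3)
        chron = rng.uniform(1, 33, 25)
        sex = np.where(rng.random(25) < 0.5, "M", "F")
        dnam = chron + rng.normal(0, 2, 25)
        assert np.allclose(
            compute_eaa(dnam, chron, sex),
            compute_eaa(dnam + 100.0, chron, sex),
        )

    def test_collinear_design_error(self):
        with pytest.raises(ValueError):
            compute_eaa([1, 2, 3, 4.0], [5, 5, 5, 5.0], ["F", "F", "F", "F"])

    def test_planted_subgroup_shift_recovered(self):
        rng = np.random.default_rng(4)
        n = 200
        chron = rng.uniform(1, 33, n)
        sex = np.where(rng.random(n) < 0.5, "M", "F")
        group = rng.random(n) < 0.5  # independent of age and sex
        dnam = chron + 2.0 * group + rng.normal(0, 0.5, n)
        eaa = compute_eaa(dnam, chron, sex)
        assert eaa[group].mean() - eaa[~group].mean() == pytest.approx(
            2.0, abs=0.3
        )


class TestTrainClock:
    def test_out_of_fold_accuracy_on_planted_clock(self, default_dataset):
        _, ds = default_dataset
        clock = train_clock(ds, seed=0)
        assert clock.cv_summary["oof_pearson_r"] >= 0.9
        assert clock.cv_summary["n_nonzero"] > 0

    def test_seed_determinism(self, default_dataset):
        _, ds = default_dataset
        c1 = train_clock(ds, seed=3)
        c2 = train_clock(ds, seed=3)
        assert np.array_equal(c1.coefficients, c2.coefficients)

    def test_degenerate_and_invalid_inputs(self, default_dataset):
        _, ds = default_dataset
        flat = ds.metadata.copy()
        flat["age_months"] = 10.0

        class Flat:
            beta = ds.beta
            metadata = flat

        with pytest.raises(ValueError, match="degenerate"):
            train_clock(Flat())
        with pytest.raises(ValueError, match="folds"):
            train_clock(ds, folds=1000)

    def test_age_table_columns_consistent(self, default_dataset):
        _, ds = default_dataset
        clock = train_clock(ds, seed=0)
        ages = age_table(ds, clock=clock)
        assert np.allclose(
            ages["residual_age"], ages["corrected_age"] - ages["chron_age"]
        )
        assert ages["corrected_age"].mean() == pytest.approx(
            ages["chron_age"].mean()
        )


class TestLifespanCorrelation:
    def test_external_lifespan_column_correlated(self):
        import pandas as pd

        rng = np.random.default_rng(6)
        rel = rng.gamma(2, 8, 60)
        meta = pd.DataFrame(
            {
                "relatedness": rel,
                "predicted_lifespan": 30 + 0.1 * rel + rng.normal(0, 1, 60),
            }
        )
        out = lifespan_relatedness_correlation(meta)
        assert out["n"] == 60 and out["r"] > 0 and out["p"] < 0.05

    def test_absent_column_returns_none(self):
        import pandas as pd

        assert lifespan_relatedness_correlation(
            pd.DataFrame({"relatedness": [1.0, 2.0, 3.0]})
        ) is None


class TestEaaRegression:
    def test_planted_slope_recovered_by_all_estimators(self):
        df = simulate_eaa_scenario(n=96, slope=-0.0015, seed=12)
        rep = regress_eaa_on_relatedness(
            df["eaa"], df["relatedness"], age=df["age_months"], sex=df["sex"]
        )
        for beta, se in [
            (rep.beta_ols, rep.se_ols),
            (rep.beta_hc3, rep.se_hc3),
            (rep.beta_robust, rep.se_robust),
        ]:
            assert abs(beta - (-0.0015)) <= 2 * se
        assert np.sign(rep.beta_hc3) == np.sign(rep.beta_ols)

    def test_partial_r2_matches_double_residualization_oracle(self):
        df = simulate_eaa_scenario(n=96, slope=-0.002, seed=5)
        rep = regress_eaa_on_relatedness(
            df["eaa"], df["relatedness"], age=df["age_months"], sex=df["sex"]
        )
        Z = np.column_stack(
            [np.ones(96), df["age_months"],
             (df["sex"] == "M").astype(float)]
        )
        ry = df["eaa"].to_numpy() - Z @ np.linalg.lstsq(Z, df["eaa"], rcond=None)[0]
        rt = df["relatedness"].to_numpy() - Z @ np.linalg.lstsq(
            Z, df["relatedness"], rcond=None
        )[0]
        assert rep.partial_r2 == pytest.approx(
            stats.pearsonr(ry, rt)[0] ** 2, rel=1e-9
        )

    def test_added_variable_slope_equals_multivariate_ols(self):
        df = simulate_eaa_scenario(n=60, slope=-0.001, seed=9)
        rep = regress_eaa_on_relatedness(
            df["eaa"], df["relatedness"], age=df["age_months"], sex=df["sex"]
        )
        av = rep.added_variable
        slope = np.polyfit(
            av["relatedness_residual"], av["eaa_residual"], 1
        )[0]
        assert slope == pytest.approx(rep.beta_ols, rel=1e-6)

    def test_outlier_moves_robust_estimate_less_than_ols(self):
        df = simulate_eaa_scenario(n=96, slope=-0.0015, seed=3)
        base = regress_eaa_on_relatedness(df["eaa"], df["relatedness"])
        spiked = df.copy()
        spiked.loc[spiked.index[0], "eaa"] += 1.5  # gross outlier
        pert = regress_eaa_on_relatedness(spiked["eaa"], spiked["relatedness"])
        assert abs(pert.beta_robust - base.beta_robust) < abs(
            pert.beta_ols - base.beta_ols
        )

    def test_jackknife_shape_and_median_in_ols_ci(self):
        df = simulate_eaa_scenario(n=96, slope=-0.0015, seed=21)
        rep = regress_eaa_on_relatedness(
            df["eaa"], df["relatedness"], age=df["age_months"], sex=df["sex"]
        )
        assert len(rep.jackknife_betas) == 96
        lo = rep.beta_ols - 1.96 * rep.se_ols
        hi = rep.beta_ols + 1.96 * rep.se_ols
        assert lo <= rep.jackknife_median <= hi

    def test_input_validation(self):
        df = simulate_eaa_scenario(n=96, seed=0)
        with pytest.raises(ValueError):
            regress_eaa_on_relatedness(df["eaa"][:5], df["relatedness"][:5])
        with pytest.raises(ValueError):
            regress_eaa_on_relatedness(df["eaa"], np.zeros(96))
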