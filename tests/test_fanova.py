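"""Functional ANOVA estimation, permutation test, bootstrap bands, summaries."""

import numpy as np
import pandas as pd
import pytest

from fanova_activity.fanova import (
    DesignError,
    DesignSpec,
    Factor,
    bootstrap_ci,
    build_design,
    fit_fanova,
    functional_mean,
    permutation_F_test,
    pointwise_F,
    report_tables,
    window_average,
)
from fanova_activity.simulate import EffectSpec, SimulationConfig, simulate_minute_profiles
from fanova_activity.smoothing import build_basis, smooth_dataset
from fanova_activity.timegrid import MINUTE_GRID

SEX_SPEC = DesignSpec.from_refs({"sex": "Male"})
BOTH_SPEC = DesignSpec.from_refs({"sex": "Male", "transport": "Active"})


@pytest.fixture(scope="module")
def smoothed_cohort(small_cohort):
    Y, cov, truth = small_cohort
    return smooth_dataset(Y, 25, child_ids=cov["child_id"].tolist()), cov, truth


class TestDesign:
    def test_one_covariate_three_levels(self):
        cov = pd.DataFrame({"child_id": list("wxyz"), "grp": ["A", "B", "C", "A"]})
        X, labels = build_design(cov, DesignSpec((Factor("grp", "A"),)))
        assert X.shape == (4, 3)
        assert labels == ["intercept", "grp=B", "grp=C"]

    def test_two_covariates_column_count(self):
        cov = pd.DataFrame(
            {
                "child_id": [str(i) for i in range(8)],
                "a": ["x", "y"] * 4,
                "b": ["p", "q", "r", "s"] * 2,
            }
        )
        X, labels = build_design(cov, DesignSpec((Factor("a", "x"), Factor("b", "p"))))
        assert X.shape[1] == 1 + 1 + 3 and len(labels) == 5

    def test_unseen_level_names_child_and_covariate(self):
        cov = pd.DataFrame({"child_id": ["c7"], "grp": ["D"]})
        with pytest.raises(DesignError, match="'D'.*'grp'.*c7"):
            build_design(cov, DesignSpec((Factor("grp", "A", levels=("A", "B")),)))


class TestFit:
    def test_intercept_only_equals_mean(self, smoothed_cohort):
        sm, cov, _ = smoothed_cohort
        X = np.ones((sm.n, 1))
        fit = fit_fanova(sm, X, ["intercept"])
        assert np.allclose(fit.coefficients[0], sm.coefficients.mean(axis=0))
        assert np.allclose(fit.coefficients[0], functional_mean(sm))

    def test_decomposition_identity(self, smoothed_cohort):
        sm, cov, _ = smoothed_cohort
        X, labels = build_design(cov, BOTH_SPEC)
        fit = fit_fanova(sm, X, labels, cov["weight"].to_numpy())
        recon = X @ fit.coefficients + fit.residuals
        assert np.max(np.abs(recon - sm.coefficients)) < 1e-10 * np.abs(sm.coefficients).max()

    def test_weighted_normal_equations_vanish(self, smoothed_cohort):
        sm, cov, _ = smoothed_cohort
        X, labels = build_design(cov, BOTH_SPEC)
        w = cov["weight"].to_numpy()
        fit = fit_fanova(sm, X, labels, w)
        score = (X * w[:, None]).T @ fit.residuals
        assert np.max(np.abs(score)) < 1e-8 * np.abs(sm.coefficients).max()

    def test_equals_pointwise_weighted_ols(self, smoothed_cohort):
        sm, cov, _ = smoothed_cohort
        X, labels = build_design(cov, BOTH_SPEC)
        w = cov["weight"].to_numpy()
        fit = fit_fanova(sm, X, labels, w)
        Phi = sm.basis.evaluate(MINUTE_GRID)
        curves = fit.coefficients @ Phi.T  # (p, 660) via basis-coefficient regression
        Yhat = sm.coefficients @ Phi.T  # smoothed curves on the grid
        Xw = X * w[:, None]
        pointwise = np.linalg.solve(X.T @ Xw, Xw.T @ Yhat)  # per-minute WLS
        assert np.max(np.abs(curves - pointwise)) < 1e-8

    def test_rank_deficiency_reported(self, smoothed_cohort):
        sm, cov, _ = smoothed_cohort
        X = np.ones((sm.n, 2))  # duplicated intercept
        with pytest.raises(DesignError, match="collinear"):
            fit_fanova(sm, X, ["intercept", "dup"])

    def test_constant_offset_recovery(self):
        # two groups with a constant true -70 counts/min difference
        config = SimulationConfig(
            n_children=400,
            covariates={"sex": {"Male": 0.5, "Female": 0.5}},
            effects=(EffectSpec("sex", "Female", constant=-70.0),),
            propensity_offsets={},
            dispersion=1.5,
        )
        Y, cov, _ = simulate_minute_profiles(config, seed=42)
        sm = smooth_dataset(Y, 25)
        X, labels = build_design(cov, SEX_SPEC)
        fit = fit_fanova(sm, X, labels)
        curve = fit.curve("sex=Female")
        assert np.all(np.abs(curve - (-70.0)) < 5.0)


class TestFunctionalMean:
    def test_identical_profiles_idempotent(self):
        Y = np.tile(np.full(660, 80.0), (4, 1))
        sm = smooth_dataset(Y, 10)
        mean_curve = sm.basis.evaluate(MINUTE_GRID) @ functional_mean(sm)
        assert np.allclose(mean_curve, 80.0, atol=1e-6)

    def test_weighted_average_of_two_curves(self):
        t = MINUTE_GRID
        f = 100 + 50 * np.sin((t - 510) / 100)
        g = 300 + 20 * np.cos((t - 510) / 80)
        sm = smooth_dataset(np.vstack([f, g]), 30)
        mean_coef = functional_mean(sm, np.array([2.0, 1.0]))
        expected = (2 * sm.coefficients[0] + sm.coefficients[1]) / 3
        assert np.allclose(mean_coef, expected)


class TestPointwiseF:
    def test_duplication_invariance(self, smoothed_cohort):
        sm, cov, _ = smoothed_cohort
        X, labels = build_design(cov, SEX_SPEC)
        F1 = pointwise_F(fit_fanova(sm, X, labels))
        sm2 = smooth_dataset(np.tile(sm.curves(), (2, 1)), sm.basis)
        F2 = pointwise_F(fit_fanova(sm2, np.vstack([X, X]), labels))
        assert np.allclose(F1, F2, rtol=1e-8)

    def test_constant_shift_invariance(self, smoothed_cohort):
        sm, cov, _ = smoothed_cohort
        X, labels = build_design(cov, SEX_SPEC)
        F1 = pointwise_F(fit_fanova(sm, X, labels))
        shifted = smooth_dataset(sm.curves() + 500.0, sm.basis)
        F2 = pointwise_F(fit_fanova(shifted, X, labels))
        assert np.allclose(F1, F2, rtol=1e-6)

    def test_null_F_mostly_below_parametric_quantile(self):
        from scipy.stats import f as f_dist

        config = SimulationConfig(n_children=60, effects=(), propensity_offsets={})
        ok = 0
        for seed in range(50):
            Y, cov, _ = simulate_minute_profiles(config, seed=1000 + seed)
            sm = smooth_dataset(Y, 25)
            X, labels = build_design(cov, SEX_SPEC)
            F = pointwise_F(fit_fanova(sm, X, labels))
            if np.median(F) < f_dist.ppf(0.95, 1, 58):
                ok += 1
        assert ok >= 40  # median F rarely exceeds the 95th percentile under the null


class TestPermutation:
    def test_determinism(self, smoothed_cohort):
        sm, cov, _ = smoothed_cohort
        a = permutation_F_test(sm, cov, SEX_SPEC, nperm=29, seed=5)
        b = permutation_F_test(sm, cov, SEX_SPEC, nperm=29, seed=5)
        assert a.p_value == b.p_value and np.array_equal(a.permuted, b.permuted)

    def test_p_value_bounds(self, smoothed_cohort):
        sm, cov, _ = smoothed_cohort
        res = permutation_F_test(sm, cov, SEX_SPEC, nperm=19, seed=3)
        assert 1 / 20 <= res.p_value <= 1.0

    def test_power_under_strong_effect(self):
        config = SimulationConfig(
            n_children=200,
            covariates={"sex": {"Male": 0.5, "Female": 0.5}},
            effects=(EffectSpec("sex", "Female", constant=-120.0),),
            propensity_offsets={},
        )
        hits = 0
        for seed in range(20):
            Y, cov, _ = simulate_minute_profiles(config, seed=7000 + seed)
            sm = smooth_dataset(Y, 25)
            res = permutation_F_test(sm, cov, SEX_SPEC, nperm=99, seed=seed)
            hits += res.p_value == pytest.approx(1 / 100)
        assert hits >= 19  # minimal p in at least 95% of runs


class TestBootstrap:
    def test_bands_bracket_estimate(self, smoothed_cohort):
        sm, cov, _ = smoothed_cohort
        boot = bootstrap_ci(sm, cov, SEX_SPEC, n_bootstrap=49, seed=11,
                            weights=cov["weight"].to_numpy())
        band = boot.band("sex=Female")
        assert np.all(band.lower <= band.estimate) and np.all(band.estimate <= band.upper)

    def test_single_replicate_rejected(self, smoothed_cohort):
        sm, cov, _ = smoothed_cohort
        with pytest.raises(ValueError, match="at least 2"):
            bootstrap_ci(sm, cov, SEX_SPEC, n_bootstrap=1, seed=0)

    def test_determinism(self, smoothed_cohort):
        sm, cov, _ = smoothed_cohort
        a = bootstrap_ci(sm, cov, SEX_SPEC, n_bootstrap=19, seed=2)
        b = bootstrap_ci(sm, cov, SEX_SPEC, n_bootstrap=19, seed=2)
        assert np.array_equal(a.replicates, b.replicates)


class TestWindowAverage:
    def test_constant_contrast(self):
        basis = build_basis(12)
        coef = np.full(12, -33.0)  # partition of unity: the function is -33
        assert window_average(basis, coef, (720, 810)) == pytest.approx(-33.0, abs=1e-9)

    def test_linear_contrast_equals_midpoint(self):
        basis = build_basis(12)
        Phi = basis.evaluate(MINUTE_GRID)
        target = 2.0 * (MINUTE_GRID - 510.0)  # linear, representable by cubics
        coef, *_ = np.linalg.lstsq(Phi, target, rcond=None)
        mid_value = 2.0 * ((570 + 720) / 2 - 510.0)
        assert window_average(basis, coef, (570, 720)) == pytest.approx(mid_value, abs=1e-6)

    def test_reversed_window_rejected(self):
        basis = build_basis(8)
        with pytest.raises(ValueError, match="reversed"):
            window_average(basis, np.zeros(8), (810, 720))

    def test_window_outside_domain_rejected(self):
        basis = build_basis(8)
        with pytest.raises(ValueError, match="outside"):
            window_average(basis, np.zeros(8), (400, 600))


class TestReportTables:
    def test_row_counts_and_ref_marker(self, smoothed_cohort):
        sm, cov, _ = smoothed_cohort
        X, labels = build_design(cov, BOTH_SPEC)
        fit = fit_fanova(sm, X, labels, cov["weight"].to_numpy())
        windows = {"12:00-13:30": (720, 810)}
        table, curves = report_tables(fit, None, windows, BOTH_SPEC, cov)
        assert len(table) == 4  # 2 covariates x 2 levels, references included
        ref_rows = table[table["full-day"] == "Ref"]
        assert set(ref_rows["level"]) == {"Male", "Active"}
        assert "sex=Female" in curves.columns

    def test_curve_roundtrip_reproduces_window_averages(self, smoothed_cohort):
        # re-deriving basis coefficients from the written curve grid and
        # re-averaging matches the exact spline window averages
        sm, cov, _ = smoothed_cohort
        X, labels = build_design(cov, BOTH_SPEC)
        fit = fit_fanova(sm, X, labels, cov["weight"].to_numpy())
        _, curves = report_tables(fit, None, {"12:00-13:30": (720, 810)}, BOTH_SPEC, cov)
        Phi = sm.basis.evaluate(MINUTE_GRID)
        for label in ("sex=Female", "transport=Car"):
            coef, *_ = np.linalg.lstsq(Phi, curves[label].to_numpy(), rcond=None)
            direct = window_average(sm.basis, fit.coefficients[labels.index(label)], (720, 810))
            assert window_average(sm.basis, coef, (720, 810)) == pytest.approx(direct, abs=1e-9)
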