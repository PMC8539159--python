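"""Regression machinery: OLS oracle checks, BIC selection, CV, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from kayakforce import (
    CohortSpec,
    EstimationError,
    bootstrap_ci,
    cross_validate,
    diagnostics,
    explanatory_fit,
    fit_ols,
    generate_cohort,
    pearson_matrix,
    predict_vmax,
    select_model_bic,
)

PUBLISHED_COEFS = {"peak_force_n": 0.0045, "impulse_10s_ns": 0.0017, "stroke_rate_spm": 0.05}


def published_cohort(n=25, residual_sd=0.0, seed=0):
    return generate_cohort(
        CohortSpec(n_paddlers=n, coefficients=PUBLISHED_COEFS, intercept=7.62,
                   residual_sd=residual_sd, seed=seed)
    )


class TestPearsonMatrix:
    def test_unit_diagonal_and_symmetry(self):
        df = published_cohort(n=50, residual_sd=0.5, seed=1)
        cm = pearson_matrix(df, ["velocity_kmh", "peak_force_n", "stroke_rate_spm"])
        r = cm.r.to_numpy()
        np.testing.assert_allclose(np.diag(r), 1.0)
        np.testing.assert_allclose(r, r.T)
        assert np.all(np.abs(r) <= 1.0)

    def test_bivariate_normal_correlation_recovered(self):
        rng = np.random.default_rng(2)
        rho, n = 0.827, 10_000
        z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
        df = pd.DataFrame({"a": z[:, 0], "b": z[:, 1]})
        cm = pearson_matrix(df, ["a", "b"])
        assert cm.r.loc["a", "b"] == pytest.approx(rho, abs=0.02)
        assert cm.p.loc["a", "b"] < 0.01

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"a": rng.normal(size=10_000),
                           "b": rng.normal(size=10_000)})
        cm = pearson_matrix(df, ["a", "b"])
        assert abs(cm.r.loc["a", "b"]) < 0.05

    def test_zero_variance_flagged_not_zeroed(self):
        df = pd.DataFrame({"a": np.arange(10.0), "b": np.ones(10)})
        cm = pearson_matrix(df, ["a", "b"])
        assert cm.degenerate == ["b"]
        assert np.isnan(cm.r.loc["a", "b"])


class TestFitOls:
    def test_noiseless_published_coefficients_recovery(self):
        fit = fit_ols(published_cohort(), "velocity_kmh", list(PUBLISHED_COEFS))
        for name, coef in PUBLISHED_COEFS.items():
            assert fit.coefficients[name] == pytest.approx(coef, rel=1e-6)
        assert fit.intercept == pytest.approx(7.62, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0)

    def test_agrees_with_normal_equations_oracle(self):
        rng = np.random.default_rng(10)
        for trial in range(10):
            n, p = int(rng.integers(8, 21)), int(rng.integers(1, 4))
            X = rng.normal(size=(n, p))
            beta = rng.normal(size=p + 1)
            y = beta[0] + X @ beta[1:] + rng.normal(0, 0.5, size=n)
            df = pd.DataFrame(X, columns=[f"x{j}" for j in range(p)])
            df["y"] = y
            fit = fit_ols(df, "y", [f"x{j}" for j in range(p)])
            A = np.column_stack([np.ones(n), X])
            oracle = np.linalg.solve(A.T @ A, A.T @ y)
            assert fit.intercept == pytest.approx(oracle[0], abs=1e-8)
            for j in range(p):
                assert fit.coefficients[f"x{j}"] == pytest.approx(
                    oracle[j + 1], abs=1e-8
                )

    def test_prediction_at_means_equals_response_mean(self):
        df = published_cohort(n=40, residual_sd=1.0, seed=5)
        fit = fit_ols(df, "velocity_kmh", list(PUBLISHED_COEFS))
        at_means = fit.intercept + sum(
            coef * df[name].mean() for name, coef in fit.coefficients.items()
        )
        assert at_means == pytest.approx(df["velocity_kmh"].mean(), abs=1e-8)

    def test_residuals_sum_to_zero(self):
        df = published_cohort(n=40, residual_sd=1.0, seed=6)
        fit = fit_ols(df, "velocity_kmh", list(PUBLISHED_COEFS))
        assert abs(np.sum(fit.residuals)) < 1e-8 * np.abs(
            df["velocity_kmh"]
        ).sum()
        assert fit.adj_r_squared <= fit.r_squared <= 1.0

    def test_constant_response_convention(self):
        df = pd.DataFrame({"x": np.arange(10.0), "y": np.full(10, 3.0)})
        fit = fit_ols(df, "y", ["x"])
        assert fit.coefficients["x"] == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(3.0)
        assert fit.r_squared == 0.0

    def test_rank_deficiency_names_columns(self):
        df = published_cohort(n=30, residual_sd=0.5, seed=7)
        df["dup"] = df["peak_force_n"]
        with pytest.raises(EstimationError, match="dup|peak_force_n"):
            fit_ols(df, "velocity_kmh", ["peak_force_n", "dup"])

    def test_normal_theory_ci_coverage(self):
        """95% CIs for a slope cover the truth in roughly 95 of 100 replicates."""
        covered = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=50)
            y = 2.0 + 1.5 * x + rng.normal(0, 1.0, size=50)
            fit = fit_ols(pd.DataFrame({"x": x, "y": y}), "y", ["x"])
            lo, hi = fit.conf_int["x"]
            covered += lo <= 1.5 <= hi
        assert 88 <= covered <= 100


class TestSelectModelBic:
    def test_single_candidate_used(self):
        df = published_cohort(n=30, residual_sd=0.3, seed=8)
        fit = select_model_bic(df, "velocity_kmh", ["peak_force_n"])
        assert fit.predictors == ["peak_force_n"]

    def test_excludes_pure_noise_predictor(self):
        """The noise candidate is dropped in >=95 of 100 replicates."""
        excluded = 0
        for seed in range(100):
            df = published_cohort(n=200, residual_sd=0.1, seed=seed)
            rng = np.random.default_rng(10_000 + seed)
            df["noise"] = rng.normal(size=len(df))
            fit = select_model_bic(df, "velocity_kmh", [*PUBLISHED_COEFS, "noise"])
            excluded += "noise" not in fit.predictors
        assert excluded >= 95

    def test_agrees_with_independent_bic_enumeration(self):
        """Exhaustive search matches a hand-coded subset/BIC enumeration."""
        import itertools

        df = published_cohort(n=60, residual_sd=0.5, seed=9)
        cands = list(PUBLISHED_COEFS)
        best, best_key = None, None
        n = len(df)
        for size in range(1, len(cands) + 1):
            for subset in itertools.combinations(sorted(cands), size):
                A = np.column_stack(
                    [np.ones(n)] + [df[c].to_numpy() for c in subset]
                )
                y = df["velocity_kmh"].to_numpy()
                beta, *_ = np.linalg.lstsq(A, y, rcond=None)
                rss = float(np.sum((y - A @ beta) ** 2))
                bic = n * np.log(rss / n) + (size + 1) * np.log(n)
                key = (bic, size, subset)
                if best_key is None or key < best_key:
                    best_key, best = key, subset
        fit = select_model_bic(df, "velocity_kmh", cands)
        assert tuple(sorted(fit.predictors)) == tuple(sorted(best))
        assert fit.bic == pytest.approx(best_key[0], rel=1e-9)

    def test_duplicated_candidates_skip_degenerate_subsets(self):
        df = published_cohort(n=40, residual_sd=0.3, seed=11)
        df["dup"] = df["peak_force_n"]
        fit = select_model_bic(df, "velocity_kmh", ["peak_force_n", "dup"])
        assert len(fit.predictors) == 1


class TestPredictVmax:
    def test_maximal_effort_group_means(self):
        v = predict_vmax(
            {"peak_force_n": 398.2, "impulse_10s_ns": 2383.6,
             "stroke_rate_spm": 125.0}
        )
        assert v == pytest.approx(19.714, abs=1e-3)
        assert round(v, 1) == 19.7

    def test_intercept_only(self):
        v = predict_vmax({"peak_force_n": 0, "impulse_10s_ns": 0,
                          "stroke_rate_spm": 0})
        assert v == pytest.approx(7.62)

    def test_stroke_rate_contribution(self):
        v = predict_vmax({"peak_force_n": 0, "impulse_10s_ns": 0,
                          "stroke_rate_spm": 100})
        assert v == pytest.approx(12.62)

    def test_missing_predictor_named(self):
        with pytest.raises(ValueError, match="impulse_10s_ns"):
            predict_vmax({"peak_force_n": 400.0, "stroke_rate_spm": 120.0})

    def test_unknown_builtin_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            predict_vmax({}, model="nope")

    def test_fitted_model_usable(self):
        df = published_cohort(n=50, residual_sd=0.0, seed=12)
        fit = fit_ols(df, "velocity_kmh", list(PUBLISHED_COEFS))
        rec = {"peak_force_n": 398.2, "impulse_10s_ns": 2383.6,
               "stroke_rate_spm": 125.0}
        assert predict_vmax(rec, fit) == pytest.approx(19.714, abs=1e-3)


class TestCrossValidate:
    def test_noiseless_cohort_zero_error(self):
        df = published_cohort(n=50, residual_sd=0.0, seed=13)
        cv = cross_validate(df, "velocity_kmh", list(PUBLISHED_COEFS), seed=0)
        assert cv.prediction_sd < 1e-6

    def test_error_sd_estimates_residual_sd(self):
        df = published_cohort(n=200, residual_sd=1.0, seed=14)
        cv = cross_validate(df, "velocity_kmh", list(PUBLISHED_COEFS), seed=0)
        assert cv.prediction_sd == pytest.approx(1.0, abs=0.15)

    def test_folds_partition_evenly(self):
        df = published_cohort(n=52, residual_sd=0.5, seed=15)
        cv = cross_validate(df, "velocity_kmh", list(PUBLISHED_COEFS), k=5, seed=3)
        sizes = np.bincount(cv.fold_assignment)
        assert len(sizes) == 5 and sizes.max() - sizes.min() <= 1

    def test_seed_determinism(self):
        df = published_cohort(n=60, residual_sd=0.5, seed=16)
        a = cross_validate(df, "velocity_kmh", list(PUBLISHED_COEFS), seed=9)
        b = cross_validate(df, "velocity_kmh", list(PUBLISHED_COEFS), seed=9)
        np.testing.assert_array_equal(a.fold_assignment, b.fold_assignment)
        np.testing.assert_array_equal(a.predicted, b.predicted)

    def test_loo_mode(self):
        df = published_cohort(n=20, residual_sd=0.5, seed=17)
        cv = cross_validate(df, "velocity_kmh", list(PUBLISHED_COEFS), loo=True)
        assert cv.k == 20 and len(np.unique(cv.fold_assignment)) == 20

    def test_too_small_sample_rejected(self):
        df = published_cohort(n=8, residual_sd=0.5, seed=18)
        with pytest.raises(ValueError, match="n >= 2k"):
            cross_validate(df, "velocity_kmh", ["peak_force_n"], k=5)


class TestExplanatoryFit:
    def test_mean_force_slope_recovered(self):
        df = generate_cohort(
            CohortSpec(n_paddlers=10_000, direction="feature_on_velocity",
                       coefficients={"mean_force_n": 14.13}, intercept=60.0,
                       residual_sd=0.5, seed=19)
        )
        fit = explanatory_fit(df, "mean_force_n")
        assert fit.coefficients["velocity_kmh"] == pytest.approx(14.13, rel=0.01)

    def test_velocity_independent_feature_ci_covers_zero(self):
        df = generate_cohort(
            CohortSpec(n_paddlers=200, direction="feature_on_velocity",
                       coefficients={"mean_force_n": 0.0}, intercept=200.0,
                       residual_sd=10.0, seed=20)
        )
        fit = explanatory_fit(df, "mean_force_n")
        lo, hi = fit.conf_int["velocity_kmh"]
        assert lo <= 0.0 <= hi

    def test_group_offsets_leave_adjusted_slope_unchanged(self):
        df = generate_cohort(
            CohortSpec(n_paddlers=2000, direction="feature_on_velocity",
                       coefficients={"mean_force_n": 14.13}, intercept=60.0,
                       residual_sd=2.0, seed=21,
                       group_offsets={"girls U16": -30.0, "boys U18": 0.0,
                                      "senior women": -10.0, "senior men": 20.0})
        )
        uni = explanatory_fit(df, "mean_force_n", adjusted=False)
        adj = explanatory_fit(df, "mean_force_n", adjusted=True)
        assert adj.coefficients["velocity_kmh"] == pytest.approx(
            uni.coefficients["velocity_kmh"], abs=0.5
        )
        assert adj.coefficients["velocity_kmh"] == pytest.approx(14.13, rel=0.02)

    def test_single_group_degenerates_to_univariate(self):
        df = generate_cohort(
            CohortSpec(n_paddlers=100, direction="feature_on_velocity",
                       coefficients={"mean_force_n": 10.0}, intercept=50.0,
                       residual_sd=1.0, seed=22,
                       group_offsets={"senior men": 0.0})
        )
        fit = explanatory_fit(df, "mean_force_n", adjusted=True)
        assert fit.predictors == ["velocity_kmh"]


class TestBootstrapCi:
    def test_noiseless_cohort_degenerate_interval(self):
        df = published_cohort(n=40, residual_sd=0.0, seed=23)
        ci = bootstrap_ci(df, "velocity_kmh", list(PUBLISHED_COEFS), n_reps=100, seed=0)
        for lo, hi in ci.values():
            assert hi - lo < 1e-6

    def test_seed_determinism(self):
        df = published_cohort(n=40, residual_sd=0.5, seed=24)
        a = bootstrap_ci(df, "velocity_kmh", list(PUBLISHED_COEFS), n_reps=200, seed=5)
        b = bootstrap_ci(df, "velocity_kmh", list(PUBLISHED_COEFS), n_reps=200, seed=5)
        assert a == b

    def test_slope_coverage(self):
        """Bootstrap percentile CIs cover the true slope ~95% of the time."""
        covered = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=100)
            y = 2.0 + 1.5 * x + rng.normal(0, 1.0, size=100)
            ci = bootstrap_ci(pd.DataFrame({"x": x, "y": y}), "y", ["x"],
                              n_reps=400, seed=seed)
            lo, hi = ci["x"]
            covered += lo <= 1.5 <= hi
        assert 85 <= covered <= 100

    def test_small_sample_rejected(self):
        df = published_cohort(n=6, residual_sd=0.5, seed=25)
        with pytest.raises(ValueError, match="n >= 10"):
            bootstrap_ci(df, "velocity_kmh", ["peak_force_n"])


class TestDiagnostics:
    def test_balanced_duplicated_design_equal_leverage(self):
        x = np.tile(np.array([1.0, 2.0, 3.0, 4.0]), 5)
        rng = np.random.default_rng(26)
        df = pd.DataFrame({"x": x, "y": 2 * x + rng.normal(0, 0.1, len(x))})
        fit = fit_ols(df, "y", ["x"])
        lev = diagnostics(fit)["leverage"].to_numpy()
        groups = {v: lev[x == v] for v in np.unique(x)}
        for vals in groups.values():
            np.testing.assert_allclose(vals, vals[0])

    def test_gross_outlier_maximizes_cooks_distance(self):
        rng = np.random.default_rng(27)
        x = rng.normal(size=50)
        y = 2.0 + 1.5 * x + rng.normal(0, 0.2, size=50)
        x[0], y[0] = 6.0, -20.0  # far point, far off the line
        fit = fit_ols(pd.DataFrame({"x": x, "y": y}), "y", ["x"])
        assert int(np.argmax(fit.cooks_distance)) == 0

    def test_qq_table_is_monotone(self):
        df = published_cohort(n=40, residual_sd=0.5, seed=28)
        fit = fit_ols(df, "velocity_kmh", list(PUBLISHED_COEFS))
        qq = diagnostics(fit)["qq"]
        assert np.all(np.diff(qq["theoretical_quantile"]) >= 0)
        assert np.all(np.diff(qq["ordered_residual"]) >= 0)

    def test_per_paddler_residuals_present(self):
        df = published_cohort(n=40, residual_sd=0.5, seed=29)
        fit = fit_ols(df, "velocity_kmh", list(PUBLISHED_COEFS))
        diag = diagnostics(fit)
        assert "by_paddler" in diag
        assert len(diag["by_paddler"]) == fit.n_obs
        assert abs(diag["residual_vs_fitted"]["residual"].sum()) < 1e-8
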