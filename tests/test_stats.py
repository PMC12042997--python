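"""Regression, dominance analysis, LOOCV, paired t, reliability."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cheechlab.simulate import PREDICTOR_NAMES, CohortSpec, generate_cohort
from cheechlab.stats import (
    diagnostics,
    dominance_analysis,
    fit_ols,
    loocv_rmse,
    paired_t,
    paired_t_from_summary,
    reliability,
    zscore,
)


def normal_equations_oracle(X, y):
    """Closed-form OLS with SEs, independent of the fitting route."""
    A = np.column_stack([np.ones(len(y)), X])
    xtx_inv = np.linalg.inv(A.T @ A)
    beta = xtx_inv @ A.T @ y
    resid = y - A @ beta
    sigma2 = resid @ resid / (len(y) - A.shape[1])
    se = np.sqrt(np.diag(sigma2 * xtx_inv))
    return beta, se


class TestFitOls:
    def test_identity_regression(self):
        x = np.arange(10.0)
        fit = fit_ols(x, x, standardize=False)
        assert fit.coef[0] == pytest.approx(1.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.standard_normal((30, 3))
        y = X @ [0.5, -1.0, 0.2] + rng.standard_normal(30)
        fit = fit_ols(X, y, standardize=False)
        beta, se = normal_equations_oracle(X, y)
        np.testing.assert_allclose(fit.coef, beta[1:], atol=1e-10)
        np.testing.assert_allclose(fit.se, se[1:], atol=1e-10)

    def test_adjusted_r2_identity(self, rng):
        X = rng.standard_normal((24, 5))
        y = rng.standard_normal(24)
        fit = fit_ols(X, y)
        n, p = 24, 5
        assert fit.adj_r2 == pytest.approx(1 - (1 - fit.r2) * (n - 1) / (n - p - 1), abs=1e-12)

    def test_standardized_intercept_is_zero(self, rng):
        X = rng.standard_normal((20, 3)) * 5 + 2
        y = rng.standard_normal(20) * 3 - 1
        fit = fit_ols(X, y, standardize=True)
        assert abs(fit.intercept) < 1e-12

    def test_rank_deficiency_names_columns(self):
        X = pd.DataFrame({"a": np.arange(10.0), "b": 2 * np.arange(10.0)})
        with pytest.raises(ValueError, match="rank deficient"):
            fit_ols(X, np.arange(10.0))

    def test_type_one_error_rate_under_null(self):
        """With all-zero generating betas, per-coefficient tests at α = 0.05
        reject at the nominal rate."""
        spec = CohortSpec(betas=np.zeros(5), residual_sd=1.0)
        hits = total = 0
        for seed in range(1500):
            spec.seed = seed
            cohort = generate_cohort(spec)
            fit = fit_ols(cohort[list(PREDICTOR_NAMES)], cohort["true_n1_diff_uv"])
            hits += int((fit.pvalues < 0.05).sum())
            total += 5
        assert hits / total == pytest.approx(0.05, abs=0.01)


class TestDiagnostics:
    def test_orthogonal_predictors_have_unit_vif(self):
        n = 32
        X = np.column_stack(
            [np.tile([1, -1], n // 2), np.repeat([1, -1], n // 2)]
        ).astype(float)
        y = X @ [1.0, 2.0] + 0.1 * np.sin(np.arange(n))
        rep = diagnostics(fit_ols(X, y), X)
        for v in rep.vif.values():
            assert v == pytest.approx(1.0, abs=1e-9)

    def test_correlated_pair_vif_closed_form(self, rng):
        n = 100_000
        z = rng.standard_normal((n, 2))
        x1 = z[:, 0]
        x2 = 0.9 * z[:, 0] + np.sqrt(1 - 0.81) * z[:, 1]
        X = np.column_stack([x1, x2])
        y = x1 + x2 + rng.standard_normal(n)
        rep = diagnostics(fit_ols(X, y), X)
        for v in rep.vif.values():
            assert v == pytest.approx(1 / (1 - 0.81), rel=0.02)

    def test_planted_outlier_flagged_by_cooks_distance(self, rng):
        n = 30
        x = np.linspace(0, 1, n)
        y = 2 * x + 0.01 * rng.standard_normal(n)
        y[-1] += 5.0
        fit = fit_ols(x, y, standardize=False)
        rep = diagnostics(fit, x)
        assert rep.flagged_observations == [n - 1]

    def test_cooks_distance_matches_leave_one_out_refit_oracle(self, rng):
        X = rng.standard_normal((20, 2))
        y = X @ [1.0, -0.5] + rng.standard_normal(20)
        fit = fit_ols(X, y, standardize=False)
        rep = diagnostics(fit, X)
        A = np.column_stack([np.ones(20), X])
        full, *_ = np.linalg.lstsq(A, y, rcond=None)
        yhat = A @ full
        p = A.shape[1]
        s2 = np.sum((y - yhat) ** 2) / (20 - p)
        for i in range(20):
            mask = np.ones(20, dtype=bool)
            mask[i] = False
            sub, *_ = np.linalg.lstsq(A[mask], y[mask], rcond=None)
            d_oracle = np.sum((yhat - A @ sub) ** 2) / (p * s2)
            assert rep.cooks_distance[i] == pytest.approx(d_oracle, rel=1e-6)


def dominance_oracle(X, y):
    """Independent subset-enumeration dominance analysis (pinv-based)."""
    p = X.shape[1]

    def r2(cols):
        if not cols:
            return 0.0
        A = np.column_stack([np.ones(len(y)), X[:, list(cols)]])
        yhat = A @ np.linalg.pinv(A) @ y
        return 1 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2)

    gdw = []
    for j in range(p):
        others = [k for k in range(p) if k != j]
        by_size = {s: [] for s in range(p)}
        for size in range(p):
            for S in itertools.combinations(others, size):
                by_size[size].append(r2(set(S) | {j}) - r2(S))
        gdw.append(np.mean([np.mean(v) for v in by_size.values()]))
    return np.array(gdw)


class TestDominance:
    def test_single_predictor_gdw_is_simple_r2(self, rng):
        x = rng.standard_normal(50)
        y = 0.8 * x + rng.standard_normal(50)
        res = dominance_analysis(x, y)
        fit = fit_ols(x, y, standardize=False)
        assert res.gdw["x0"] == pytest.approx(fit.r2, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        X = rng.standard_normal((40, 3))
        y = X @ [1.0, 0.3, -0.4] + rng.standard_normal(40)
        res = dominance_analysis(X, y)
        oracle = dominance_oracle(X, y)
        np.testing.assert_allclose(list(res.gdw.values()), oracle, atol=1e-12)

    def test_gdw_sum_equals_full_r2(self, rng):
        for _ in range(10):
            p = rng.integers(1, 6)
            X = rng.standard_normal((30, p))
            y = rng.standard_normal(30)
            res = dominance_analysis(X, y)
            assert sum(res.gdw.values()) == pytest.approx(res.full_r2, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 5))
    def test_gdw_sum_identity_property(self, seed, p):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((25, p))
        y = rng.standard_normal(25)
        res = dominance_analysis(X, y)
        assert sum(res.gdw.values()) == pytest.approx(res.full_r2, abs=1e-10)

    def test_too_many_predictors_rejected(self, rng):
        with pytest.raises(ValueError, match="limit"):
            dominance_analysis(rng.standard_normal((20, 16)), rng.standard_normal(20))


class TestLoocv:
    def test_exact_linear_data_zero_rmse(self):
        X = np.arange(20.0)[:, None]
        y = 3.0 * X[:, 0] + 1.0
        assert loocv_rmse(X, y, standardize=False).rmse == pytest.approx(0.0, abs=1e-10)

    def test_matches_press_identity(self, rng):
        X = rng.standard_normal((25, 4))
        y = X @ [1, -1, 0.5, 0] + rng.standard_normal(25)
        res = loocv_rmse(X, y, standardize=False)
        A = np.column_stack([np.ones(25), X])
        hat = np.diag(A @ np.linalg.inv(A.T @ A) @ A.T)
        e = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
        press_rmse = np.sqrt(np.mean((e / (1 - hat)) ** 2))
        assert res.rmse == pytest.approx(press_rmse, abs=1e-10)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_press_identity_property(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((15, 3))
        y = rng.standard_normal(15)
        res = loocv_rmse(X, y, standardize=False)
        A = np.column_stack([np.ones(15), X])
        hat = np.diag(A @ np.linalg.inv(A.T @ A) @ A.T)
        e = y - A @ np.linalg.lstsq(A, y, rcond=None)[0]
        assert res.rmse == pytest.approx(np.sqrt(np.mean((e / (1 - hat)) ** 2)), abs=1e-9)

    def test_row_permutation_invariance(self, rng):
        X = rng.standard_normal((18, 3))
        y = rng.standard_normal(18)
        perm = rng.permutation(18)
        assert loocv_rmse(X, y).rmse == pytest.approx(loocv_rmse(X[perm], y[perm]).rmse, abs=1e-12)


class TestPairedT:
    def test_equal_samples_zero_difference(self):
        a = np.arange(10.0)
        res = paired_t(a, a.copy())
        assert res.mean_diff == 0.0
        assert res.flags  # zero variance flagged

    def test_hand_computed_small_sample(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = np.array([1.5, 2.0, 2.5, 4.5, 4.0])
        d = a - b
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        res = paired_t(a, b)
        assert res.t == pytest.approx(expected_t, abs=1e-12)
        assert res.df == 4


class TestReliability:
    def test_identical_items_alpha_one(self, rng):
        col = rng.standard_normal(30)
        M = np.column_stack([col, col, col])
        assert reliability(M, "alpha").value == pytest.approx(1.0, abs=1e-12)

    def test_alpha_covariance_closed_form(self, rng):
        z = rng.standard_normal((500, 2))
        x1 = z[:, 0]
        x2 = 0.6 * z[:, 0] + 0.8 * z[:, 1]
        M = np.column_stack([x1, x2])
        v1, v2 = M.var(axis=0, ddof=1)
        cov = np.cov(M.T)[0, 1]
        expected = 2 * (1 - (v1 + v2) / (v1 + v2 + 2 * cov))
        assert reliability(M, "alpha").value == pytest.approx(expected, abs=1e-10)

    def test_alpha_matches_pingouin(self, rng):
        import pingouin as pg

        M = rng.standard_normal((40, 4)) + rng.standard_normal((40, 1))
        mine = reliability(M, "alpha").value
        theirs = pg.cronbach_alpha(pd.DataFrame(M))[0]
        assert mine == pytest.approx(theirs, abs=1e-10)

    def test_degenerate_dichotomous_items_rejected(self):
        M = np.ones((10, 4))
        with pytest.raises(ValueError, match="undefined"):
            reliability(M, "kr20")

    def test_kr20_on_mixed_items(self, rng):
        M = (rng.uniform(size=(50, 6)) < 0.7).astype(float)
        val = reliability(M, "kr20").value
        assert val <= 1.0

    def test_icc_matches_pingouin(self, rng):
        import pingouin as pg

        n = 30
        subject_effect = rng.standard_normal(n)
        M = subject_effect[:, None] + 0.5 * rng.standard_normal((n, 2))
        mine_c = reliability(M, "icc_consistency").value
        mine_a = reliability(M, "icc_agreement").value
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(n), 2),
                "rater": np.tile([0, 1], n),
                "score": M.ravel(),
            }
        )
        icc = pg.intraclass_corr(long, targets="subject", raters="rater", ratings="score")
        theirs_c = icc.set_index("Type").loc["ICC(C,1)", "ICC"]
        theirs_a = icc.set_index("Type").loc["ICC(A,1)", "ICC"]
        assert mine_c == pytest.approx(theirs_c, abs=1e-6)
        assert mine_a == pytest.approx(theirs_a, abs=1e-6)

    def test_pearson_matrix_symmetric_unit_diagonal(self, rng):
        M = rng.standard_normal((25, 4))
        res = reliability(M, "pearson")
        r = res.detail["r"]
        np.testing.assert_allclose(r, r.T)
        np.testing.assert_allclose(np.diag(r), 1.0)


class TestRecovery:
    def test_large_cohort_recovers_generating_coefficients(self):
        """Cohorts from the default generator recover each generating β
        within ±0.02 averaged over replicates."""
        reps = 20
        coefs = np.zeros((reps, 5))
        for r in range(reps):
            cohort = generate_cohort(CohortSpec(n_participants=5000, seed=100 + r))
            fit = fit_ols(cohort[list(PREDICTOR_NAMES)], cohort["true_n1_diff_uv"])
            coefs[r] = fit.coef
        mean = coefs.mean(axis=0)
        expected = np.array([0.047, 0.598, -0.094, 0.649, -0.359])
        np.testing.assert_allclose(mean, expected, atol=0.02)
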