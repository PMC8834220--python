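import warnings

import numpy as np
import pytest

from nirtex.pls_core import (fit_simpls, jackknife_beta, loo_cv, predict)


def brute_force_loo(X, y, a_max):
    """Independent n-refit loop oracle for RMSECV."""
    n = X.shape[0]
    rmse = []
    for A in range(1, a_max + 1):
        errs = []
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = fit_simpls(X[mask], y[mask], A)
            errs.append(predict(m, X[i:i + 1])[0] - y[i])
        rmse.append(np.sqrt(np.mean(np.square(errs))))
    return np.array(rmse)


class TestFitSimpls:
    def test_univariate_collapse_to_regression_slope(self, rng):
        x = rng.normal(size=(15, 1))
        y = 3 * x[:, 0] + rng.normal(size=15)
        m = fit_simpls(x, y, 1)
        slope = np.cov(x[:, 0], y, ddof=1)[0, 1] / np.var(x[:, 0], ddof=1)
        assert m.beta[0] == pytest.approx(slope, rel=1e-10)

    def test_full_rank_equals_ols(self, rng):
        X = rng.normal(size=(20, 5))
        y = X @ rng.normal(size=5) + rng.normal(size=20) * 0.1
        m = fit_simpls(X, y, 5)
        coef = np.linalg.lstsq(np.column_stack([np.ones(20), X]), y, rcond=None)[0]
        ols_pred = coef[0] + X @ coef[1:]
        assert np.abs(m.fitted - ols_pred).max() < 1e-8

    def test_noiseless_recovery_at_true_component_count(self, rng):
        W = rng.normal(size=(40, 3)) @ rng.normal(size=(3, 10))
        y = W @ rng.normal(size=10)  # y exactly linear in a rank-3 X
        m = fit_simpls(W, y, 3)
        assert np.sqrt(np.mean(m.residuals ** 2)) < 1e-10

    def test_scores_orthonormal_and_beta_reproduces_fit(self, rng):
        X = rng.normal(size=(25, 12))
        y = rng.normal(size=25)
        m = fit_simpls(X, y, 6)
        assert np.abs(m.T.T @ m.T - np.eye(6)).max() < 1e-8
        yhat = m.y_mean + (X - m.x_mean) @ m.beta
        assert np.abs(yhat - m.fitted).max() < 1e-10

    def test_matches_nipals_reference_implementation(self, rng):
        # same Krylov space for single-response PLS
        from sklearn.cross_decomposition import PLSRegression
        X = rng.normal(size=(30, 8))
        y = X @ rng.normal(size=8) + rng.normal(size=30)
        m = fit_simpls(X, y, 5)
        for A in range(1, 6):
            sk = PLSRegression(n_components=A, scale=False).fit(X, y[:, None])
            assert np.abs(predict(m, X, A) - sk.predict(X).ravel()).max() < 1e-8

    def test_rank_excess_truncates_with_warning(self, rng):
        X = np.tile(rng.normal(size=(1, 4)), (10, 1)) + 0.0
        X[:, 0] = rng.normal(size=10)  # rank 2 centered
        y = X[:, 0] + rng.normal(size=10) * 0.01
        with pytest.warns(UserWarning, match="truncating"):
            m = fit_simpls(X, y, 4)
        assert m.n_components < 4

    def test_zero_variance_response_rejected(self, rng):
        with pytest.raises(ValueError, match="variance"):
            fit_simpls(rng.normal(size=(5, 3)), np.ones(5), 2)


class TestPredict:
    def test_training_rows_reproduce_fitted_values(self, rng):
        X = rng.normal(size=(12, 4))
        y = rng.normal(size=12)
        m = fit_simpls(X, y, 3)
        np.testing.assert_allclose(predict(m, X), m.fitted, atol=1e-12)

    def test_center_maps_to_mean_response(self, rng):
        X = rng.normal(size=(12, 4))
        y = rng.normal(size=12)
        m = fit_simpls(X, y, 2)
        assert predict(m, m.x_mean[None, :])[0] == pytest.approx(m.y_mean)

    def test_three_by_two_example_via_explicit_algebra(self):
        # independent long-hand SIMPLS at one component
        X = np.array([[1.0, 2.0], [3.0, 1.0], [5.0, 6.0]])
        y = np.array([1.0, 2.0, 6.0])
        X0 = X - X.mean(axis=0)
        y0 = y - y.mean()
        s = X0.T @ y0
        t = X0 @ s
        t_unit = t / np.linalg.norm(t)
        q = y0 @ t_unit
        beta = (s / np.linalg.norm(X0 @ s)) * q
        expected = y.mean() + X0 @ beta
        m = fit_simpls(X, y, 1)
        np.testing.assert_allclose(m.fitted, expected, atol=1e-12)

    def test_column_mismatch_rejected(self, rng):
        m = fit_simpls(rng.normal(size=(8, 3)), rng.normal(size=8), 2)
        with pytest.raises(ValueError, match="columns"):
            predict(m, np.zeros((1, 4)))


class TestLooCV:
    def test_equals_brute_force_refit_loop(self, rng):
        X = rng.normal(size=(12, 6))
        y = X @ rng.normal(size=6) + rng.normal(size=12) * 0.3
        cv = loo_cv(X, y, 4)
        np.testing.assert_array_equal(cv.rmsecv, brute_force_loo(X, y, 4))

    def test_tiny_three_sample_case(self, rng):
        X = rng.normal(size=(3, 2))
        y = rng.normal(size=3)
        cv = loo_cv(X, y, 1)
        np.testing.assert_array_equal(cv.rmsecv, brute_force_loo(X, y, 1))

    def test_null_response_selects_few_components(self):
        # y independent of X: RMSECV should not improve with A
        selected, nonimp = [], 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            X = r.normal(size=(20, 10))
            y = r.normal(size=20)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cv = loo_cv(X, y, 8)
            selected.append(cv.selected)
            nonimp += cv.rmsecv[-1] >= cv.rmsecv[0]
        assert np.median(selected) <= 2
        assert nonimp >= 40

    def test_duplicated_rows_leak_into_near_perfect_loo(self, rng):
        X = rng.normal(size=(6, 4))
        y = X @ rng.normal(size=4)
        X2, y2 = np.vstack([X, X]), np.concatenate([y, y])
        cv = loo_cv(X2, y2, 4)
        assert cv.rmsecv.min() < 1e-8

    def test_selection_rule_first_minimum_on_ties(self):
        from nirtex.pls_core import CVResult
        r = CVResult(rmsecv=np.array([1.0, 0.5, 0.5]), selected=2,
                     loo_predictions=np.zeros(3))
        assert r.selected == 2


class TestJackknife:
    def test_delete_one_matches_explicit_loop(self, rng):
        X = rng.normal(size=(8, 3))
        y = X @ np.array([2.0, 0.0, 0.0]) + rng.normal(size=8) * 0.01
        jk = jackknife_beta(X, y, 2)
        betas = []
        for i in range(8):
            mask = np.ones(8, dtype=bool)
            mask[i] = False
            betas.append(fit_simpls(X[mask], y[mask], 2).beta)
        betas = np.array(betas)
        bbar = betas.mean(axis=0)
        se = np.sqrt(7 / 8 * np.sum((betas - bbar) ** 2, axis=0))
        np.testing.assert_allclose(jk.se, se, atol=1e-12)

    def test_planted_signal_significant_noise_not(self):
        # strong planted coefficient drives p -> 0; irrelevant column p
        # behaves roughly uniformly across repetitions
        p_sig, p_null = [], []
        for rep in range(100):
            r = np.random.default_rng(500 + rep)
            X = r.normal(size=(25, 5))
            y = 2 * X[:, 1] + r.normal(size=25) * 1e-6
            jk = jackknife_beta(X, y, 2)
            p_sig.append(jk.p[1])
            p_null.append(jk.p[3])
        # the planted coefficient is overwhelmingly significant; the
        # jack-knife SE reflects X-sampling variability, so individual
        # repetitions bottom out near but not exactly at zero
        assert np.median(p_sig) < 1e-10
        assert max(p_sig) < 0.05
        p_null = np.array(p_null)
        assert 0.2 < np.mean(p_null > 0.5) < 0.8

    def test_degenerate_zero_se_convention(self, rng):
        # two mirror-image segments: both segment-deleted refits see the
        # same rows, so the estimates are bit-identical and SE = 0
        B = rng.normal(size=(6, 2))
        yb = B @ np.array([2.0, -1.0])
        X = np.vstack([B, B])
        y = np.concatenate([yb, yb])
        jk = jackknife_beta(X, y, 2, n_segments=2)
        assert np.all(jk.se == 0.0)
        assert np.all(jk.p == 0.0)  # nonzero beta with zero SE

    def test_pvalues_invariant_under_response_rescaling(self, rng):
        X = rng.normal(size=(15, 4))
        y = X @ rng.normal(size=4) + rng.normal(size=15) * 0.2
        jk1 = jackknife_beta(X, y, 3)
        jk2 = jackknife_beta(X, 13.7 * y - 4.0, 3)
        np.testing.assert_allclose(jk1.p, jk2.p, atol=1e-10)

    def test_ci_contains_point_estimate(self, rng):
        X = rng.normal(size=(15, 4))
        y = rng.normal(size=15)
        m = fit_simpls(X, y, 2)
        jk = jackknife_beta(X, y, 2)
        assert np.all(jk.ci_lower <= m.beta)
        assert np.all(m.beta <= jk.ci_upper)

    def test_invalid_segment_count_rejected(self, rng):
        X = rng.normal(size=(6, 2))
        y = rng.normal(size=6)
        with pytest.raises(ValueError):
            jackknife_beta(X, y, 1, n_segments=1)
        with pytest.raises(ValueError):
            jackknife_beta(X, y, 1, n_segments=7)
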