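import numpy as np
import pytest
from scipy import stats

from nirtex.outliers import (DistancePair, critical_limits, mahalanobis_flag,
                             pca_fit, pls_distances)
from nirtex.pls_core import fit_simpls


class TestPCA:
    def test_rank_one_matrix_pc1_explains_everything(self, rng):
        X = np.outer(rng.normal(size=20), rng.normal(size=6))
        r = pca_fit(X, 3)
        assert r.explained_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_cumulative_variance_completes_to_one(self, rng):
        X = rng.normal(size=(15, 6))
        r = pca_fit(X, 6)
        assert r.cumulative[-1] == pytest.approx(1.0, abs=1e-10)

    def test_reconstruction_at_full_rank(self, rng):
        X = rng.normal(size=(10, 5))
        r = pca_fit(X, 5)
        assert np.abs(r.reconstruct() - X).max() < 1e-8

    def test_loadings_orthonormal(self, rng):
        X = rng.normal(size=(30, 8))
        r = pca_fit(X, 4)
        assert np.abs(r.loadings.T @ r.loadings - np.eye(4)).max() < 1e-8

    def test_matches_sklearn_up_to_fixed_sign(self, rng):
        from sklearn.decomposition import PCA
        X = rng.normal(size=(25, 7))
        r = pca_fit(X, 3)
        sk = PCA(n_components=3).fit(X)
        for j in range(3):
            v = sk.components_[j]
            if v[np.argmax(np.abs(v))] < 0:
                v = -v
            np.testing.assert_allclose(r.loadings[:, j], v, atol=1e-8)

    def test_excessive_k_rejected(self, rng):
        with pytest.raises(ValueError):
            pca_fit(rng.normal(size=(5, 3)), 5)


class TestMahalanobis:
    def test_whitened_scores_give_squared_norm(self, rng):
        # pre-whitened scores: D^2 reduces to the squared Euclidean norm
        Z = rng.normal(size=(500, 3))
        Z = (Z - Z.mean(axis=0)) @ np.linalg.inv(np.linalg.cholesky(
            np.cov(Z, rowvar=False)).T)
        _, d2 = mahalanobis_flag(Z)
        np.testing.assert_allclose(d2, np.sum((Z - Z.mean(0)) ** 2, axis=1),
                                   atol=1e-8)

    def test_four_point_hand_algebra(self):
        # 2-D example small enough to invert the covariance by hand
        T = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0], [2.0, 2.0]])
        center = np.array([1.0, 1.0])
        S = np.cov(T, rowvar=False, ddof=1)       # [[4/3, 0], [0, 4/3]]
        expected = np.array([(r - center) @ np.linalg.inv(S) @ (r - center)
                             for r in T])          # all 1.5
        _, d2 = mahalanobis_flag(T, alpha=0.5)
        np.testing.assert_allclose(d2, expected, atol=1e-12)
        np.testing.assert_allclose(d2, 1.5, atol=1e-12)

    def test_planted_ten_sigma_point_is_flagged(self, rng):
        T = rng.normal(size=(60, 3))
        T[17] = [10 * T[:, 0].std(), 0.0, 0.0]
        flags, _ = mahalanobis_flag(T, alpha=0.025)
        assert list(np.flatnonzero(flags)) == [17]

    def test_affine_invariance_of_distances(self, rng):
        T = rng.normal(size=(40, 3))
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        _, d2 = mahalanobis_flag(T)
        _, d2t = mahalanobis_flag(T @ A + rng.normal(size=3))
        np.testing.assert_allclose(d2, d2t, atol=1e-8)

    def test_singular_covariance_rejected(self, rng):
        t = rng.normal(size=20)
        T = np.column_stack([t, 2 * t])
        with pytest.raises(ValueError, match="singular"):
            mahalanobis_flag(T)


class TestPLSDistances:
    def test_row_in_model_plane_has_zero_orthogonal_distance(self, rng):
        X = rng.normal(size=(20, 6))
        y = X @ rng.normal(size=6) + rng.normal(size=20) * 0.1
        m = fit_simpls(X, y, 2)
        # project a row onto the model plane: q must vanish
        x = X[3] - m.x_mean
        t = x @ m.R
        x_plane = t @ m.P.T + m.x_mean
        d = pls_distances(m, x_plane[None, :])
        assert d.q[0] < 1e-16 * (x @ x)

    def test_center_row_has_zero_score_distance(self, rng):
        X = rng.normal(size=(15, 4))
        m = fit_simpls(X, rng.normal(size=15), 2)
        d = pls_distances(m, m.x_mean[None, :])
        assert d.h[0] == 0.0

    def test_training_mean_score_distance_formula(self, rng):
        # normalized leverage: mean h over training rows = A * (n-1) / n
        X = rng.normal(size=(30, 10))
        y = rng.normal(size=30)
        m = fit_simpls(X, y, 4)
        d = pls_distances(m, X)
        assert d.h.mean() == pytest.approx(4 * 29 / 30, rel=1e-10)


class TestCriticalLimits:
    def test_moment_recovery_of_chi_square_parameters(self):
        # d ~ u0 * chi2_N / N with u0 = 2, N = 4
        r = np.random.default_rng(11)
        d = r.chisquare(4, size=10_000) * 2 / 4
        cl = critical_limits(DistancePair(h=d, q=d), "data_driven", 0.05)
        assert abs(cl.n_h - 4) <= 1
        assert cl.u0_h == pytest.approx(2.0, rel=0.05)

    def test_flag_rate_converges_to_alpha(self):
        r = np.random.default_rng(3)
        d = DistancePair(h=r.chisquare(6, size=10_000) * 1.7,
                         q=r.chisquare(3, size=10_000))
        for alpha in (0.05, 0.01):
            cl = critical_limits(d, "data_driven", alpha)
            rate = float((d.h > cl.limit_h).mean())
            assert abs(rate - alpha) < 0.005

    def test_contamination_robust_flags_more_planted_than_classical(self):
        rob_rates, cls_rates = [], []
        for rep in range(100):
            r = np.random.default_rng(rep)
            d = r.chisquare(4, size=200)
            bad = r.choice(200, 40, replace=False)
            d[bad] *= 50
            dp = DistancePair(h=d, q=d)
            rob = critical_limits(dp, "robust", 0.01)
            cls = critical_limits(dp, "data_driven", 0.01)
            rob_rates.append(rob.flags[bad].mean())
            cls_rates.append(cls.flags[bad].mean())
        assert np.mean(rob_rates) >= 0.95
        assert np.mean(cls_rates) < np.mean(rob_rates)

    def test_single_extreme_point_moves_classical_not_robust_limits(self):
        r = np.random.default_rng(7)
        d = r.chisquare(4, size=200)
        clean = DistancePair(h=d, q=d)
        d1 = d.copy()
        d1[0] = d.max() * 60
        dirty = DistancePair(h=d1, q=d1)
        rob0 = critical_limits(clean, "robust", 0.05)
        rob1 = critical_limits(dirty, "robust", 0.05)
        cls0 = critical_limits(clean, "data_driven", 0.05)
        cls1 = critical_limits(dirty, "data_driven", 0.05)
        assert abs(rob1.limit_h - rob0.limit_h) / rob0.limit_h < 0.05
        assert abs(cls1.limit_h - cls0.limit_h) / cls0.limit_h > 0.05

    def test_equal_distances_degenerate_error(self):
        d = DistancePair(h=np.full(50, 2.0), q=np.full(50, 1.0))
        with pytest.raises(ValueError):
            critical_limits(d, "robust", 0.05)
        with pytest.raises(ValueError):
            critical_limits(d, "data_driven", 0.05)

    def test_flags_consistent_with_limits(self, rng):
        d = DistancePair(h=rng.chisquare(5, size=300),
                         q=rng.chisquare(2, size=300))
        cl = critical_limits(d, "robust", 0.05)
        np.testing.assert_array_equal(
            cl.flags, (d.h > cl.limit_h) | (d.q > cl.limit_q))
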