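"""Outlier screening for spectral calibration.

Two screens are provided:

1.  Mahalanobis distance on PCA scores of the pre-treated spectra, flagged
    against a chi-square quantile.
2.  PLS residual distances — score distance h (leverage inside the model
    plane) and orthogonal distance q (squared residual norm off the plane)
    — compared against chi-square critical limits whose scale u0 and
    degrees of freedom N are estimated either from classical moments
    ("data-driven": u0 = mean, N = round(2*mean^2/var)) or from robust
    quantiles ("robust": median and inter-quartile range matched to the
    corresponding chi-square quantile ratio).  The robust limits are used
    for screening, the data-driven ones for the final model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .pls_core import PLSModel

__all__ = [
    "PCAResult",
    "DistancePair",
    "CriticalLimits",
    "pca_fit",
    "mahalanobis_flag",
    "pls_distances",
    "critical_limits",
]

_N_MAX = 250  # cap on estimated chi-square degrees of freedom


@dataclass
class PCAResult:
    loadings: np.ndarray          # p x k, orthonormal columns
    scores: np.ndarray            # n x k
    mean: np.ndarray
    explained_ratio: np.ndarray   # fraction of total variance per PC
    cumulative: np.ndarray

    def reconstruct(self) -> np.ndarray:
        return self.scores @ self.loadings.T + self.mean


def pca_fit(X: np.ndarray, k: int) -> PCAResult:
    """PCA by SVD of the column-centered matrix.

    Deterministic up to sign; the sign is fixed so the largest-magnitude
    element of each loading vector is positive.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k must be in [1, {min(n - 1, p)}], got {k}")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention
    for j in range(Vt.shape[0]):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    var = S ** 2
    total = var.sum()
    ratio = var / total if total > 0 else np.zeros_like(var)
    loadings = Vt[:k].T
    scores = U[:, :k] * S[:k]
    return PCAResult(
        loadings=loadings, scores=scores, mean=mean,
        explained_ratio=ratio[:k], cumulative=np.cumsum(ratio)[:k],
    )


def mahalanobis_flag(scores: np.ndarray, alpha: float = 0.025):
    """Mahalanobis distance of each score row from the score centroid.

    D2_i = (t_i - tbar)' S^-1 (t_i - tbar); a sample is flagged when D2
    exceeds the chi-square(k) quantile at 1 - alpha.

    Returns ``(flags, d2)``.
    """
    T = np.atleast_2d(np.asarray(scores, dtype=float))
    n, k = T.shape
    if k >= n:
        raise ValueError("need more samples than score dimensions")
    center = T.mean(axis=0)
    S = np.cov(T, rowvar=False, ddof=1).reshape(k, k)
    try:
        Sinv = np.linalg.inv(S)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular score covariance; use fewer principal components"
        ) from exc
    if np.linalg.cond(S) > 1e12:
        raise ValueError("near-singular score covariance; use fewer principal components")
    d = T - center
    d2 = np.einsum("ij,jk,ik->i", d, Sinv, d)
    limit = stats.chi2.ppf(1 - alpha, df=k)
    return d2 > limit, d2


@dataclass
class DistancePair:
    h: np.ndarray  # score distance (leverage), >= 0
    q: np.ndarray  # orthogonal distance (squared X-residual norm), >= 0

    def __post_init__(self):
        if np.any(self.h < -1e-12) or np.any(self.q < -1e-12):
            raise ValueError("distances must be non-negative")
        self.h = np.maximum(self.h, 0.0)
        self.q = np.maximum(self.q, 0.0)


def pls_distances(model: PLSModel, X: np.ndarray) -> DistancePair:
    """Score and orthogonal distances of rows of X under a fitted PLS model.

    h_i = sum_a t_ia^2 / var_a with var_a the per-component training score
    variance (training scores are unit-norm columns, so var_a = 1/(n-1) and
    the training-row mean of h is A*(n-1)/n).  q_i is the squared norm of
    the X-residual row after projection onto the model plane.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.x_mean.size:
        raise ValueError("column count does not match the model")
    Xc = X - model.x_mean
    T_new = Xc @ model.R
    n_train = model.T.shape[0]
    var_a = (model.T ** 2).sum(axis=0) / (n_train - 1)  # = 1/(n-1) per column
    h = (T_new ** 2 / var_a).sum(axis=1)
    resid = Xc - T_new @ model.P.T
    q = (resid ** 2).sum(axis=1)
    return DistancePair(h=h, q=q)


@dataclass
class CriticalLimits:
    approach: str
    u0_h: float
    n_h: int
    limit_h: float
    u0_q: float
    n_q: int
    limit_q: float
    alpha: float
    flags: np.ndarray  # outlier if either distance exceeds its limit

    def __post_init__(self):
        if self.limit_h <= 0 or self.limit_q <= 0:
            raise ValueError("limits must be positive")
        if self.n_h < 1 or self.n_q < 1:
            raise ValueError("degrees of freedom must be >= 1")


def _fit_chi2_data_driven(d: np.ndarray) -> tuple[float, int]:
    u0 = float(np.mean(d))
    v = float(np.var(d, ddof=1))
    if v == 0:
        raise ValueError("zero variance of distances")
    N = int(np.clip(round(2.0 * u0 ** 2 / v), 1, _N_MAX))
    return u0, N


def _fit_chi2_robust(d: np.ndarray) -> tuple[float, int]:
    M = float(np.median(d))
    q25, q75 = np.percentile(d, [25, 75])
    iqr = float(q75 - q25)
    if iqr == 0 or M == 0:
        raise ValueError("degenerate distances: zero median or IQR")
    target = iqr / M
    best_n, best_err = 1, np.inf
    for N in range(1, _N_MAX + 1):
        ratio = (stats.chi2.ppf(0.75, N) - stats.chi2.ppf(0.25, N)) / stats.chi2.ppf(0.5, N)
        err = abs(ratio - target)
        if err < best_err:
            best_n, best_err = N, err
    u0 = M * best_n / stats.chi2.ppf(0.5, best_n)
    return float(u0), best_n


def critical_limits(distances: DistancePair, approach: str = "robust",
                    alpha: float = 0.05) -> CriticalLimits:
    """Chi-square critical limits for a pair of PLS distances.

    Each distance d is modeled as u0 * chi2_N / N.  'data_driven' matches
    the first two moments (u0 = mean, N = round(2 mean^2 / var)); 'robust'
    matches the median and IQR to the chi-square quantile ratio, making the
    limits insensitive to the outliers being hunted.  The limit at level
    alpha is u0 * chi2_N(1 - alpha) / N; a sample is an outlier when either
    of its distances exceeds its limit.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if approach == "data_driven":
        fit = _fit_chi2_data_driven
    elif approach == "robust":
        fit = _fit_chi2_robust
    else:
        raise ValueError(f"unknown approach {approach!r}")
    u0_h, n_h = fit(distances.h)
    u0_q, n_q = fit(distances.q)
    limit_h = u0_h * stats.chi2.ppf(1 - alpha, n_h) / n_h
    limit_q = u0_q * stats.chi2.ppf(1 - alpha, n_q) / n_q
    flags = (distances.h > limit_h) | (distances.q > limit_q)
    return CriticalLimits(
        approach=approach, u0_h=u0_h, n_h=n_h, limit_h=limit_h,
        u0_q=u0_q, n_q=n_q, limit_q=limit_q, alpha=alpha, flags=flags,
    )
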