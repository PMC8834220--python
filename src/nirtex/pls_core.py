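"""Single-response partial least squares by the SIMPLS algorithm, with
leave-one-out cross-validation, component selection and jack-knife
inference on the regression coefficients.

SIMPLS (de Jong 1993) computes each weight vector directly from the deflated
cross-product vector s = X'y, giving orthonormal X-scores without deflating
X itself.  For a single response the fitted subspace coincides with the
Krylov space spanned by NIPALS PLS1, so the two algorithms give identical
predictions at equal numbers of components — a property the test suite uses
as an independent cross-check.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PLSModel",
    "CVResult",
    "JackknifeResult",
    "fit_simpls",
    "predict",
    "loo_cv",
    "jackknife_beta",
]


@dataclass
class PLSModel:
    """Fitted SIMPLS decomposition for one response.

    R (p x A) X-weights mapping centered X to scores; T (n x A) orthonormal
    X-scores; P (p x A) X-loadings; q (A,) y-loadings; beta (p,) regression
    coefficients on the centered predictor scale; beta_path (p x A) the
    coefficient vector at every intermediate component count.
    """

    n_components: int
    R: np.ndarray
    T: np.ndarray
    P: np.ndarray
    q: np.ndarray
    beta: np.ndarray
    beta_path: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    fitted: np.ndarray
    residuals: np.ndarray

    def to_json(self, path: str) -> None:
        obj = {
            "n_components": int(self.n_components),
            "R": self.R.tolist(), "T": self.T.tolist(), "P": self.P.tolist(),
            "q": self.q.tolist(), "beta": self.beta.tolist(),
            "beta_path": self.beta_path.tolist(),
            "x_mean": self.x_mean.tolist(), "y_mean": float(self.y_mean),
            "fitted": self.fitted.tolist(), "residuals": self.residuals.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path: str) -> "PLSModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            n_components=d["n_components"],
            R=np.array(d["R"]), T=np.array(d["T"]), P=np.array(d["P"]),
            q=np.array(d["q"]), beta=np.array(d["beta"]),
            beta_path=np.array(d["beta_path"]),
            x_mean=np.array(d["x_mean"]), y_mean=d["y_mean"],
            fitted=np.array(d["fitted"]), residuals=np.array(d["residuals"]),
        )


def fit_simpls(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Fit PLS1 by SIMPLS at ``n_components`` latent variables.

    X and y are centered internally (means stored on the model).  If the
    requested number of components exceeds the effective rank the model is
    truncated with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError(f"X has {n} rows but y has {y.size} entries")
    if n < 2:
        raise ValueError("need at least 2 samples")
    if np.var(y) == 0:
        raise ValueError("zero-variance response")
    A = int(n_components)
    if A < 1:
        raise ValueError("n_components must be >= 1")
    A = min(A, n - 1, p)

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    X0 = X - x_mean
    y0 = y - y_mean

    s = X0.T @ y0
    R = np.zeros((p, A))
    T = np.zeros((n, A))
    P = np.zeros((p, A))
    q = np.zeros(A)
    V = np.zeros((p, A))

    a_used = 0
    for a in range(A):
        r = s.copy()
        t = X0 @ r
        tnorm = np.linalg.norm(t)
        if tnorm < 1e-12 * max(1.0, np.linalg.norm(X0)):
            warnings.warn(
                f"rank deficiency: truncating at {a_used} components", stacklevel=2
            )
            break
        t /= tnorm
        r /= tnorm
        pvec = X0.T @ t
        qa = float(y0 @ t)
        v = pvec.copy()
        if a > 0:
            v -= V[:, :a] @ (V[:, :a].T @ pvec)
        vnorm = np.linalg.norm(v)
        if vnorm < 1e-12:
            warnings.warn(
                f"rank deficiency: truncating at {a_used} components", stacklevel=2
            )
            break
        v /= vnorm
        s = s - v * (v @ s)
        V[:, a] = v
        R[:, a] = r
        T[:, a] = t
        P[:, a] = pvec
        q[a] = qa
        a_used = a + 1

    R, T, P, q = R[:, :a_used], T[:, :a_used], P[:, :a_used], q[:a_used]
    beta_path = np.cumsum(R * q, axis=1)
    beta = beta_path[:, -1].copy()  # contiguous: keeps dot products bit-stable
    fitted = y_mean + X0 @ beta
    return PLSModel(
        n_components=a_used, R=R, T=T, P=P, q=q, beta=beta, beta_path=beta_path,
        x_mean=x_mean, y_mean=y_mean, fitted=fitted, residuals=y - fitted,
    )


def predict(model: PLSModel, X_new: np.ndarray, n_components: int | None = None) -> np.ndarray:
    """yhat = y_mean + (X_new - x_mean) @ beta, optionally at a smaller
    component count along the stored coefficient path."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.x_mean.size:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.x_mean.size}"
        )
    if n_components is None:
        beta = model.beta
    else:
        if not 1 <= n_components <= model.n_components:
            raise ValueError("n_components out of fitted range")
        beta = np.ascontiguousarray(model.beta_path[:, n_components - 1])
    return model.y_mean + (X_new - model.x_mean) @ beta


@dataclass
class CVResult:
    rmsecv: np.ndarray            # per candidate component count, index a-1
    selected: int                 # chosen number of components
    loo_predictions: np.ndarray   # per-sample LOO prediction at `selected`
    loo_pred_path: np.ndarray = None  # n x A_max, all component counts

    def __post_init__(self):
        if np.any(self.rmsecv < 0):
            raise ValueError("RMSECV must be >= 0")
        if not 1 <= self.selected <= self.rmsecv.size:
            raise ValueError("selected component count out of range")


def loo_cv(X: np.ndarray, y: np.ndarray, a_max: int, rule: str = "min") -> CVResult:
    """Leave-one-out cross-validation over component counts 1..a_max.

    Each sample is predicted by a model refitted without it; RMSECV(A) is
    computed for every A along the coefficient path of the n-1 fit.  The
    selected count is the global RMSECV minimum (first index on ties), or
    the smallest count within one standard error of the minimum when
    ``rule='one_se'``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for LOO-CV")
    a_max = min(int(a_max), n - 2, X.shape[1])
    if a_max < 1:
        raise ValueError("a_max too small after capping")
    preds = np.full((n, a_max), np.nan)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_simpls(X[mask], y[mask], a_max)
        # same arithmetic path as predict(), so a naive refit loop
        # reproduces the RMSECV exactly
        for a in range(1, m.n_components + 1):
            preds[i, a - 1] = predict(m, X[i : i + 1], n_components=a)[0]
        # rank-truncated fits: extend the last available prediction
        preds[i, m.n_components :] = preds[i, m.n_components - 1]
    err = preds - y[:, None]
    rmsecv = np.sqrt(np.mean(err ** 2, axis=0))
    if rule == "min":
        selected = int(np.argmin(rmsecv)) + 1
    elif rule == "one_se":
        amin = int(np.argmin(rmsecv))
        se = np.std(err[:, amin] ** 2, ddof=1) / np.sqrt(n)
        thresh = rmsecv[amin] ** 2 + se
        selected = int(np.argmax(rmsecv ** 2 <= thresh)) + 1
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    return CVResult(
        rmsecv=rmsecv, selected=selected,
        loo_predictions=preds[:, selected - 1], loo_pred_path=preds,
    )


@dataclass
class JackknifeResult:
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_segments: int

    def __post_init__(self):
        if np.any(self.se < 0):
            raise ValueError("jack-knife SE must be >= 0")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("p-values must lie in [0, 1]")


def jackknife_beta(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    n_segments: int | None = None,
    alpha: float = 0.05,
) -> JackknifeResult:
    """Jack-knife standard errors, t-statistics and two-sided p-values for
    the PLS coefficients at a fixed component count.

    Segments default to delete-one (n segments).  SE uses the jack-knife
    variance formula  (m-1)/m * sum_i (b_(i) - b_bar)^2  over the m
    segment-deleted estimates; t = beta / SE with df = m - 1.  A degenerate
    SE of zero maps to p = 0 for a nonzero coefficient and p = 1 otherwise.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    m = n if n_segments is None else int(n_segments)
    if not 2 <= m <= n:
        raise ValueError(f"n_segments must be in [2, {n}]")
    segs = np.array_split(np.arange(n), m)
    if any(len(s) < 1 for s in segs):
        raise ValueError("every segment needs at least one sample")
    full = fit_simpls(X, y, n_components)
    A = full.n_components
    betas = np.zeros((m, X.shape[1]))
    for j, seg in enumerate(segs):
        mask = np.ones(n, dtype=bool)
        mask[seg] = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mj = fit_simpls(X[mask], y[mask], A)
        betas[j] = mj.beta if mj.n_components == A else mj.beta_path[:, -1]
    bbar = betas.mean(axis=0)
    se = np.sqrt((m - 1) / m * np.sum((betas - bbar) ** 2, axis=0))
    df = m - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, full.beta / np.where(se > 0, se, 1.0), np.inf * np.sign(full.beta))
    p = np.where(
        se > 0,
        2 * stats.t.sf(np.abs(np.where(se > 0, t, 0.0)), df),
        np.where(full.beta != 0, 0.0, 1.0),
    )
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return JackknifeResult(
        se=se, t=t, p=p,
        ci_lower=full.beta - tcrit * se, ci_upper=full.beta + tcrit * se,
        n_segments=m,
    )
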