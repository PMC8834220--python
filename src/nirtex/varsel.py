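"""Wavelength selection: Monte Carlo uninformative variable elimination
(MC-UVE) and significant high-|beta| coefficient selection, plus predictor
augmentation with an external factor such as the berry equatorial diameter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .pls_core import JackknifeResult, PLSModel, fit_simpls

__all__ = ["SelectionResult", "mcuve", "beta_select", "augment"]

log = logging.getLogger(__name__)


@dataclass
class SelectionResult:
    """Outcome of a wavelength-selection run.

    ``indices`` are the selected predictor columns in ascending order;
    ``criterion`` holds the per-column criterion value for *all* columns
    (MC-UVE stability, or |beta| for the beta method, with ``p`` the
    jack-knife p-values).
    """

    method: str
    indices: np.ndarray
    criterion: np.ndarray
    p: np.ndarray | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if self.indices.size != np.unique(self.indices).size:
            raise ValueError("selected indices must be unique")
        if self.indices.size and (
            self.indices.min() < 0 or self.indices.max() >= self.criterion.size
        ):
            raise ValueError("selected index out of bounds")
        self.indices = np.sort(self.indices)


def mcuve(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    n_runs: int = 500,
    sample_fraction: float = 0.8,
    cutoff_rule: str = "noise_p99",
    seed: int = 0,
    n_noise: int | None = None,
) -> SelectionResult:
    """Monte Carlo uninformative variable elimination.

    Repeatedly fits PLS on random subsamples of the calibration rows and
    records the coefficient vector; the stability of column j is
    s_j = mean_r(b_j) / sd_r(b_j).  Columns whose |s| falls below the
    cutoff are eliminated — a column with a large but unstable coefficient
    is discarded, which is the point of the method.

    The default cutoff appends artificial N(0,1) noise columns to X and
    uses the 99th percentile of their |s| (the classical UVE cutoff);
    ``cutoff_rule`` may also be a float used as an absolute |s| threshold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n_runs < 50:
        raise ValueError("n_runs must be >= 50")
    if not 0 < sample_fraction < 1:
        raise ValueError("sample_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)

    use_noise = cutoff_rule == "noise_p99"
    if use_noise:
        k_noise = n_noise if n_noise is not None else min(p, 300)
        noise_block = rng.normal(0.0, 1.0, size=(n, k_noise)) * 1e-3 * max(X.std(), 1e-12)
        Xa = np.hstack([X, noise_block])
    else:
        k_noise = 0
        Xa = X

    n_sub = max(int(round(sample_fraction * n)), n_components + 2)
    betas = np.zeros((n_runs, Xa.shape[1]))
    for r in range(n_runs):
        idx = rng.choice(n, size=n_sub, replace=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = fit_simpls(Xa[idx], y[idx], n_components)
        betas[r] = m.beta
    mean_b = betas.mean(axis=0)
    sd_b = betas.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        stab = np.where(sd_b > 0, mean_b / np.where(sd_b > 0, sd_b, 1.0),
                        np.sign(mean_b) * np.inf)
    if np.any(sd_b == 0):
        log.warning("MC-UVE: %d columns had zero coefficient spread; "
                    "stability set to signed infinity and retained",
                    int((sd_b == 0).sum()))
    stab_real = stab[:p]
    if use_noise:
        cutoff = float(np.percentile(np.abs(stab[p:]), 99))
    else:
        cutoff = float(cutoff_rule)
    selected = np.flatnonzero(np.abs(stab_real) > cutoff)
    return SelectionResult(
        method="mcuve", indices=selected, criterion=stab_real,
        params={"n_runs": n_runs, "sample_fraction": sample_fraction,
                "cutoff": cutoff, "n_components": n_components,
                "n_noise": k_noise, "seed": seed},
    )


def _local_extrema(v: np.ndarray) -> np.ndarray:
    """Indices of strict local extrema of v, keeping the leftmost index of a
    plateau; endpoints count when they extend the adjacent trend."""
    n = v.size
    if n == 1:
        return np.array([0])
    keep = []
    for i in range(n):
        if i == 0 or i == n - 1:
            continue
        if v[i] > v[i - 1] and v[i] > v[i + 1]:
            keep.append(i)
        elif v[i] < v[i - 1] and v[i] < v[i + 1]:
            keep.append(i)
        elif v[i] > v[i - 1] and v[i] == v[i + 1]:
            # leftmost point of a plateau that is a maximum on its left side
            j = i
            while j < n - 1 and v[j] == v[j + 1]:
                j += 1
            if j < n - 1 and v[i] > v[j + 1]:
                keep.append(i)
        elif v[i] < v[i - 1] and v[i] == v[i + 1]:
            j = i
            while j < n - 1 and v[j] == v[j + 1]:
                j += 1
            if j < n - 1 and v[i] < v[j + 1]:
                keep.append(i)
    return np.asarray(keep, dtype=int)


def beta_select(
    jk: JackknifeResult,
    model: PLSModel,
    p_threshold: float = 0.05,
    magnitude_rule: str = "extrema",
    quantile: float = 0.75,
) -> SelectionResult:
    """Select wavelengths with statistically significant high |beta|.

    Keeps columns with jack-knife p < ``p_threshold`` that also satisfy the
    magnitude rule: 'extrema' keeps the peaks and valleys of the beta curve
    (strict local extrema over the wavenumber axis, leftmost index on
    plateaus); 'quantile' keeps the top-|beta| quantile among significant
    columns.
    """
    beta = model.beta
    sig = jk.p < p_threshold
    if not np.any(sig):
        raise ValueError(
            "no coefficient is significant at p < "
            f"{p_threshold}; relax the threshold"
        )
    if magnitude_rule == "extrema":
        ext = np.zeros(beta.size, dtype=bool)
        ext[_local_extrema(beta)] = True
        selected = np.flatnonzero(sig & ext)
        if selected.size == 0:
            raise ValueError(
                "no significant column is a local extremum of the beta "
                "curve; relax the threshold or use magnitude_rule='quantile'"
            )
    elif magnitude_rule == "quantile":
        thr = np.quantile(np.abs(beta[sig]), quantile)
        selected = np.flatnonzero(sig & (np.abs(beta) >= thr))
    else:
        raise ValueError(f"unknown magnitude_rule {magnitude_rule!r}")
    return SelectionResult(
        method="beta", indices=selected, criterion=np.abs(beta), p=jk.p,
        params={"p_threshold": p_threshold, "magnitude_rule": magnitude_rule,
                "quantile": quantile},
    )


def augment(X_selected: np.ndarray, extra: np.ndarray) -> np.ndarray:
    """Append an external predictor (e.g. equatorial diameter) as the final
    column.  The extra factor never participates in wavelength selection."""
    X_selected = np.atleast_2d(np.asarray(X_selected, dtype=float))
    extra = np.asarray(extra, dtype=float).ravel()
    if extra.size != X_selected.shape[0]:
        raise ValueError(
            f"extra factor has {extra.size} entries for {X_selected.shape[0]} rows"
        )
    return np.hstack([X_selected, extra[:, None]])
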