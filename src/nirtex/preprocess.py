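"""Spectral pre-treatments: SNV, MSC, Savitzky-Golay, mean centering, min-max.

All transforms are column-count preserving.  Transforms with learned
constants (MSC reference, column means, per-column min/max) are fitted on
the training partition only and re-applied elsewhere via
:class:`FittedTransform`; SNV and Savitzky-Golay are per-row and stateless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .spectra_io import SpectraSet

__all__ = [
    "snv",
    "msc",
    "savgol",
    "fit_apply_scaler",
    "FittedTransform",
    "Pretreatment",
    "FittedPretreatment",
]


def _as_matrix(x):
    if isinstance(x, SpectraSet):
        return x.absorbance, x
    return np.atleast_2d(np.asarray(x, dtype=float)), None


def _wrap(mat, template):
    if template is None:
        return mat
    return template.copy_with(mat)


def snv(spectra):
    """Standard normal variate: each row centered and scaled to unit sample SD
    (n-1 denominator).  Removes per-row affine scatter distortions.
    """
    X, tpl = _as_matrix(spectra)
    sd = X.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        who = tpl.sample_ids[bad[0]] if tpl is not None else f"row {bad[0]}"
        raise ValueError(f"constant spectrum (SD = 0) for sample {who}")
    out = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    return _wrap(out, tpl)


def msc(spectra, reference: np.ndarray | None = None):
    """Multiplicative scatter correction against a reference spectrum.

    Each row x is regressed on the reference by OLS, x = a + b*ref, and
    replaced by (x - a)/b.  The reference defaults to the column-mean
    spectrum of the input (the training set when used in a pipeline).

    Returns ``(corrected, FittedTransform)`` so the same reference can be
    re-applied to new data.
    """
    X, tpl = _as_matrix(spectra)
    ref = X.mean(axis=0) if reference is None else np.asarray(reference, dtype=float)
    if ref.std() == 0:
        raise ValueError("MSC reference spectrum has zero variance")
    rc = ref - ref.mean()
    b = (X - X.mean(axis=1, keepdims=True)) @ rc / (rc @ rc)
    if np.any(b == 0):
        raise ValueError("zero MSC slope; spectrum uncorrelated with reference")
    a = X.mean(axis=1) - b * ref.mean()
    out = (X - a[:, None]) / b[:, None]
    ft = FittedTransform(method="msc", constants={"reference": ref.copy()})
    return _wrap(out, tpl), ft


def savgol(spectra, window: int = 15, polyorder: int = 2, deriv: int = 0,
           delta: float | None = None):
    """Savitzky-Golay smoothing / derivative along each spectrum.

    ``delta`` defaults to the absolute grid spacing when a
    :class:`SpectraSet` is given (so derivatives are per cm^-1), else 1.
    Edges are handled by polynomial extrapolation within the end windows.
    """
    X, tpl = _as_matrix(spectra)
    if window % 2 == 0 or window < 3:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    if polyorder >= window:
        raise ValueError(f"polyorder {polyorder} must be < window {window}")
    if deriv > polyorder:
        raise ValueError(f"derivative order {deriv} exceeds polyorder {polyorder}")
    if delta is None:
        delta = abs(float(tpl.grid[1] - tpl.grid[0])) if tpl is not None else 1.0
    out = savgol_filter(X, window_length=window, polyorder=polyorder,
                        deriv=deriv, delta=delta, axis=1, mode="interp")
    return _wrap(out, tpl)


@dataclass
class FittedTransform:
    """Constants learned on a training partition, reusable via :meth:`apply`."""

    method: str
    constants: dict = field(default_factory=dict)

    def apply(self, X):
        mat, tpl = _as_matrix(X)
        if self.method == "mean_center":
            out = mat - self.constants["mean"]
        elif self.method == "minmax":
            mn, mx = self.constants["min"], self.constants["max"]
            out = (mat - mn) / (mx - mn)
        elif self.method == "msc":
            out, _ = msc(mat, reference=self.constants["reference"])
        else:
            raise ValueError(f"unknown fitted method {self.method!r}")
        return _wrap(out, tpl)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "constants": {k: np.asarray(v).tolist() for k, v in self.constants.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedTransform":
        return cls(method=d["method"],
                   constants={k: np.asarray(v, dtype=float) for k, v in d["constants"].items()})


def fit_apply_scaler(train, apply_to=None, mode: str = "mean_center"):
    """Fit a column scaler on ``train`` and apply it to ``train`` and
    (optionally) ``apply_to`` with the *training* constants.

    mode='mean_center': train columns get mean 0.
    mode='minmax': train columns map exactly onto [0, 1]; applied values may
    fall outside that interval.
    """
    Xt, tpl_t = _as_matrix(train)
    if Xt.shape[0] == 0:
        raise ValueError("empty training matrix")
    if mode == "mean_center":
        ft = FittedTransform("mean_center", {"mean": Xt.mean(axis=0)})
    elif mode == "minmax":
        mn, mx = Xt.min(axis=0), Xt.max(axis=0)
        bad = np.flatnonzero(mx == mn)
        if bad.size:
            raise ValueError(f"constant column {bad[0]} under min-max scaling")
        ft = FittedTransform("minmax", {"min": mn, "max": mx})
    else:
        raise ValueError(f"unknown scaler mode {mode!r}")
    out_train = ft.apply(train)
    if apply_to is None:
        return out_train, ft
    return out_train, ft.apply(apply_to), ft


# ---------------------------------------------------------------------------
# Composable pre-treatment chains

_STATELESS = {"snv", "savgol"}
_STATEFUL = {"msc", "mean_center", "minmax"}


@dataclass
class Pretreatment:
    """An ordered pre-treatment chain, e.g. ``[("snv", {}), ("mean_center", {})]``.

    Steps are applied in list order; stateful steps learn their constants
    from the data passed to :meth:`fit` and never re-estimate them.
    """

    steps: list = field(default_factory=list)

    def __post_init__(self) -> None:
        norm = []
        for s in self.steps:
            if isinstance(s, str):
                norm.append((s, {}))
            else:
                name, params = s
                norm.append((name, dict(params)))
        for name, params in norm:
            if name not in _STATELESS | _STATEFUL:
                raise ValueError(f"unknown pre-treatment step {name!r}")
            if name == "savgol":
                w = params.get("window", 15)
                po = params.get("polyorder", 2)
                dv = params.get("deriv", 0)
                if w % 2 == 0 or po >= w or dv > po:
                    raise ValueError(f"invalid savgol parameters {params}")
        self.steps = norm

    @property
    def name(self) -> str:
        return "+".join(n for n, _ in self.steps) or "raw"

    def fit(self, train) -> "FittedPretreatment":
        fitted = []
        cur = train
        for name, params in self.steps:
            if name == "snv":
                cur = snv(cur)
                fitted.append((name, params, None))
            elif name == "savgol":
                cur = savgol(cur, **params)
                fitted.append((name, params, None))
            elif name == "msc":
                cur, ft = msc(cur, **params)
                fitted.append((name, params, ft))
            else:  # mean_center / minmax
                cur, ft = fit_apply_scaler(cur, mode=name)
                fitted.append((name, params, ft))
        return FittedPretreatment(steps=fitted, train_result=cur)


@dataclass
class FittedPretreatment:
    steps: list
    train_result: object = None

    def apply(self, X):
        cur = X
        for name, params, ft in self.steps:
            if ft is not None:
                cur = ft.apply(cur)
            elif name == "snv":
                cur = snv(cur)
            elif name == "savgol":
                cur = savgol(cur, **params)
        return cur

    def to_dict(self) -> dict:
        return {
            "steps": [
                {"name": n, "params": p, "fitted": (f.to_dict() if f is not None else None)}
                for n, p, f in self.steps
            ]
        }
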