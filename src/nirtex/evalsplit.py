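"""Kennard-Stone sample partitioning and calibration performance metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SplitResult", "FitMetrics", "kennard_stone", "metrics"]


@dataclass
class SplitResult:
    train: np.ndarray            # sorted train indices
    test: np.ndarray             # sorted test indices
    selection_order: np.ndarray  # train indices in the order picked

    def __post_init__(self):
        if np.intersect1d(self.train, self.test).size:
            raise ValueError("train and test sets overlap")


def kennard_stone(X: np.ndarray, fraction: float = 0.8) -> SplitResult:
    """Classical Kennard-Stone maximin selection of a calibration subset.

    The first two picks are the pair at maximal Euclidean distance; each
    subsequent pick maximizes its minimum distance to the already-selected
    set, until round(fraction * n) samples are selected.  Ties break to the
    lowest original index, so the split is deterministic and
    permutation-equivariant on duplicate-free data.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n_train = int(round(fraction * n))
    n_train = min(max(n_train, 2), n - 1)

    sq = np.sum(X ** 2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2 * X @ X.T
    np.maximum(d2, 0.0, out=d2)
    # farthest pair; lexicographically smallest (i, j) on ties
    iu = np.triu_indices(n, k=1)
    flat = d2[iu]
    best = np.argmax(flat)  # argmax returns the first maximum => lowest (i, j)
    i0, j0 = iu[0][best], iu[1][best]
    selected = [int(i0), int(j0)]
    in_model = np.zeros(n, dtype=bool)
    in_model[[i0, j0]] = True
    min_d = np.minimum(d2[:, i0], d2[:, j0])
    while len(selected) < n_train:
        min_d[in_model] = -np.inf
        k = int(np.argmax(min_d))  # first max => lowest index on ties
        selected.append(k)
        in_model[k] = True
        min_d = np.minimum(min_d, d2[:, k])
    train = np.sort(selected)
    test = np.setdiff1d(np.arange(n), train)
    return SplitResult(train=train, test=test,
                       selection_order=np.asarray(selected, dtype=int))


@dataclass
class FitMetrics:
    """Performance of predictions against reference values on one set.

    R² is the coefficient of determination 1 - SSE/SST (the squared Pearson
    correlation is carried alongside as ``r2_pearson``); RMSE and bias are
    in response units; SEP is the sample SD of the residuals; RPD is
    SD(reference)/SEP, with values above ~2 indicating a quantitatively
    useful calibration.  RMSE² = SEP²·(n-1)/n + bias² by construction.
    """

    r2: float
    rmse: float
    bias: float
    sep: float
    rpd: float
    n: int
    r2_pearson: float = float("nan")

    def __post_init__(self):
        if self.rmse < 0 or self.sep < 0:
            raise ValueError("RMSE and SEP must be >= 0")

    def to_dict(self) -> dict:
        return {"r2": self.r2, "rmse": self.rmse, "bias": self.bias,
                "sep": self.sep, "rpd": self.rpd, "n": self.n,
                "r2_pearson": self.r2_pearson}


def metrics(y_ref: np.ndarray, y_pred: np.ndarray) -> FitMetrics:
    """Evaluate predictions: R², RMSE, bias (predicted minus reference),
    SEP and RPD = SD(y_ref)/SEP."""
    y_ref = np.asarray(y_ref, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_ref.size != y_pred.size:
        raise ValueError("length mismatch")
    n = y_ref.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    if np.var(y_ref) == 0:
        raise ValueError("constant reference values")
    e = y_pred - y_ref
    bias = float(e.mean())
    rmse = float(np.sqrt(np.mean(e ** 2)))
    sep = float(e.std(ddof=1))
    sst = float(np.sum((y_ref - y_ref.mean()) ** 2))
    r2 = 1.0 - float(np.sum(e ** 2)) / sst
    if sep <= 1e-12 * rmse or sep == 0:
        # residuals numerically constant
        if rmse == 0:
            rpd = float("inf")  # perfect prediction
        else:
            raise ValueError("zero residual spread with nonzero bias: RPD undefined")
    else:
        rpd = float(y_ref.std(ddof=1)) / sep
    r = np.corrcoef(y_ref, y_pred)[0, 1] if y_pred.std() > 0 else np.nan
    return FitMetrics(r2=r2, rmse=rmse, bias=bias, sep=sep, rpd=rpd, n=n,
                      r2_pearson=float(r ** 2) if np.isfinite(r) else float("nan"))
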