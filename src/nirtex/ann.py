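"""Feed-forward neural network for spectral regression, in NumPy.

Architecture: input:hidden:output = (n+1) : ceil((n+1)/2) : 1 for n
predictors, with ReLU on the first two weighted layers, a linear output,
He-normal initialization, L1 regularization on the input and hidden
weights, Adam optimization of an MSE loss with MAE monitoring, and a
validation split whose best-loss epoch weights are restored after training.

The "+1" input unit is realized as an appended constant-1 column on the
(min-max scaled) predictor matrix, so the literal width rule holds; a
``plus_one='none'`` switch drops it.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["ANNSpec", "Network", "TrainingHistory", "build_ann", "train_ann",
           "predict_ann", "prepare_inputs"]


@dataclass
class ANNSpec:
    """Topology and training hyper-parameters.

    ``n_predictors`` is the number of real predictors (selected wavenumbers
    plus any appended factor such as diameter); the input width is
    n_predictors + 1 under the constant-column convention.
    """

    n_predictors: int
    plus_one: str = "constant"          # 'constant' | 'none'
    l1_lambda: float = 1e-4
    epochs: int = 1000
    batch_size: int = 32
    validation_split: float = 0.2
    seed: int = 0
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self):
        if self.n_predictors < 1:
            raise ValueError("need at least one predictor")
        if self.plus_one not in ("constant", "none"):
            raise ValueError("plus_one must be 'constant' or 'none'")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if not 0 < self.validation_split < 1:
            raise ValueError("validation_split must be in (0, 1)")

    @property
    def input_width(self) -> int:
        return self.n_predictors + (1 if self.plus_one == "constant" else 0)

    @property
    def hidden_width(self) -> int:
        return max(math.ceil(self.input_width / 2), 1)


@dataclass
class Network:
    """Three weighted dense layers; ReLU, ReLU, linear."""

    weights: list    # [(W1, b1), (W2, b2), (W3, b3)]
    spec: ANNSpec

    def forward(self, X: np.ndarray) -> np.ndarray:
        a = X
        for i, (W, b) in enumerate(self.weights):
            z = a @ W + b
            a = np.maximum(z, 0.0) if i < len(self.weights) - 1 else z
        return a.ravel()

    def copy_weights(self):
        return [(W.copy(), b.copy()) for W, b in self.weights]

    def save(self, path: str) -> None:
        arrays = {}
        for i, (W, b) in enumerate(self.weights):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        np.savez(path if path.endswith(".npz") else path + ".npz", **arrays)
        with open(path + ".json" if not path.endswith(".npz") else path[:-4] + ".json", "w") as fh:
            json.dump(asdict(self.spec), fh)


def build_ann(spec: ANNSpec) -> Network:
    """Build the network with seeded He-normal weights (SD = sqrt(2/fan_in))
    and zero biases."""
    rng = np.random.default_rng(spec.seed)
    widths = [spec.input_width, spec.input_width, spec.hidden_width, 1]
    weights = []
    for fan_in, fan_out in zip(widths[:-1], widths[1:]):
        W = rng.normal(0.0, math.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
        b = np.zeros(fan_out)
        weights.append((W, b))
    return Network(weights=weights, spec=spec)


def prepare_inputs(X: np.ndarray, spec: ANNSpec) -> np.ndarray:
    """Append the constant-1 input column when the spec asks for it."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != spec.n_predictors:
        raise ValueError(f"expected {spec.n_predictors} predictors, got {X.shape[1]}")
    if spec.plus_one == "constant":
        X = np.hstack([X, np.ones((X.shape[0], 1))])
    return X


@dataclass
class TrainingHistory:
    loss: np.ndarray
    mae: np.ndarray
    val_loss: np.ndarray
    val_mae: np.ndarray
    best_epoch: int

    def __post_init__(self):
        if self.best_epoch > self.loss.size:
            raise ValueError("best epoch beyond training length")


def train_ann(net: Network, X: np.ndarray, y: np.ndarray,
              spec: ANNSpec | None = None) -> TrainingHistory:
    """Train with Adam on MSE + L1 on the first two layers' weights.

    X must already carry the constant column when the spec uses one (see
    :func:`prepare_inputs`).  The validation split, batch shuffling and
    weight init all draw from the spec seed; weights at the best
    validation-loss epoch are restored at the end.
    """
    spec = spec or net.spec
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[1] != spec.input_width:
        raise ValueError(f"X has {X.shape[1]} columns, spec input width is {spec.input_width}")
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    n = X.shape[0]
    rng = np.random.default_rng(spec.seed + 1)
    perm = rng.permutation(n)
    n_val = max(int(round(spec.validation_split * n)), 1)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr, Xval, yval = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]
    ntr = Xtr.shape[0]

    params = [arr for Wb in net.weights for arr in Wb]
    m_adam = [np.zeros_like(p) for p in params]
    v_adam = [np.zeros_like(p) for p in params]
    step = 0

    loss_h, mae_h, vloss_h, vmae_h = [], [], [], []
    best_val = np.inf
    best_weights = net.copy_weights()
    best_epoch = 0

    lam = spec.l1_lambda
    for epoch in range(1, spec.epochs + 1):
        order = rng.permutation(ntr)
        for start in range(0, ntr, spec.batch_size):
            idx = order[start : start + spec.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            nb = xb.shape[0]
            (W1, b1), (W2, b2), (W3, b3) = net.weights
            z1 = xb @ W1 + b1
            a1 = np.maximum(z1, 0.0)
            z2 = a1 @ W2 + b2
            a2 = np.maximum(z2, 0.0)
            out = (a2 @ W3 + b3).ravel()
            err = out - yb
            # dL/dout for MSE = 2 err / nb
            g_out = (2.0 * err / nb)[:, None]
            gW3 = a2.T @ g_out
            gb3 = g_out.sum(axis=0)
            g_a2 = g_out @ W3.T
            g_z2 = g_a2 * (z2 > 0)
            gW2 = a1.T @ g_z2 + lam * np.sign(W2)
            gb2 = g_z2.sum(axis=0)
            g_a1 = g_z2 @ W2.T
            g_z1 = g_a1 * (z1 > 0)
            gW1 = xb.T @ g_z1 + lam * np.sign(W1)
            gb1 = g_z1.sum(axis=0)
            grads = [gW1, gb1, gW2, gb2, gW3, gb3]
            step += 1
            for p, g, mi, vi in zip(params, grads, m_adam, v_adam):
                mi *= spec.beta1
                mi += (1 - spec.beta1) * g
                vi *= spec.beta2
                vi += (1 - spec.beta2) * g * g
                mhat = mi / (1 - spec.beta1 ** step)
                vhat = vi / (1 - spec.beta2 ** step)
                p -= spec.learning_rate * mhat / (np.sqrt(vhat) + spec.eps)

        pred_tr = net.forward(Xtr)
        pred_val = net.forward(Xval)
        tl = float(np.mean((pred_tr - ytr) ** 2))
        vl = float(np.mean((pred_val - yval) ** 2))
        if not (np.isfinite(tl) and np.isfinite(vl)):
            raise RuntimeError(f"non-finite loss at epoch {epoch}")
        loss_h.append(tl)
        mae_h.append(float(np.mean(np.abs(pred_tr - ytr))))
        vloss_h.append(vl)
        vmae_h.append(float(np.mean(np.abs(pred_val - yval))))
        if vl < best_val:
            best_val = vl
            best_weights = net.copy_weights()
            best_epoch = epoch

    net.weights = best_weights
    return TrainingHistory(
        loss=np.array(loss_h), mae=np.array(mae_h),
        val_loss=np.array(vloss_h), val_mae=np.array(vmae_h),
        best_epoch=best_epoch,
    )


def predict_ann(net: Network, X_new: np.ndarray) -> np.ndarray:
    """Deterministic forward pass."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != net.weights[0][0].shape[0]:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, network expects "
            f"{net.weights[0][0].shape[0]}"
        )
    return net.forward(X_new)
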