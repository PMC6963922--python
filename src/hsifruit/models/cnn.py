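"""A small 1-D convolutional network on spectra, implemented in numpy.

Architecture (no padding anywhere):

    input (1 x L)
    Conv1D(64, k=3, s=1) -> ReLU -> MaxPool(2, 2) -> BatchNorm
    Conv1D(32, k=3, s=1) -> ReLU -> MaxPool(2, 2) -> BatchNorm
    flatten
    Dense(512) -> ReLU -> BatchNorm
    Dense(128) -> ReLU -> BatchNorm
    Dense(3)   -> softmax

Training minimizes softmax cross-entropy with plain SGD.  Inputs are
standardized per band with statistics of the calibration set.  The model
returned after training carries the parameters of the epoch with the best
validation accuracy.  Everything is deterministic under the spec seed.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..errors import ArchitectureError

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.9


@dataclass
class CNNSpec:
    conv_channels: tuple[int, int] = (64, 32)
    kernel_size: int = 3
    dense_units: tuple[int, int] = (512, 128)
    n_classes: int = 3
    learning_rate: float = 0.0005
    batch_size: int = 400
    epochs: int = 400
    seed: int = 0


def cnn_shape_arithmetic(input_length: int, kernel_size: int = 3) -> dict[str, int]:
    """Layer output lengths under the no-padding conv/pool stack."""
    c1 = input_length - (kernel_size - 1)
    p1 = c1 // 2
    c2 = p1 - (kernel_size - 1)
    p2 = c2 // 2
    return {
        "conv1": c1,
        "pool1": p1,
        "conv2": c2,
        "pool2": p2,
        "flatten": p2 * 32,
    }


def _he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


class _BatchNorm:
    """Batch normalization over the batch (and length, for conv activations)."""

    def __init__(self, n_channels: int):
        self.gamma = np.ones(n_channels)
        self.beta = np.zeros(n_channels)
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)

    def forward(self, x: np.ndarray, train: bool):
        # x is (n, C, L) or (n, C); normalize per channel C
        axes = (0, 2) if x.ndim == 3 else (0,)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = _BN_MOMENTUM * self.running_mean + (1 - _BN_MOMENTUM) * mean
            self.running_var = _BN_MOMENTUM * self.running_var + (1 - _BN_MOMENTUM) * var
        else:
            mean, var = self.running_mean, self.running_var
        shape = (1, -1, 1) if x.ndim == 3 else (1, -1)
        xhat = (x - mean.reshape(shape)) / np.sqrt(var.reshape(shape) + _BN_EPS)
        out = self.gamma.reshape(shape) * xhat + self.beta.reshape(shape)
        cache = (xhat, var, shape, axes, x.shape)
        return out, cache

    def backward(self, dout: np.ndarray, cache):
        xhat, var, shape, axes, x_shape = cache
        m = np.prod([x_shape[a] for a in axes])
        dgamma = (dout * xhat).sum(axis=axes)
        dbeta = dout.sum(axis=axes)
        inv_std = 1.0 / np.sqrt(var.reshape(shape) + _BN_EPS)
        dxhat = dout * self.gamma.reshape(shape)
        dx = (
            inv_std
            / m
            * (
                m * dxhat
                - dxhat.sum(axis=axes).reshape(shape)
                - xhat * (dxhat * xhat).sum(axis=axes).reshape(shape)
            )
        )
        return dx, dgamma, dbeta


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray):
    # x: (n, C_in, L); W: (C_out, C_in, k) -> out (n, C_out, L-k+1)
    k = W.shape[2]
    win = sliding_window_view(x, k, axis=2)  # (n, C_in, T, k)
    out = np.einsum("ocj,nctj->not", W, win, optimize=True) + b[None, :, None]
    return out, win


def _conv_backward(dout: np.ndarray, x_shape, win: np.ndarray, W: np.ndarray):
    dW = np.einsum("not,nctj->ocj", dout, win, optimize=True)
    db = dout.sum(axis=(0, 2))
    dx = np.zeros(x_shape)
    tmp = np.einsum("not,ocj->nctj", dout, W, optimize=True)
    T = dout.shape[2]
    for j in range(W.shape[2]):
        dx[:, :, j : j + T] += tmp[:, :, :, j]
    return dx, dW, db


def _pool_forward(x: np.ndarray):
    n, c, L = x.shape
    T = L // 2
    xr = x[:, :, : 2 * T].reshape(n, c, T, 2)
    idx = xr.argmax(axis=3)
    out = np.take_along_axis(xr, idx[..., None], axis=3)[..., 0]
    return out, (idx, x.shape)

def _pool_backward(dout: np.ndarray, cache):
    idx, x_shape = cache
    n, c, L = x_shape
    T = L // 2
    dxr = np.zeros((n, c, T, 2))
    np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=3)
    dx = np.zeros(x_shape)
    dx[:, :, : 2 * T] = dxr.reshape(n, c, 2 * T)
    return dx


class CNN1D:
    """The network plus its SGD training loop."""

    def __init__(self, spec: CNNSpec, input_length: int):
        if input_length < 11:
            sh = cnn_shape_arithmetic(input_length, spec.kernel_size)
            raise ArchitectureError(
                f"input length {input_length} too short: conv1 -> {sh['conv1']}, "
                f"pool1 -> {sh['pool1']}, conv2 -> {sh['conv2']}, "
                f"pool2 -> {sh['pool2']}; need input >= 11"
            )
        self.spec = spec
        self.input_length = input_length
        self.shapes = cnn_shape_arithmetic(input_length, spec.kernel_size)
        rng = np.random.default_rng(spec.seed)
        c1, c2 = spec.conv_channels
        k = spec.kernel_size
        d1, d2 = spec.dense_units
        flat = self.shapes["pool2"] * c2
        self.params: dict[str, np.ndarray] = {
            "Wc1": _he_uniform(rng, (c1, 1, k), fan_in=k),
            "bc1": np.zeros(c1),
            "Wc2": _he_uniform(rng, (c2, c1, k), fan_in=c1 * k),
            "bc2": np.zeros(c2),
            "Wd1": _he_uniform(rng, (flat, d1), fan_in=flat),
            "bd1": np.zeros(d1),
            "Wd2": _he_uniform(rng, (d1, d2), fan_in=d1),
            "bd2": np.zeros(d2),
            "Wd3": _he_uniform(rng, (d2, spec.n_classes), fan_in=d2),
            "bd3": np.zeros(spec.n_classes),
        }
        self.bn = {
            "bn1": _BatchNorm(c1),
            "bn2": _BatchNorm(c2),
            "bn3": _BatchNorm(d1),
            "bn4": _BatchNorm(d2),
        }
        self._rng = rng
        # per-band standardization, set at training time
        self.x_mean = np.zeros(input_length)
        self.x_std = np.ones(input_length)
        self.history: list[float] = []

    # ----------------------------------------------------------------- forward
    def _forward(self, X: np.ndarray, train: bool):
        p = self.params
        cache: dict = {}
        x = X[:, None, :]  # (n, 1, L)
        z1, win1 = _conv_forward(x, p["Wc1"], p["bc1"])
        a1 = np.maximum(z1, 0.0)
        pl1, pc1 = _pool_forward(a1)
        b1, bc1 = self.bn["bn1"].forward(pl1, train)
        z2, win2 = _conv_forward(b1, p["Wc2"], p["bc2"])
        a2 = np.maximum(z2, 0.0)
        pl2, pc2 = _pool_forward(a2)
        b2, bc2 = self.bn["bn2"].forward(pl2, train)
        flat = b2.reshape(b2.shape[0], -1)
        h1 = flat @ p["Wd1"] + p["bd1"]
        r1 = np.maximum(h1, 0.0)
        n1, nc1 = self.bn["bn3"].forward(r1, train)
        h2 = n1 @ p["Wd2"] + p["bd2"]
        r2 = np.maximum(h2, 0.0)
        n2, nc2 = self.bn["bn4"].forward(r2, train)
        logits = n2 @ p["Wd3"] + p["bd3"]
        cache.update(
            x=x, z1=z1, win1=win1, a1=a1, pc1=pc1, bc1=bc1, b1=b1,
            z2=z2, win2=win2, a2=a2, pc2=pc2, bc2=bc2, b2=b2,
            flat=flat, h1=h1, nc1=nc1, n1=n1, h2=h2, nc2=nc2, n2=n2,
        )
        return logits, cache

    def _backward(self, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        p = self.params
        g: dict[str, np.ndarray] = {}
        g["Wd3"] = cache["n2"].T @ dlogits
        g["bd3"] = dlogits.sum(axis=0)
        dn2 = dlogits @ p["Wd3"].T
        dr2, g["g4"], g["b4"] = self.bn["bn4"].backward(dn2, cache["nc2"])
        dh2 = dr2 * (cache["h2"] > 0)
        g["Wd2"] = cache["n1"].T @ dh2
        g["bd2"] = dh2.sum(axis=0)
        dn1 = dh2 @ p["Wd2"].T
        dr1, g["g3"], g["b3"] = self.bn["bn3"].backward(dn1, cache["nc1"])
        dh1 = dr1 * (cache["h1"] > 0)
        g["Wd1"] = cache["flat"].T @ dh1
        g["bd1"] = dh1.sum(axis=0)
        dflat = dh1 @ p["Wd1"].T
        db2 = dflat.reshape(cache["b2"].shape)
        dpl2, g["g2"], g["b2"] = self.bn["bn2"].backward(db2, cache["bc2"])
        da2 = _pool_backward(dpl2, cache["pc2"])
        dz2 = da2 * (cache["z2"] > 0)
        db1, g["Wc2"], g["bc2"] = _conv_backward(dz2, cache["b1"].shape, cache["win2"], p["Wc2"])
        dpl1, g["g1"], g["b1"] = self.bn["bn1"].backward(db1, cache["bc1"])
        da1 = _pool_backward(dpl1, cache["pc1"])
        dz1 = da1 * (cache["z1"] > 0)
        _, g["Wc1"], g["bc1"] = _conv_backward(dz1, cache["x"].shape, cache["win1"], p["Wc1"])
        return g

    def _apply_gradients(self, g: dict[str, np.ndarray]) -> None:
        lr = self.spec.learning_rate
        for key in ("Wc1", "bc1", "Wc2", "bc2", "Wd1", "bd1", "Wd2", "bd2", "Wd3", "bd3"):
            self.params[key] -= lr * g[key]
        for bn_key, gk, bk in (("bn1", "g1", "b1"), ("bn2", "g2", "b2"),
                               ("bn3", "g3", "b3"), ("bn4", "g4", "b4")):
            self.bn[bn_key].gamma -= lr * g[gk]
            self.bn[bn_key].beta -= lr * g[bk]

    # ------------------------------------------------------------------ public
    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.x_mean) / self.x_std

    def train(
        self,
        X_cal: np.ndarray,
        y_cal: np.ndarray,
        X_val: np.ndarray,
        y_val: np.ndarray,
        epochs: int | None = None,
    ) -> "CNN1D":
        """SGD training; keeps the epoch-best parameters on validation."""
        spec = self.spec
        epochs = spec.epochs if epochs is None else epochs
        X_cal = np.asarray(X_cal, float)
        y_cal = np.asarray(y_cal, int)
        self.x_mean = X_cal.mean(axis=0)
        self.x_std = X_cal.std(axis=0)
        self.x_std[self.x_std < 1e-12] = 1.0
        Xc = self._standardize(X_cal)
        Xv = self._standardize(X_val)
        y_val = np.asarray(y_val, int)
        n = Xc.shape[0]
        batch = spec.batch_size
        if batch > n:
            warnings.warn(f"batch_size {batch} > {n} calibration samples; clamping", stacklevel=2)
            batch = n
        onehot = np.eye(spec.n_classes)[y_cal]
        best_acc, best_state = -1.0, None
        self.history = []
        for _ in range(epochs):
            perm = self._rng.permutation(n)
            for start in range(0, n, batch):
                sel = perm[start : start + batch]
                logits, cache = self._forward(Xc[sel], train=True)
                logits = logits - logits.max(axis=1, keepdims=True)
                probs = np.exp(logits)
                probs /= probs.sum(axis=1, keepdims=True)
                dlogits = (probs - onehot[sel]) / sel.size
                grads = self._backward(dlogits, cache)
                self._apply_gradients(grads)
            val_acc = float(np.mean(self._predict_standardized(Xv) == y_val))
            self.history.append(val_acc)
            if val_acc > best_acc:
                best_acc = val_acc
                best_state = (
                    copy.deepcopy(self.params),
                    copy.deepcopy({k: vars(v).copy() for k, v in self.bn.items()}),
                )
        if best_state is not None:
            self.params = best_state[0]
            for k, state in best_state[1].items():
                vars(self.bn[k]).update(state)
        return self

    def _predict_standardized(self, Xs: np.ndarray) -> np.ndarray:
        logits, _ = self._forward(Xs, train=False)
        return np.argmax(logits, axis=1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted origin codes."""
        return self._predict_standardized(self._standardize(X))

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits, _ = self._forward(self._standardize(X), train=False)
        logits = logits - logits.max(axis=1, keepdims=True)
        probs = np.exp(logits)
        return probs / probs.sum(axis=1, keepdims=True)


def cnn_build(spec: CNNSpec, input_length: int) -> CNN1D:
    """Validate the length arithmetic and construct the network."""
    return CNN1D(spec, input_length)
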