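"""Minimal CNN engine on numpy: layers, losses, Adam, training callbacks.

This is a compact, deterministic neural-network kernel sized for the
small convolutional models this package trains. Data layout is NHWC,
parameters are float32, convolutions are stride-1 'same' implemented via
``sliding_window_view`` + ``tensordot`` (forward), with the input gradient
computed as a correlation with the spatially flipped kernel. All randomness
(initialization, dropout) flows through an explicit ``numpy`` generator, so
training runs are bit-reproducible on a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer", "Conv2D", "Dense", "BatchNorm", "LeakyReLU", "ReLU",
    "MaxPool2", "Upsample2", "Dropout", "GlobalAvgPool", "Adam",
    "sigmoid", "bce_with_logits", "huber_loss",
    "ReduceLROnPlateau", "EarlyStopping",
]

_F = np.float32


# ---------------------------------------------------------------------------
# Layers


class Layer:
    """Base layer: ``params``/``grads`` dicts plus forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(xp: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """Contiguous patch matrix (N*H*W, kh*kw*Ci) from a padded NHWC input."""
    patches = sliding_window_view(xp, (kh, kw), axis=(1, 2))  # N,H,W,Ci,kh,kw
    n, h, w = patches.shape[:3]
    p2 = patches.transpose(0, 1, 2, 4, 5, 3)  # N,H,W,kh,kw,Ci
    return np.ascontiguousarray(p2).reshape(n * h * w, -1)


def _conv_same(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Stride-1 'same' correlation: x (N,H,W,Ci), w (kh,kw,Ci,Co)."""
    kh, kw, c_in, c_out = w.shape
    if kh == kw == 1:
        return (x.reshape(-1, c_in) @ w.reshape(c_in, c_out)).reshape(
            x.shape[:3] + (c_out,)
        )
    xp = np.pad(x, ((0, 0), (kh // 2, kh // 2), (kw // 2, kw // 2), (0, 0)))
    p2 = _im2col(xp, kh, kw)
    return (p2 @ w.reshape(-1, c_out)).reshape(x.shape[:3] + (c_out,))


class Conv2D(Layer):
    """3×3 (or 1×1) stride-1 'same' convolution with He-normal init.

    Implemented as im2col + GEMM; the input gradient is scattered back with
    nine shifted in-place adds (the col2im adjoint), avoiding a second large
    patch materialization.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / (kernel * kernel * c_in))
        self.params["w"] = (rng.standard_normal((kernel, kernel, c_in, c_out)) * std).astype(_F)
        self.params["b"] = np.zeros(c_out, dtype=_F)

    def forward(self, x, training=False):
        self._x = x
        return _conv_same(x, self.params["w"]) + self.params["b"]

    def backward(self, dout):
        w = self.params["w"]
        kh, kw, c_in, c_out = w.shape
        n, h, wd = self._x.shape[:3]
        df = dout.reshape(-1, c_out)
        self.grads["b"] = df.sum(axis=0).astype(_F)
        if kh == kw == 1:
            xf = self._x.reshape(-1, c_in)
            self.grads["w"] = (xf.T @ df).reshape(w.shape).astype(_F)
            dx = (df @ w.reshape(c_in, c_out).T).reshape(self._x.shape)
            del self._x
            return dx.astype(_F)
        ph, pw = kh // 2, kw // 2
        xp = np.pad(self._x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
        p2 = _im2col(xp, kh, kw)
        self.grads["w"] = (p2.T @ df).reshape(w.shape).astype(_F)
        del p2, self._x
        # input gradient = correlation of dout with the flipped kernel
        w_flip = np.ascontiguousarray(w[::-1, ::-1].transpose(0, 1, 3, 2))
        return _conv_same(dout, w_flip)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / n_in)
        self.params["w"] = (rng.standard_normal((n_in, n_out)) * std).astype(_F)
        self.params["b"] = np.zeros(n_out, dtype=_F)

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dout):
        self.grads["w"] = (self._x.T @ dout).astype(_F)
        self.grads["b"] = dout.sum(axis=0).astype(_F)
        return (dout @ self.params["w"].T).astype(_F)


class BatchNorm(Layer):
    """Batch normalization over all axes but the last (channel) axis."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.params["gamma"] = np.ones(channels, dtype=_F)
        self.params["beta"] = np.zeros(channels, dtype=_F)
        self.running_mean = np.zeros(channels, dtype=_F)
        self.running_var = np.ones(channels, dtype=_F)
        self.momentum, self.eps = momentum, eps

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                self.momentum * self.running_mean + (1 - self.momentum) * mean
            ).astype(_F)
            self.running_var = (
                self.momentum * self.running_var + (1 - self.momentum) * var
            ).astype(_F)
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = (1.0 / np.sqrt(var + self.eps)).astype(_F)
        self._xhat = ((x - mean) * self._inv_std).astype(_F)
        self._training = training
        return self.params["gamma"] * self._xhat + self.params["beta"]

    def backward(self, dout):
        axes = tuple(range(dout.ndim - 1))
        n = dout.size // dout.shape[-1]
        self.grads["gamma"] = (dout * self._xhat).sum(axis=axes).astype(_F)
        self.grads["beta"] = dout.sum(axis=axes).astype(_F)
        g = self.params["gamma"] * self._inv_std
        if not self._training:
            return (dout * g).astype(_F)
        dxhat = dout * self.params["gamma"]
        dx = self._inv_std * (
            dxhat
            - dxhat.mean(axis=axes)
            - self._xhat * (dxhat * self._xhat).mean(axis=axes)
        )
        del self._xhat
        return dx.astype(_F)


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.1):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, training=False):
        self._neg = x < 0
        return np.where(self._neg, self.alpha * x, x)

    def backward(self, dout):
        return np.where(self._neg, self.alpha * dout, dout)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(alpha=0.0)


class MaxPool2(Layer):
    """2×2 max pooling; spatial dims must be even."""

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        flat = xr.transpose(0, 1, 3, 5, 2, 4).reshape(n, h // 2, w // 2, c, 4)
        self._arg = flat.argmax(axis=-1)
        self._shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dout):
        n, h2, w2, c = dout.shape
        dflat = np.zeros((n, h2, w2, c, 4), dtype=_F)
        np.put_along_axis(dflat, self._arg[..., None], dout[..., None], axis=-1)
        dx = dflat.reshape(n, h2, w2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return dx.reshape(self._shape)


class Upsample2(Layer):
    """2×2 nearest-neighbor upsampling."""

    def forward(self, x, training=False):
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dout):
        n, h, w, c = dout.shape
        return dout.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4)).astype(_F)


class Dropout(Layer):
    """Inverted dropout driven by an explicit generator."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate, self.rng = rate, rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.uniform(size=x.shape) < keep).astype(_F) / keep
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class GlobalAvgPool(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        n, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :] / (h * w), self._shape).astype(_F)


# ---------------------------------------------------------------------------
# Losses


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=_F)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Numerically stable mean binary cross-entropy; returns (loss, dlogits)."""
    z, t = logits.astype(_F), targets.astype(_F)
    loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
    grad = (sigmoid(z) - t) / z.size
    return float(loss.mean()), grad.astype(_F)


def huber_loss(pred: np.ndarray, target: np.ndarray, delta: float = 1.0) -> tuple[float, np.ndarray]:
    """Mean Huber loss (quadratic within ``delta``, linear outside)."""
    err = pred.astype(_F) - target.astype(_F)
    a = np.abs(err)
    quad = a <= delta
    loss = np.where(quad, 0.5 * err**2, delta * (a - 0.5 * delta))
    grad = np.where(quad, err, delta * np.sign(err)) / err.size
    return float(loss.mean()), grad.astype(_F)


# ---------------------------------------------------------------------------
# Optimizer and schedule callbacks


class Adam:
    """Adam over the parameters of a list of layers."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1t, b2t = 1 - self.b1**self.t, 1 - self.b2**self.t
        for li, layer in enumerate(self.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                self.m[li][k] = self.b1 * self.m[li][k] + (1 - self.b1) * g
                self.v[li][k] = self.b2 * self.v[li][k] + (1 - self.b2) * g * g
                mhat = self.m[li][k] / b1t
                vhat = self.v[li][k] / b2t
                p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(_F)


class ReduceLROnPlateau:
    """Halve (by ``factor``) the LR after ``patience`` epochs w/o improvement."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 5,
                 mode: str = "max", min_delta: float = 1e-6):
        self.opt, self.factor, self.patience = optimizer, factor, patience
        self.sign = 1.0 if mode == "max" else -1.0
        self.min_delta = min_delta
        self.best = -np.inf
        self.wait = 0

    def on_epoch_end(self, metric: float) -> bool:
        """Returns True when the LR was reduced this epoch."""
        if self.sign * metric > self.best + self.min_delta:
            self.best = self.sign * metric
            self.wait = 0
            return False
        self.wait += 1
        if self.wait >= self.patience:
            self.opt.lr *= self.factor
            self.wait = 0
            return True
        return False


class EarlyStopping:
    """Stop after ``patience`` epochs without improvement; keeps best weights."""

    def __init__(self, layers: list[Layer], patience: int = 5, mode: str = "max",
                 restore_best: bool = True, min_delta: float = 1e-6):
        self.layers = layers
        self.patience, self.restore_best = patience, restore_best
        self.sign = 1.0 if mode == "max" else -1.0
        self.min_delta = min_delta
        self.best = -np.inf
        self.best_epoch = -1
        self.wait = 0
        self._snapshot: list[dict[str, np.ndarray]] | None = None
        self._bn_stats: list[tuple[np.ndarray, np.ndarray]] | None = None

    def on_epoch_end(self, metric: float, epoch: int) -> bool:
        """Returns True when training should stop."""
        if self.sign * metric > self.best + self.min_delta:
            self.best = self.sign * metric
            self.best_epoch = epoch
            self.wait = 0
            self._snapshot = [
                {k: v.copy() for k, v in l.params.items()} for l in self.layers
            ]
            self._bn_stats = [
                (l.running_mean.copy(), l.running_var.copy())
                if isinstance(l, BatchNorm) else (None, None)
                for l in self.layers
            ]
            return False
        self.wait += 1
        return self.wait >= self.patience

    def restore(self) -> None:
        if self.restore_best and self._snapshot is not None:
            for layer, snap, bn in zip(self.layers, self._snapshot, self._bn_stats):
                for k in layer.params:
                    layer.params[k][...] = snap[k]
                if isinstance(layer, BatchNorm):
                    layer.running_mean[...] = bn[0]
                    layer.running_var[...] = bn[1]

    @property
    def best_metric(self) -> float:
        return self.sign * self.best


def weights_digest(layers: list[Layer]) -> str:
    """Stable hex digest of all parameters (for frozen-weight contracts)."""
    import hashlib

    h = hashlib.sha256()
    for layer in layers:
        for k in sorted(layer.params):
            h.update(np.ascontiguousarray(layer.params[k]).tobytes())
    return h.hexdigest()
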