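"""Minimal 1-D convolutional network primitives in NumPy.

Implements exactly the layer set the fall detector needs — 1-D convolution
with same-padding, batch normalization, ReLU, non-overlapping max pooling,
dropout, a fully-connected head and softmax cross-entropy — each with an
explicit backward pass, plus stochastic gradient descent with momentum and L2
weight decay.  All randomness flows through explicitly passed
``numpy.random.Generator`` objects so training is bit-reproducible.

Layers are stateful: ``forward`` caches whatever ``backward`` needs, so a
layer instance serves one forward/backward pair at a time (single-threaded
training), which is all the trainer requires.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "MaxPool1d",
    "Dropout",
    "Flatten",
    "Linear",
    "softmax",
    "softmax_cross_entropy",
    "SGDMomentum",
]


class Layer:
    """Base layer: no parameters, identity behaviour hooks."""

    def parameters(self) -> list[dict]:
        """Parameter slots as dicts with keys value/grad/decay."""
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1d(Layer):
    """1-D convolution (cross-correlation), stride 1, symmetric zero-padding.

    Input ``(B, C_in, W)`` → output ``(B, C_out, W)`` when ``pad == (k-1)/2``.
    Weights are He-initialized (ReLU follows every convolution here).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 5, pad: int = 2,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        fan_in = c_in * kernel
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel))
        self.b = np.zeros(c_out)
        self.kernel, self.pad = kernel, pad
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x_windows: np.ndarray | None = None

    def parameters(self) -> list[dict]:
        return [
            {"value": self.w, "grad": lambda: self.dw, "decay": True},
            {"value": self.b, "grad": lambda: self.db, "decay": False},
        ]

    def out_width(self, w: int) -> int:
        return w + 2 * self.pad - self.kernel + 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        win = sliding_window_view(xp, self.kernel, axis=2)  # (B, C_in, W_out, k)
        self._x_windows = win if train else None
        return np.einsum("bcwk,ock->bow", win, self.w, optimize=True) + self.b[:, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        win = self._x_windows
        self.db = dy.sum(axis=(0, 2))
        self.dw = np.einsum("bow,bcwk->ock", dy, win, optimize=True)
        # transpose conv = correlation of dy with the flipped kernels
        dyp = np.pad(dy, ((0, 0), (0, 0), (self.kernel - 1 - self.pad,) * 2))
        dywin = sliding_window_view(dyp, self.kernel, axis=2)
        return np.einsum("bowk,ock->bcw", dywin, self.w[:, :, ::-1], optimize=True)


class BatchNorm1d(Layer):
    """Per-channel batch normalization over the batch and time axes."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.eps, self.momentum = eps, momentum
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self._cache: tuple | None = None

    def parameters(self) -> list[dict]:
        return [
            {"value": self.gamma, "grad": lambda: self.dgamma, "decay": False},
            {"value": self.beta, "grad": lambda: self.dbeta, "decay": False},
        ]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[:, None]) * inv_std[:, None]
        if train:
            self._cache = (xhat, inv_std)
        return self.gamma[:, None] * xhat + self.beta[:, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        n = dy.shape[0] * dy.shape[2]
        self.dgamma = np.sum(dy * xhat, axis=(0, 2))
        self.dbeta = dy.sum(axis=(0, 2))
        # standard batch-norm gradient with mean/variance dependence
        t = n * dy - self.dbeta[:, None] - xhat * self.dgamma[:, None]
        return (self.gamma * inv_std)[:, None] / n * t


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling: width ``w → floor(w / size)``.

    A remainder shorter than ``size`` at the tail is dropped, matching the
    floor rule.  An input already narrower than ``size`` is pooled as a single
    region (output width 1) so the fixed four-block architecture also accepts
    the very short windows produced by low sampling rates.
    """

    def __init__(self, size: int = 5):
        self.size = size

    def out_width(self, w: int) -> int:
        return max(1, w // self.size)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        b, c, w = x.shape
        size = self.size if w >= self.size else w
        n_out = w // size
        x_trim = x[:, :, : n_out * size].reshape(b, c, n_out, size)
        self._argmax = np.argmax(x_trim, axis=3)
        self._in_shape = x.shape
        self._size = size
        return np.max(x_trim, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, w = self._in_shape
        n_out = dy.shape[2]
        dx = np.zeros((b, c, n_out, self._size))
        bi, ci, wi = np.ogrid[:b, :c, :n_out]
        dx[bi, ci, wi, self._argmax] = dy
        out = np.zeros(self._in_shape)
        out[:, :, : n_out * self._size] = dx.reshape(b, c, n_out * self._size)
        return out


class Dropout(Layer):
    """Inverted dropout; active only during training."""

    def __init__(self, rate: float = 0.5):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng: np.random.Generator = np.random.default_rng()
        self._mask: np.ndarray | float = 1.0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = 1.0
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Linear(Layer):
    """Fully-connected layer.

    ``init='he'`` suits hidden ReLU layers; ``init='zero'`` suits a softmax
    classifier head, which then starts from indifference between the classes
    instead of a random initial preference the optimizer must first unlearn.
    """

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None,
                 init: str = "he"):
        rng = rng or np.random.default_rng()
        if init == "he":
            self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in))
        elif init == "zero":
            self.w = np.zeros((n_out, n_in))
        else:
            raise ValueError(f"unknown init {init!r}")
        self.b = np.zeros(n_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def parameters(self) -> list[dict]:
        return [
            {"value": self.w, "grad": lambda: self.dw, "decay": True},
            {"value": self.b, "grad": lambda: self.db, "decay": False},
        ]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x if train else None
        return x @ self.w.T + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dw = dy.T @ self._x
        self.db = dy.sum(axis=0)
        return dy @ self.w


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of integer labels and its gradient w.r.t. logits."""
    p = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -np.mean(np.log(p[np.arange(n), labels] + eps))
    grad = p.copy()
    grad[np.arange(n), labels] -= 1.0
    return float(loss), grad / n


class SGDMomentum:
    """Stochastic gradient descent with classical momentum and L2 decay.

    ``v ← μ·v − lr·(g + λ·w)``; ``w ← w + v``.  Weight decay applies only to
    convolution and fully-connected weights, never to biases or batch-norm
    affine parameters (each parameter slot declares its own ``decay`` flag).
    """

    def __init__(self, params: list[dict], lr: float, momentum: float = 0.9,
                 l2: float = 0.0):
        self.params = params
        self.lr, self.momentum, self.l2 = lr, momentum, l2
        self._velocity = [np.zeros_like(p["value"]) for p in params]

    def step(self) -> None:
        for p, v in zip(self.params, self._velocity):
            g = p["grad"]()
            if p["decay"] and self.l2 > 0:
                g = g + self.l2 * p["value"]
            v *= self.momentum
            v -= self.lr * g
            p["value"] += v
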