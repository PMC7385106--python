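"""Minimal seeded convolutional-network engine (numpy, CPU).

Implements exactly the pieces the MLI regressor needs — 5x5 same-padding
convolutions, ReLU, 2x2 max-pooling, a linear head, mean-squared-error
loss and Adam — with hand-written backward passes.  Inputs are tiny
(``D x D`` with ``D`` around 8), so im2col-style windowing with ``einsum``
is plenty fast and keeps every operation bit-deterministic.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Conv2dSame:
    """2-D convolution, stride 1, padding ``k // 2`` (output size = input)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        fan_in = in_ch * kernel * kernel
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), (out_ch, in_ch, kernel, kernel))
        self.b = np.zeros(out_ch)
        self.kernel = kernel
        self._cols: np.ndarray | None = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = sliding_window_view(xp, (self.kernel, self.kernel), axis=(2, 3))
        self._cols = cols
        out = np.einsum("bchwij,ocij->bohw", cols, self.w, optimize=True)
        return out + self.b[None, :, None, None]

    def backward(self, grad: np.ndarray):
        self.dw = np.einsum("bchwij,bohw->ocij", self._cols, grad, optimize=True)
        self.db = grad.sum(axis=(0, 2, 3))
        p = self.kernel // 2
        gp = np.pad(grad, ((0, 0), (0, 0), (p, p), (p, p)))
        gcols = sliding_window_view(gp, (self.kernel, self.kernel), axis=(2, 3))
        wf = self.w[:, :, ::-1, ::-1]
        return np.einsum("bohwij,ocij->bchw", gcols, wf, optimize=True)

    @property
    def grads(self):
        return [self.dw, self.db]


class ReLU:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class MaxPool2:
    """2x2 max pooling; on ties the gradient routes to the first maximum."""

    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(b, c, h // 2, w // 2, 4)
        self._argmax = flat.argmax(axis=-1)
        self._shape = x.shape
        return flat.max(axis=-1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        onehot = np.eye(4)[self._argmax]  # (b, c, h/2, w/2, 4)
        flat = onehot * grad[..., None]
        xr = flat.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return xr.reshape(b, c, h, w)


class Flatten:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Linear:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), (n_in, n_out))
        self.b = np.zeros(n_out)

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w + self.b

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.dw = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.w.T

    @property
    def grads(self):
        return [self.dw, self.db]


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights) -> None:
        params = self.params
        if len(weights) != len(params):
            raise ValueError("weight list does not match the architecture")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError("weight shapes do not match the architecture")
            p[...] = w


class Adam:
    """Adam with bias correction (the standard defaults)."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. ``pred``."""
    diff = pred - target
    return float(np.mean(diff * diff)), 2.0 * diff / diff.size
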