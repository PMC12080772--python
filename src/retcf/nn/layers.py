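"""Minimal neural-network layers in numpy with hand-written backprop.

Every layer keeps the forward cache it needs on ``self`` so that
``backward`` can be called (repeatedly, with different cotangents) after a
single ``forward``.  ``backward(dy, param_grads=False)`` skips the weight
gradients, which is the mode used during guided sampling where only the
input gradient is needed.  All math is float32.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("v", "g")

    def __init__(self, v: np.ndarray):
        self.v = np.asarray(v, dtype=np.float32)
        self.g = np.zeros_like(self.v)

    def zero_grad(self) -> None:
        self.g[...] = 0.0


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class SiLU:
    """x * sigmoid(x); cache-free derivative from the stored input."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._s = sigmoid(x)
        self._x = x
        return x * self._s

    def backward(self, dy: np.ndarray) -> np.ndarray:
        s = self._s
        return dy * (s * (1.0 + self._x * (1.0 - s)))


class Conv2d:
    """3x3 (or kxk) same-padding convolution via im2col."""

    def __init__(self, cin: int, cout: int, k: int = 3, rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        self.cin, self.cout, self.k = cin, cout, k
        fan_in = cin * k * k
        if zero_init:
            w = np.zeros((cout, fan_in), dtype=np.float32)
        else:
            rng = rng or np.random.default_rng(0)
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, fan_in)).astype(np.float32)
        self.W = Param(w)
        self.b = Param(np.zeros(cout, dtype=np.float32))

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        cols = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))  # n,c,h,w,k,k
        cols = np.ascontiguousarray(cols.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * self.k * self.k)
        self._cols = cols
        self._xshape = x.shape
        y = cols @ self.W.v.T + self.b.v
        return np.ascontiguousarray(y.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2))

    def backward(self, dy: np.ndarray, param_grads: bool = True) -> np.ndarray:
        n, c, h, w = self._xshape
        k, p = self.k, self.k // 2
        dyr = np.ascontiguousarray(dy.transpose(0, 2, 3, 1)).reshape(n * h * w, self.cout)
        if param_grads:
            self.W.g += dyr.T @ self._cols
            self.b.g += dyr.sum(axis=0)
        dcols = (dyr @ self.W.v).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w]


class Dense:
    def __init__(self, din: int, dout: int, rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((dout, din), dtype=np.float32)
        else:
            rng = rng or np.random.default_rng(0)
            w = rng.normal(0.0, np.sqrt(2.0 / din), size=(dout, din)).astype(np.float32)
        self.W = Param(w)
        self.b = Param(np.zeros(dout, dtype=np.float32))

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.v.T + self.b.v

    def backward(self, dy: np.ndarray, param_grads: bool = True) -> np.ndarray:
        if param_grads:
            self.W.g += dy.T @ self._x
            self.b.g += dy.sum(axis=0)
        return dy @ self.W.v


class AvgPool2:
    """2x2 average pooling, stride 2."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._shape = x.shape
        return x.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        up = np.repeat(np.repeat(dy, 2, axis=2), 2, axis=3)
        return (up * 0.25).astype(np.float32)


class MaxPool2:
    """2x2 max pooling, stride 2 (argmax-routed backward)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._shape = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        self._arg = xr.argmax(axis=-1)
        return xr.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        out = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(out, self._arg[..., None], dy[..., None], axis=-1)
        out = out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return out.reshape(n, c, h, w)


class Upsample2:
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=axis, keepdims=True))


def sinusoidal_embedding(t: np.ndarray, dim: int, max_period: float = 10000.0) -> np.ndarray:
    """Transformer-style timestep embedding, shape (len(t), dim)."""
    half = dim // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half, dtype=np.float32) / half)
    args = np.asarray(t, dtype=np.float32)[:, None] * freqs[None, :]
    return np.concatenate([np.cos(args), np.sin(args)], axis=1).astype(np.float32)


class Adam:
    def __init__(self, params: list[Param], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p.v) for p in params]
        self.s = [np.zeros_like(p.v) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, s in zip(self.params, self.m, self.s):
            m *= self.b1
            m += (1 - self.b1) * p.g
            s *= self.b2
            s += (1 - self.b2) * p.g ** 2
            p.v -= self.lr * (m / b1t) / (np.sqrt(s / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


class SGDMomentum:
    """SGD with classical momentum; learning rate is set per-step by the caller
    (cosine decay lives in the training loop)."""

    def __init__(self, params: list[Param], lr: float = 0.01, momentum: float = 0.9):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.buf = [np.zeros_like(p.v) for p in params]

    def step(self) -> None:
        for p, b in zip(self.params, self.buf):
            b *= self.momentum
            b += p.g
            p.v -= self.lr * b

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
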