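"""Layer primitives with hand-written backward passes (float32, NCHW)."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable tensor with its gradient and Adam moment buffers."""

    __slots__ = ("v", "g", "m", "s")

    def __init__(self, value: np.ndarray):
        self.v = np.ascontiguousarray(value, dtype=np.float32)
        self.g = np.zeros_like(self.v)
        self.m = np.zeros_like(self.v)
        self.s = np.zeros_like(self.v)


class Conv2d:
    """k x k convolution, stride 1, 'same' padding, via im2col."""

    def __init__(self, cin: int, cout: int, k: int = 3, bias: bool = False,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (cin * k * k))
        self.W = Param(rng.normal(0.0, std, size=(cout, cin * k * k)))
        self.b = Param(np.zeros(cout)) if bias else None
        self.cin, self.cout, self.k = cin, cout, k
        self._cache = None

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])

    def buffers(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.k, self.k // 2
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        # (N, C, H, W, k, k) -> (N*H*W, C*k*k)
        win = sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * k * k)
        out = cols @ self.W.v.T
        if self.b is not None:
            out += self.b.v
        self._cache = (cols, (n, c, h, w)) if train else None
        return np.ascontiguousarray(out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, (n, c, h, w) = self._cache
        k, p = self.k, self.k // 2
        dr = np.ascontiguousarray(dout.transpose(0, 2, 3, 1)).reshape(n * h * w, self.cout)
        self.W.g += dr.T @ cols
        if self.b is not None:
            self.b.g += dr.sum(axis=0)
        dcols = (dr @ self.W.v).reshape(n, h, w, c, k, k).transpose(0, 3, 4, 5, 1, 2)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for di in range(k):
            for dj in range(k):
                dxp[:, :, di:di + h, dj:dj + w] += dcols[:, :, di, dj]
        self._cache = None
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class ConvTranspose2:
    """2 x 2 transpose convolution with stride 2 (doubles H and W)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / cin)
        self.W = Param(rng.normal(0.0, std, size=(cin, cout, 2, 2)))
        self._x = None

    def params(self):
        return [self.W]

    def buffers(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        t = np.einsum("nchw,cdij->ndhiwj", x, self.W.v)
        self._x = x if train else None
        return np.ascontiguousarray(t.reshape(n, self.W.v.shape[1], 2 * h, 2 * w))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, d, h2, w2 = dout.shape
        dt = dout.reshape(n, d, h2 // 2, 2, w2 // 2, 2)
        self.W.g += np.einsum("nchw,ndhiwj->cdij", self._x, dt)
        dx = np.einsum("ndhiwj,cdij->nchw", dt, self.W.v)
        self._x = None
        return np.ascontiguousarray(dx)


class BatchNorm2d:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return self.gamma.v[None, :, None, None] * xhat + self.beta.v[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        n, c, h, w = dout.shape
        m = n * h * w
        self.gamma.g += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.g += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.v[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        dx = (inv[None, :, None, None] / m) * (m * dxhat - s1 - xhat * s2)
        self._cache = None
        return dx.astype(np.float32)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mask = x > 0
        if train:
            self._mask = mask
        return np.where(mask, x, 0.0).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = np.where(self._mask, dout, 0.0).astype(np.float32)
        self._mask = None
        return dx


class MaxPool2:
    """2 x 2 max pooling with stride 2."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        if train:
            winners = xr == out[:, :, :, None, :, None]
            self._cache = (winners, (n, c, h, w))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        winners, (n, c, h, w) = self._cache
        dx = winners * dout[:, :, :, None, :, None]
        self._cache = None
        return dx.reshape(n, c, h, w).astype(np.float32)


def softmax_cross_entropy(logits: np.ndarray, targets: np.ndarray):
    """Mean pixel-wise cross-entropy and its gradient w.r.t. the logits.

    ``logits`` (N, K, H, W) float, ``targets`` (N, H, W) integer class indices.
    """
    n, k, h, w = logits.shape
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    pick = np.take_along_axis(z, targets[:, None, :, :], axis=1)[:, 0]
    lse = np.log(ez.sum(axis=1))
    loss = float((lse - pick).mean())
    dlogits = p.copy()
    # each (n, h, w) position indexes a unique element, so plain fancy indexing is safe
    i0 = np.arange(n)[:, None, None]
    i2 = np.arange(h)[None, :, None]
    i3 = np.arange(w)[None, None, :]
    dlogits[i0, targets, i2, i3] -= 1.0
    dlogits /= n * h * w
    return loss, dlogits.astype(np.float32)


class Adam:
    def __init__(self, params, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.g[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p in self.params:
            p.m[...] = self.b1 * p.m + (1.0 - self.b1) * p.g
            p.s[...] = self.b2 * p.s + (1.0 - self.b2) * p.g**2
            p.v -= self.lr * (p.m / b1t) / (np.sqrt(p.s / b2t) + self.eps)
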