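"""Layers with hand-derived backward passes (float32, NCHW)."""

from __future__ import annotations

import numpy as np

from ..errors import ConfigError

F32 = np.float32


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value.astype(F32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return int(self.value.size)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(F32)


class Conv2D(Layer):
    """3x3 (or 1x1) same-padding convolution via im2col + GEMM."""

    def __init__(self, cin: int, cout: int, ksize: int, rng: np.random.Generator, name: str = "conv"):
        if ksize % 2 != 1:
            raise ConfigError("Conv2D expects an odd kernel size (same padding)")
        self.cin, self.cout, self.k = cin, cout, ksize
        self.pad = ksize // 2
        self.W = Param(f"{name}.W", _he_init(rng, (cout, cin, ksize, ksize), cin * ksize * ksize))
        self.b = Param(f"{name}.b", np.zeros(cout, dtype=F32))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training):
        n, c, h, w = x.shape
        k, p = self.k, self.pad
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        # win: (n, c, h, w, k, k) -> col: (n*h*w, c*k*k)
        col = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k).astype(F32)
        self._col, self._xshape = col, x.shape
        wmat = self.W.value.reshape(self.cout, -1)
        y = col @ wmat.T + self.b.value
        return y.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, gout):
        n, _, h, w = self._xshape
        k, p, c = self.k, self.pad, self.cin
        gy = gout.transpose(0, 2, 3, 1).reshape(n * h * w, self.cout).astype(F32)
        wmat = self.W.value.reshape(self.cout, -1)
        self.W.grad += (gy.T @ self._col).reshape(self.W.value.shape)
        self.b.grad += gy.sum(axis=0)
        gcol = gy @ wmat  # (n*h*w, c*k*k)
        gcol = gcol.reshape(n, h, w, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        gxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=F32)
        for di in range(k):
            for dj in range(k):
                gxp[:, :, di:di + h, dj:dj + w] += gcol[:, :, :, :, di, dj]
        self._col = None
        return gxp[:, :, p:p + h, p:p + w] if p else gxp


class ConvTranspose2D(Layer):
    """2x2 stride-2 learned up-convolution (doubles H and W)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str = "upconv"):
        self.cin, self.cout = cin, cout
        self.W = Param(f"{name}.W", _he_init(rng, (cin, cout, 2, 2), cin))
        self.b = Param(f"{name}.b", np.zeros(cout, dtype=F32))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training):
        self._x = x
        n, c, h, w = x.shape
        t = np.einsum("nchw,cokl->nohkwl", x, self.W.value, optimize=True)
        y = t.reshape(n, self.cout, 2 * h, 2 * w) + self.b.value[None, :, None, None]
        return y.astype(F32)

    def backward(self, gout):
        x = self._x
        n, c, h, w = x.shape
        gt = gout.reshape(n, self.cout, h, 2, w, 2)
        self.W.grad += np.einsum("nchw,nohkwl->cokl", x, gt, optimize=True)
        self.b.grad += gout.sum(axis=(0, 2, 3))
        gx = np.einsum("nohkwl,cokl->nchw", gt, self.W.value, optimize=True)
        self._x = None
        return gx.astype(F32)


class BatchNorm2D(Layer):
    """Batch normalization over (N, H, W) per channel.

    ``momentum`` follows the Keras convention:
    running = momentum * running + (1 - momentum) * batch.
    """

    def __init__(self, c: int, momentum: float = 0.6, eps: float = 1e-3, name: str = "bn"):
        self.c, self.momentum, self.eps = c, momentum, eps
        self.gamma = Param(f"{name}.gamma", np.ones(c, dtype=F32))
        self.beta = Param(f"{name}.beta", np.zeros(c, dtype=F32))
        self.running_mean = np.zeros(c, dtype=F32)
        self.running_var = np.ones(c, dtype=F32)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = (m * self.running_mean + (1 - m) * mean).astype(F32)
            self.running_var = (m * self.running_var + (1 - m) * var).astype(F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat.astype(F32), inv.astype(F32), training, x.shape)
        return (self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]).astype(F32)

    def backward(self, gout):
        xhat, inv, training, shape = self._cache
        n_eff = shape[0] * shape[2] * shape[3]
        self.gamma.grad += (gout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += gout.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        if not training:
            return (gout * g * inv[None, :, None, None]).astype(F32)
        gxhat = gout * g
        term = (
            gxhat
            - gxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (gxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / n_eff
        )
        self._cache = None
        return (term * inv[None, :, None, None]).astype(F32)


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return np.where(self._mask, x, 0).astype(F32)

    def backward(self, gout):
        g = np.where(self._mask, gout, 0).astype(F32)
        self._mask = None
        return g


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ConfigError("dropout rate must be in [0, 1)")
        self.rate, self.rng = rate, rng
        self._mask = None

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(F32) / keep
        return (x * self._mask).astype(F32)

    def backward(self, gout):
        if self._mask is None:
            return gout
        g = (gout * self._mask).astype(F32)
        self._mask = None
        return g


class MaxPool2x2(Layer):
    def forward(self, x, training):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        win = xr.reshape(n, c, h // 2, w // 2, 4)
        self._arg = win.argmax(axis=-1)
        self._shape = x.shape
        return win.max(axis=-1).astype(F32)

    def backward(self, gout):
        n, c, h, w = self._shape
        g4 = np.zeros((n, c, h // 2, w // 2, 4), dtype=F32)
        np.put_along_axis(g4, self._arg[..., None], gout[..., None].astype(F32), axis=-1)
        gx = g4.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        self._arg = None
        return gx.reshape(n, c, h, w)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class SEBlock(Layer):
    """Squeeze-and-excitation channel gating.

    Global average pooling squeezes each channel to a scalar; a bottleneck
    C -> floor(C/r) -> C with ReLU then sigmoid produces per-channel gates in
    (0, 1) that rescale the input map.
    """

    def __init__(self, c: int, r: int, rng: np.random.Generator, name: str = "se"):
        if c < r:
            raise ConfigError(f"SE reduction r={r} exceeds channel count C={c}")
        self.c, self.r = c, r
        cr = max(1, c // r)
        self.cr = cr
        self.W1 = Param(f"{name}.W1", _he_init(rng, (c, cr), c))
        self.b1 = Param(f"{name}.b1", np.zeros(cr, dtype=F32))
        self.W2 = Param(f"{name}.W2", _he_init(rng, (cr, c), cr))
        self.b2 = Param(f"{name}.b2", np.zeros(c, dtype=F32))

    def params(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def forward(self, x, training):
        s0 = x.mean(axis=(2, 3))                      # (n, c) squeeze
        z1 = s0 @ self.W1.value + self.b1.value
        a1 = np.maximum(z1, 0.0)
        z2 = a1 @ self.W2.value + self.b2.value
        s = _sigmoid(z2)                              # (n, c) gates
        self._cache = (x, s0, z1, a1, s)
        return (x * s[:, :, None, None]).astype(F32)

    def backward(self, gout):
        x, s0, z1, a1, s = self._cache
        hw = x.shape[2] * x.shape[3]
        gx = gout * s[:, :, None, None]
        gs = (gout * x).sum(axis=(2, 3))
        gz2 = gs * s * (1.0 - s)
        self.W2.grad += a1.T @ gz2
        self.b2.grad += gz2.sum(axis=0)
        ga1 = gz2 @ self.W2.value.T
        gz1 = ga1 * (z1 > 0)
        self.W1.grad += s0.T @ gz1
        self.b1.grad += gz1.sum(axis=0)
        gs0 = gz1 @ self.W1.value.T
        gx = gx + gs0[:, :, None, None] / hw
        self._cache = None
        return gx.astype(F32)
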