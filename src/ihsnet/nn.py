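"""Minimal numpy layer library with manual backpropagation.

Implements exactly the pieces the MUNet architecture needs -- 2-D
convolution (im2col), batch normalization, leaky ReLU, fully connected
layers, x2 upsampling, global average pooling -- plus the Adam
optimizer.  All computation is float32 NCHW.  Every layer caches what
its backward pass needs during ``forward`` and releases it on
``backward``; forward in eval mode is a pure function of (weights,
input).
"""

from __future__ import annotations

import numpy as np


class Param:
    """A learnable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int, stride: int, pad: int):
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    n, c, hp, wp = x.shape
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]  # (n, c, ho, wo, k, k)
    cols = np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(
        n, c * k * k, ho * wo
    )
    return cols, ho, wo


def _col2im(dcols, x_shape, k, stride, pad, ho, wo):
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    dcols = dcols.reshape(n, c, k, k, ho, wo)
    for a in range(k):
        for b in range(k):
            dxp[:, :, a : a + ho * stride : stride, b : b + wo * stride : stride] += (
                dcols[:, :, a, b]
            )
    if pad:
        return dxp[:, :, pad : pad + h, pad : pad + w]
    return dxp


class Conv2d(Layer):
    """k x k convolution, He-initialized, same-padding by default."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int = 3,
        stride: int = 1,
        pad: int | None = None,
        rng: np.random.Generator | None = None,
        bias: bool = True,
    ):
        rng = rng or np.random.default_rng(0)
        self.k = kernel
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad
        fan_in = in_channels * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Param(rng.normal(0.0, std, size=(out_channels, fan_in)))
        self.bias = Param(np.zeros(out_channels)) if bias else None
        self._cache = None

    def params(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x, train=False):
        x = np.ascontiguousarray(x, dtype=np.float32)
        cols, ho, wo = _im2col(x, self.k, self.stride, self.pad)
        y = np.matmul(self.weight.value, cols)
        if self.bias is not None:
            y += self.bias.value[:, None]
        self._cache = (cols, x.shape, ho, wo) if train else None
        return y.reshape(x.shape[0], -1, ho, wo)

    def backward(self, dy):
        cols, x_shape, ho, wo = self._cache
        self._cache = None
        n = x_shape[0]
        dyf = dy.reshape(n, -1, ho * wo)
        self.weight.grad += np.matmul(dyf, cols.transpose(0, 2, 1)).sum(axis=0)
        if self.bias is not None:
            self.bias.grad += dyf.sum(axis=(0, 2))
        dcols = np.matmul(self.weight.value.T, dyf)
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad, ho, wo)


# ---------------------------------------------------------------------------
# batch normalization
# ---------------------------------------------------------------------------

class BatchNorm2d(Layer):
    """Per-channel batch normalization over batch and spatial positions.

    Training mode normalizes with the batch statistics and updates
    exponential running statistics (momentum 0.1 by default); eval mode
    uses the running statistics.
    """

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.eps = eps
        self.momentum = momentum
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def _moments(self, x):
        axes = (0, 2, 3) if x.ndim == 4 else (0,)
        return x.mean(axis=axes), x.var(axis=axes), axes

    @staticmethod
    def _expand(v, ndim):
        return v[None, :, None, None] if ndim == 4 else v[None, :]

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=np.float32)
        if train:
            mean, var, axes = self._moments(x)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._expand(mean, x.ndim)) * self._expand(inv_std, x.ndim)
        y = self._expand(self.gamma.value, x.ndim) * xhat + self._expand(
            self.beta.value, x.ndim
        )
        if train:
            self._cache = (xhat, inv_std)
        return y.astype(np.float32)

    def backward(self, dy):
        xhat, inv_std = self._cache
        self._cache = None
        ndim = dy.ndim
        axes = (0, 2, 3) if ndim == 4 else (0,)
        m = float(np.prod([dy.shape[a] for a in axes]))
        self.gamma.grad += (dy * xhat).sum(axis=axes)
        self.beta.grad += dy.sum(axis=axes)
        dxhat = dy * self._expand(self.gamma.value, ndim)
        term = (
            dxhat
            - self._expand(dxhat.mean(axis=axes), ndim)
            - xhat * self._expand((dxhat * xhat).mean(axis=axes), ndim)
        )
        return (term * self._expand(inv_std, ndim)).astype(np.float32)


def batchnorm_apply(
    x: np.ndarray,
    gamma: np.ndarray | float = 1.0,
    beta: np.ndarray | float = 0.0,
    eps: float = 1e-12,
) -> np.ndarray:
    """Functional batch normalization with the batch's own statistics.

    Convolutional inputs (N, C, H, W) are normalized jointly over batch
    and spatial positions; 2-D inputs (N, C) over the batch.  Scaling
    the input by any positive scalar leaves the output unchanged.
    """
    x = np.asarray(x, dtype=np.float64)
    axes = (0, 2, 3) if x.ndim == 4 else (0,)
    mean = x.mean(axis=axes, keepdims=True)
    var = x.var(axis=axes, keepdims=True)
    xhat = (x - mean) / np.sqrt(var + eps)
    g = np.asarray(gamma, dtype=np.float64)
    b = np.asarray(beta, dtype=np.float64)
    if x.ndim == 4 and g.ndim == 1:
        g, b = g[None, :, None, None], b[None, :, None, None]
    return g * xhat + b


# ---------------------------------------------------------------------------
# activations and simple layers
# ---------------------------------------------------------------------------

class LeakyReLU(Layer):
    """max(0, x) plus ``slope`` * x on the negative side."""

    def __init__(self, slope: float = 0.001):
        self.slope = slope
        self._mask = None

    def forward(self, x, train=False):
        mask = x >= 0
        if train:
            self._mask = mask
        return np.where(mask, x, self.slope * x).astype(np.float32)

    def backward(self, dy):
        mask = self._mask
        self._mask = None
        return np.where(mask, dy, self.slope * dy).astype(np.float32)


def relu(x: np.ndarray) -> np.ndarray:
    """Plain rectifier y = max(0, x)."""
    return np.maximum(0.0, x)


def leaky_relu(x: np.ndarray, slope: float = 0.001) -> np.ndarray:
    return np.where(x >= 0, x, slope * x)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng=None):
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / in_features)
        self.weight = Param(rng.normal(0.0, std, size=(out_features, in_features)))
        self.bias = Param(np.zeros(out_features))
        self._x = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x, train=False):
        x = np.asarray(x, dtype=np.float32)
        if train:
            self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dy):
        x = self._x
        self._x = None
        self.weight.grad += dy.T @ x
        self.bias.grad += dy.sum(axis=0)
        return (dy @ self.weight.value).astype(np.float32)


class Upsample2x(Layer):
    """x2 spatial upsampling, bilinear (half-pixel centers) or nearest.

    Implemented as separable interpolation matrices so the backward pass
    is their exact transpose.
    """

    _matrices: dict[tuple[int, str], np.ndarray] = {}

    def __init__(self, mode: str = "bilinear"):
        if mode not in ("bilinear", "nearest"):
            raise ValueError(f"unknown upsample mode {mode!r}")
        self.mode = mode
        self._shape = None

    @classmethod
    def _matrix(cls, n: int, mode: str) -> np.ndarray:
        key = (n, mode)
        if key not in cls._matrices:
            a = np.zeros((2 * n, n), dtype=np.float32)
            for i in range(2 * n):
                if mode == "nearest":
                    a[i, i // 2] = 1.0
                else:
                    src = min(max((i + 0.5) / 2.0 - 0.5, 0.0), n - 1.0)
                    i0 = int(np.floor(src))
                    i1 = min(i0 + 1, n - 1)
                    w = src - i0
                    a[i, i0] += 1.0 - w
                    a[i, i1] += w
            cls._matrices[key] = a
        return cls._matrices[key]

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        if train:
            self._shape = x.shape
        ah = self._matrix(h, self.mode)
        aw = self._matrix(w, self.mode)
        flat = x.reshape(n * c, h, w)
        y = np.matmul(np.matmul(ah, flat), aw.T)
        return y.reshape(n, c, 2 * h, 2 * w).astype(np.float32)

    def backward(self, dy):
        n, c, h, w = self._shape
        self._shape = None
        ah = self._matrix(h, self.mode)
        aw = self._matrix(w, self.mode)
        flat = dy.reshape(n * c, 2 * h, 2 * w)
        dx = np.matmul(np.matmul(ah.T, flat), aw)
        return dx.reshape(n, c, h, w).astype(np.float32)


class GlobalAvgPool(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x, train=False):
        if train:
            self._shape = x.shape
        return x.mean(axis=(2, 3)).astype(np.float32)

    def backward(self, dy):
        n, c, h, w = self._shape
        self._shape = None
        return np.broadcast_to(
            dy[:, :, None, None] / (h * w), (n, c, h, w)
        ).astype(np.float32)


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with the conventional betas (0.9, 0.999) and eps 1e-8."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
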