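"""Minimal CPU neural-network engine: layers, backprop and Adam.

Everything operates on float32 NHWC arrays (batch, height, width,
channels) — the layout that keeps the frequent 1x1 convolutions and the
batch-norm reductions contiguous on CPU.  Each layer is a :class:`Module`
that caches what its backward pass needs during ``forward`` and returns
the gradient with respect to its input from ``backward``.

Convolutions are stride-1 with "same" padding (the architecture only
needs odd kernels: 1x1, 3x3, 1x3, 3x1) and are evaluated by im2col +
matmul; the input gradient is itself a convolution with the spatially
flipped, channel-transposed kernel, which keeps the engine free of
scatter-add on the hot path.  Patch extraction and max-pooling run as
numba kernels.

Weight initialisation is He-uniform driven by an explicit
``numpy.random.Generator``, so a seeded build is bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = [
    "Parameter",
    "Module",
    "Sequential",
    "Conv2d",
    "ConvTranspose2x2",
    "UpsampleConv2x",
    "MaxPool2x2",
    "MaxPool3x3Same",
    "BatchNorm2d",
    "ReLU",
    "Sigmoid",
    "Adam",
]


# ---------------------------------------------------------------------------
# numba kernels (NHWC)


@njit(cache=True, fastmath=False)
def _im2col_kernel(xp, kh, kw, h, w, out):
    """xp is the already zero-padded input (n, h+kh-1, w+kw-1, c)."""
    n = xp.shape[0]
    c = xp.shape[3]
    for ni in range(n):
        for i in range(h):
            for j in range(w):
                col = 0
                base = (ni * h + i) * w + j
                for u in range(kh):
                    for v in range(kw):
                        for ci in range(c):
                            out[base, col] = xp[ni, i + u, j + v, ci]
                            col += 1


@njit(cache=True)
def _maxpool2_fwd(x, out, idx):
    n, h, w, c = x.shape
    for ni in range(n):
        for i in range(h // 2):
            for j in range(w // 2):
                for ci in range(c):
                    best = x[ni, 2 * i, 2 * j, ci]
                    bk = 0
                    for k in range(1, 4):
                        v = x[ni, 2 * i + k // 2, 2 * j + k % 2, ci]
                        if v > best:
                            best = v
                            bk = k
                    out[ni, i, j, ci] = best
                    idx[ni, i, j, ci] = bk


@njit(cache=True)
def _maxpool2_bwd(grad, idx, dx):
    n, h2, w2, c = grad.shape
    for ni in range(n):
        for i in range(h2):
            for j in range(w2):
                for ci in range(c):
                    k = idx[ni, i, j, ci]
                    dx[ni, 2 * i + k // 2, 2 * j + k % 2, ci] = grad[ni, i, j, ci]


@njit(cache=True)
def _bn_stats(flat):
    m, c = flat.shape
    mean = np.zeros(c, dtype=np.float64)
    for i in range(m):
        for j in range(c):
            mean[j] += flat[i, j]
    mean /= m
    var = np.zeros(c, dtype=np.float64)
    for i in range(m):
        for j in range(c):
            d = flat[i, j] - mean[j]
            var[j] += d * d
    var /= m
    return mean, var


@njit(cache=True)
def _bn_fwd(flat, mean, inv, gamma, beta, relu, out, xhat):
    m, c = flat.shape
    for i in range(m):
        for j in range(c):
            xh = (flat[i, j] - mean[j]) * inv[j]
            xhat[i, j] = xh
            y = gamma[j] * xh + beta[j]
            if relu and y < 0.0:
                y = 0.0
            out[i, j] = y


@njit(cache=True)
def _bn_bwd(g, xhat, out, gamma, inv, relu, dgamma, dbeta, dx):
    m, c = g.shape
    gsum = np.zeros(c, dtype=np.float64)
    gx = np.zeros(c, dtype=np.float64)
    for i in range(m):
        for j in range(c):
            gi = g[i, j]
            if relu and out[i, j] <= 0.0:
                gi = 0.0
                g[i, j] = 0.0
            dgamma[j] += gi * xhat[i, j]
            dbeta[j] += gi
            gsum[j] += gi * gamma[j]
            gx[j] += gi * gamma[j] * xhat[i, j]
    for i in range(m):
        for j in range(c):
            dx[i, j] = (g[i, j] * gamma[j] - gsum[j] / m - xhat[i, j] * gx[j] / m) * inv[j]


@njit(cache=True)
def _maxpool3_fwd(xp, out, idx):
    """xp is padded by one pixel with -inf on the spatial borders."""
    n, h, w, c = out.shape
    for ni in range(n):
        for i in range(h):
            for j in range(w):
                for ci in range(c):
                    best = xp[ni, i, j, ci]
                    bk = 0
                    for k in range(1, 9):
                        v = xp[ni, i + k // 3, j + k % 3, ci]
                        if v > best:
                            best = v
                            bk = k
                    out[ni, i, j, ci] = best
                    idx[ni, i, j, ci] = bk


@njit(cache=True)
def _maxpool3_bwd(grad, idx, dxp):
    """dxp is padded by one pixel; caller slices the interior."""
    n, h, w, c = grad.shape
    for ni in range(n):
        for i in range(h):
            for j in range(w):
                for ci in range(c):
                    k = idx[ni, i, j, ci]
                    dxp[ni, i + k // 3, j + k % 3, ci] += grad[ni, i, j, ci]


# ---------------------------------------------------------------------------
# module framework


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Module:
    """Base class: forward caches, backward consumes the cache."""

    training: bool = True

    def parameters(self) -> list[Parameter]:
        return []

    def train(self, mode: bool = True) -> None:
        self.training = mode
        for child in self.children():
            child.train(mode)

    def eval(self) -> None:
        self.train(False)

    def children(self) -> list["Module"]:
        return []

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def children(self) -> list[Module]:
        return self.layers

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


def he_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, H, W, C) -> (N*H*W, kh*kw*C) same-padded patch matrix."""
    n, h, w, c = x.shape
    if kh == 1 and kw == 1:  # channel mixing only: rows are already patches
        return x.reshape(n * h * w, c)
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    out = np.empty((n * h * w, kh * kw * c), dtype=np.float32)
    _im2col_kernel(xp, kh, kw, h, w, out)
    return out


class Conv2d(Module):
    """Stride-1 same-padding convolution for odd kernel sizes.

    The kernel is stored as ``(kh*kw*in_channels, out_channels)`` so the
    forward pass is a single patch-matrix multiply.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: tuple[int, int] | int,
        rng: np.random.Generator,
        bias: bool = True,
    ):
        if in_channels < 1 or out_channels < 1:
            raise ValueError("channel counts must be >= 1")
        kh, kw = (kernel_size, kernel_size) if isinstance(kernel_size, int) else kernel_size
        if kh % 2 == 0 or kw % 2 == 0:
            raise ValueError("same-padding convolution requires odd kernel sizes")
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kh, self.kw = kh, kw
        fan_in = in_channels * kh * kw
        self.weight = Parameter(he_uniform(rng, (fan_in, out_channels), fan_in), "conv.w")
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32), "conv.b") if bias else None
        self._cols: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {c}")
        cols = _im2col(x, self.kh, self.kw)
        out = cols @ self.weight.value
        if self.bias is not None:
            out += self.bias.value
        if self.training:
            self._cols = cols
        return out.reshape(n, h, w, self.out_channels)

    def _kernel_flipped(self) -> np.ndarray:
        """Kernel for the input-gradient convolution: spatially flipped,
        in/out channels swapped, shape (kh*kw*out, in)."""
        w4 = self.weight.value.reshape(self.kh, self.kw, self.in_channels, self.out_channels)
        wf = w4[::-1, ::-1].transpose(0, 1, 3, 2)  # flip space, swap channels
        return np.ascontiguousarray(wf).reshape(self.kh * self.kw * self.out_channels, self.in_channels)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, co = grad.shape
        g = grad.reshape(-1, co)
        self.weight.grad += self._cols.T @ g
        if self.bias is not None:
            self.bias.grad += g.sum(axis=0)
        self._cols = None
        gcols = _im2col(np.ascontiguousarray(grad, dtype=np.float32), self.kh, self.kw)
        dx = gcols @ self._kernel_flipped()
        return dx.reshape(n, h, w, self.in_channels)


class ConvTranspose2x2(Module):
    """2x upsampling transposed convolution, kernel 2x2, stride 2.

    With a 2x2 kernel and stride 2 the output windows do not overlap, so
    the whole operation is one matmul followed by a pixel-shuffle:
    ``out[n, 2i+u, 2j+v, co] = sum_ci x[n, i, j, ci] W[ci, u, v, co]``.
    """

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        self.in_channels, self.out_channels = in_channels, out_channels
        self.weight = Parameter(
            he_uniform(rng, (in_channels, 2 * 2 * out_channels), in_channels), "upconv.w"
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=np.float32), "upconv.b")
        self._x: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        y = (x.reshape(-1, c) @ self.weight.value).reshape(n, h, w, 2, 2, self.out_channels)
        out = np.ascontiguousarray(y.transpose(0, 1, 3, 2, 4, 5)).reshape(
            n, 2 * h, 2 * w, self.out_channels
        )
        out += self.bias.value
        if self.training:
            self._x = x
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h2, w2, co = grad.shape
        h, w = h2 // 2, w2 // 2
        g = grad.reshape(n, h, 2, w, 2, co).transpose(0, 1, 3, 2, 4, 5)
        g = np.ascontiguousarray(g).reshape(n * h * w, 4 * co)
        self.weight.grad += self._x.reshape(-1, self.in_channels).T @ g
        self.bias.grad += grad.reshape(-1, co).sum(axis=0)
        dx = g @ self.weight.value.T
        self._x = None
        return dx.reshape(n, h, w, self.in_channels)


class UpsampleConv2x(Module):
    """Nearest-neighbour 2x upsampling followed by a 3x3 convolution —
    the checkerboard-free alternative to a transposed convolution."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        self.conv = Conv2d(in_channels, out_channels, 3, rng)
        self.in_channels, self.out_channels = in_channels, out_channels

    def children(self) -> list[Module]:
        return [self.conv]

    def parameters(self) -> list[Parameter]:
        return self.conv.parameters()

    def forward(self, x: np.ndarray) -> np.ndarray:
        up = x.repeat(2, axis=1).repeat(2, axis=2)
        return self.conv.forward(up)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dup = self.conv.backward(grad)
        n, h2, w2, c = dup.shape
        return dup.reshape(n, h2 // 2, 2, w2 // 2, 2, c).sum(axis=(2, 4))


class MaxPool2x2(Module):
    """2x2 max-pooling with stride 2."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        out = np.empty((n, h // 2, w // 2, c), dtype=x.dtype)
        idx = np.empty((n, h // 2, w // 2, c), dtype=np.int8)
        _maxpool2_fwd(x, out, idx)
        if self.training:
            self._idx, self._in_shape = idx, x.shape
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._in_shape, dtype=grad.dtype)
        _maxpool2_bwd(np.ascontiguousarray(grad), self._idx, dx)
        self._idx = None
        return dx


class MaxPool3x3Same(Module):
    """3x3 max-pooling with stride 1 and same padding (inception pool branch)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)), constant_values=-np.inf)
        out = np.empty_like(x)
        idx = np.empty(x.shape, dtype=np.int8)
        _maxpool3_fwd(xp, out, idx)
        if self.training:
            self._idx = idx
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, h, w, c = grad.shape
        dxp = np.zeros((n, h + 2, w + 2, c), dtype=grad.dtype)
        _maxpool3_bwd(np.ascontiguousarray(grad), self._idx, dxp)
        self._idx = None
        return dxp[:, 1:-1, 1:-1, :]


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics.

    ``relu=True`` fuses the ReLU that always follows batch-norm in this
    architecture into the same kernel pass.
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5, relu: bool = False):
        self.gamma = Parameter(np.ones(channels, dtype=np.float32), "bn.gamma")
        self.beta = Parameter(np.zeros(channels, dtype=np.float32), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum, self.eps = momentum, eps
        self.channels = channels
        self.relu = relu

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray) -> np.ndarray:
        flat = np.ascontiguousarray(x, dtype=np.float32).reshape(-1, x.shape[-1])
        if self.training:
            mean, var = _bn_stats(flat)
            self.running_mean = (self.momentum * self.running_mean + (1 - self.momentum) * mean).astype(np.float32)
            self.running_var = (self.momentum * self.running_var + (1 - self.momentum) * var).astype(np.float32)
        else:
            mean = self.running_mean.astype(np.float64)
            var = self.running_var.astype(np.float64)
        inv = 1.0 / np.sqrt(var + self.eps)
        out = np.empty_like(flat)
        xhat = np.empty_like(flat) if self.training else out  # dummy target in eval
        _bn_fwd(flat, mean, inv, self.gamma.value, self.beta.value, self.relu, out, xhat)
        if self.training:
            self._xhat, self._inv, self._out = xhat, inv, out
        return out.reshape(x.shape)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = np.ascontiguousarray(grad, dtype=np.float32).reshape(-1, grad.shape[-1])
        dgamma = np.zeros(self.channels, dtype=np.float64)
        dbeta = np.zeros(self.channels, dtype=np.float64)
        dx = np.empty_like(g)
        _bn_bwd(g, self._xhat, self._out, self.gamma.value, self._inv, self.relu, dgamma, dbeta, dx)
        self.gamma.grad += dgamma.astype(np.float32)
        self.beta.grad += dbeta.astype(np.float32)
        self._xhat = self._out = None
        return dx.reshape(grad.shape)


class ReLU(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if self.training:
            self._pos = x > 0
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dx = grad * self._pos
        self._pos = None
        return dx


class Sigmoid(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        out = 1.0 / (1.0 + np.exp(-x))
        self._out = out
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        dx = grad * self._out * (1.0 - self._out)
        self._out = None
        return dx


class Adam:
    """Adam optimiser over a list of :class:`Parameter`."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
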