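"""Minimal reverse-mode layer library for small 3D convolutional networks.

All layers operate on single samples laid out channel-first as
``(C, H, W, D)`` float32 arrays; mini-batching is realised by the training
loops as gradient accumulation over samples.  Convolutions are evaluated as
im2col + BLAS matrix products, which is the fastest pure-numpy route for the
volume sizes this package targets.

Batch normalisation computes its statistics per sample over the spatial
voxels of each channel (the single-image formulation used by differentiable
feature clustering).  This makes evaluation deterministic and independent of
batch composition, at the cost of not tracking running averages.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "xavier_uniform",
    "Conv3d",
    "ReLU",
    "ChannelNorm",
    "MaxPool2x",
    "UpsampleNearest2x",
    "Sequential",
    "SGD",
    "Adam",
]


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)


def xavier_uniform(shape, fan_in: int, fan_out: int, rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv3d:
    """3D convolution (cross-correlation), stride 1, 'same' zero padding, odd kernel.

    Evaluated as one GEMM per kernel offset against a strided slice of the
    zero-padded input, which keeps the working set small (no unfolded column
    matrix); the backward pass is the exact adjoint of the same decomposition.
    """

    def __init__(self, c_in: int, c_out: int, kernel_size: int, rng: np.random.Generator):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for 'same' padding")
        if c_in < 1 or c_out < 1:
            raise ValueError("channel counts must be >= 1")
        self.c_in, self.c_out, self.k = c_in, c_out, kernel_size
        k3 = kernel_size ** 3
        self.w = Param(xavier_uniform((c_out, c_in) + (kernel_size,) * 3, c_in * k3, c_out * k3, rng))
        self.b = Param(np.zeros(c_out, dtype=np.float32))
        self._xp: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def _offsets(self):
        k = self.k
        for a in range(k):
            for b in range(k):
                for c in range(k):
                    yield a, b, c

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        c_in, h, w_, d = x.shape
        p = self.k // 2
        xp = np.pad(x.astype(np.float32, copy=False), ((0, 0), (p, p), (p, p), (p, p)))
        n = h * w_ * d
        y = np.zeros((self.c_out, n), dtype=np.float32)
        buf = np.empty((c_in, n), dtype=np.float32)
        for a, b, c in self._offsets():
            buf.reshape(c_in, h, w_, d)[...] = xp[:, a:a + h, b:b + w_, c:c + d]
            y += self.w.value[:, :, a, b, c] @ buf
        y += self.b.value[:, None]
        if train:
            self._xp = xp
        return y.reshape(self.c_out, h, w_, d)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c_out, h, w_, d = dy.shape
        p = self.k // 2
        n = h * w_ * d
        dyf = np.ascontiguousarray(dy.reshape(c_out, n), dtype=np.float32)
        xp = self._xp
        dxp = np.zeros_like(xp)
        buf = np.empty((self.c_in, n), dtype=np.float32)
        for a, b, c in self._offsets():
            buf.reshape(self.c_in, h, w_, d)[...] = xp[:, a:a + h, b:b + w_, c:c + d]
            self.w.grad[:, :, a, b, c] += dyf @ buf.T
            dxp[:, a:a + h, b:b + w_, c:c + d] += (
                self.w.value[:, :, a, b, c].T @ dyf
            ).reshape(self.c_in, h, w_, d)
        self.b.grad += dyf.sum(axis=1)
        self._xp = None
        if p == 0:
            return dxp
        return np.ascontiguousarray(dxp[:, p:p + h, p:p + w_, p:p + d])


class ReLU:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class ChannelNorm:
    """Per-channel normalisation over spatial voxels with learnable affine.

    Statistics are those of the current sample in both train and eval mode,
    so forward passes are deterministic functions of the input.
    """

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels, dtype=np.float32))
        self.beta = Param(np.zeros(channels, dtype=np.float32))
        self.eps = eps

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        m = x.mean(axis=(1, 2, 3), keepdims=True)
        v = x.var(axis=(1, 2, 3), keepdims=True)
        inv = 1.0 / np.sqrt(v + self.eps)
        xhat = (x - m) * inv
        if train:
            self._xhat, self._inv = xhat, inv
        g = self.gamma.value[:, None, None, None]
        return g * xhat + self.beta.value[:, None, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        n = float(np.prod(dy.shape[1:]))
        self.gamma.grad += (dy * xhat).sum(axis=(1, 2, 3))
        self.beta.grad += dy.sum(axis=(1, 2, 3))
        dxhat = dy * self.gamma.value[:, None, None, None]
        s1 = dxhat.sum(axis=(1, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(1, 2, 3), keepdims=True)
        return (inv / n) * (n * dxhat - s1 - xhat * s2)


class MaxPool2x:
    """Max pooling with a 2x2x2 window and stride 2; requires even spatial dims."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        c, h, w_, d = x.shape
        if h % 2 or w_ % 2 or d % 2:
            raise ValueError(f"spatial dims must be even for 2x pooling, got {x.shape[1:]}")
        blocks = x.reshape(c, h // 2, 2, w_ // 2, 2, d // 2, 2)
        blocks = blocks.transpose(0, 1, 3, 5, 2, 4, 6).reshape(c, h // 2, w_ // 2, d // 2, 8)
        idx = blocks.argmax(axis=-1)
        y = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, h, w_, d = self._shape
        blocks = np.zeros((c, h // 2, w_ // 2, d // 2, 8), dtype=dy.dtype)
        np.put_along_axis(blocks, self._idx[..., None], dy[..., None], axis=-1)
        blocks = blocks.reshape(c, h // 2, w_ // 2, d // 2, 2, 2, 2)
        return blocks.transpose(0, 1, 4, 2, 5, 3, 6).reshape(c, h, w_, d)


class UpsampleNearest2x:
    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        c, h, w_, d = dy.shape
        return dy.reshape(c, h // 2, 2, w_ // 2, 2, d // 2, 2).sum(axis=(2, 4, 6))


class Sequential:
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class SGD:
    def __init__(self, params, lr: float, momentum: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.velocity = [np.zeros_like(p.value) for p in self.params] if momentum else None

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        if self.velocity is None:
            for p in self.params:
                p.value -= self.lr * p.grad
            return
        for p, v in zip(self.params, self.velocity):
            v *= self.momentum
            v += p.grad
            p.value -= self.lr * v


class Adam:
    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
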