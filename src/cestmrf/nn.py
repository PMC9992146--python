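"""A small deterministic neural-network core (numpy, explicit backprop).

Purpose-built for this package's two quantifiers: the pixelwise fully
connected reference network and the conditional-GAN generator/discriminator.
Everything is plain numpy with hand-written backward passes and a seeded
initializer, so training is bit-reproducible for a fixed seed in a
single-threaded BLAS configuration.

Layers follow the (batch, channels, height, width) convention for images and
(batch, features) for dense nets.  Each layer stores its forward cache on
``self``; call ``backward`` before the next ``forward`` of the same module.
"""

from __future__ import annotations

import math
from typing import Iterable, List, Sequence, Tuple

import numpy as np

__all__ = ["Param", "Dense", "Conv2d", "Upsample2x", "LeakyReLU", "ReLU",
           "Sigmoid", "Adam", "Sequential", "l1_loss", "mse_loss",
           "bce_with_logits", "tv_loss", "DTYPE"]

#: working precision of the trainable networks; single precision keeps the
#: convolutional memory traffic (the single-thread bottleneck) manageable
DTYPE = np.float32


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(DTYPE)
        self.grad = np.zeros_like(self.value)


class Module:
    def params(self) -> List[Param]:
        return []

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def get_weights(self) -> List[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights):
            p.value[...] = w

    def astype(self, dtype) -> "Module":
        """Recast parameters in place (e.g. float64 for gradient checks)."""
        for p in self.params():
            p.value = p.value.astype(dtype)
            p.grad = p.grad.astype(dtype)
        return self


class Dense(Module):
    """Fully connected layer, He-normal initialized."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = math.sqrt(2.0 / n_in)
        self.w = Param(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = Param(np.zeros(n_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.w.value.T


class Conv2d(Module):
    """2D convolution ('same' padding for stride 1, half-size for stride 2).

    Implemented by im2col + matmul; the backward pass scatters column
    gradients back with a col2im loop over the kernel footprint.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 ksize: int = 3, stride: int = 1):
        if ksize % 2 != 1:
            raise ValueError("odd kernel sizes only")
        self.ksize, self.stride = ksize, stride
        self.c_in, self.c_out = c_in, c_out
        scale = math.sqrt(2.0 / (c_in * ksize * ksize))
        self.w = Param(rng.normal(0.0, scale, size=(c_out, c_in * ksize * ksize)))
        self.b = Param(np.zeros(c_out))

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        k, s = self.ksize, self.stride
        pad = k // 2
        bsz, c, h, w = x.shape
        if s > 1 and (h % s or w % s):
            raise ValueError(f"spatial dims {h}x{w} not divisible by stride {s}")
        dtype = np.result_type(x.dtype, self.w.value.dtype)
        xp = np.pad(x.astype(dtype, copy=False),
                    ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        ho, wo = (h + s - 1) // s, (w + s - 1) // s
        # im2col laid out (C, k, k) innermost to match the weight matrix
        cols = np.empty((bsz, ho, wo, c, k, k), dtype=dtype)
        for i in range(k):
            for j in range(k):
                cols[:, :, :, :, i, j] = \
                    xp[:, :, i:i + s * ho:s, j:j + s * wo:s].transpose(0, 2, 3, 1)
        cols = cols.reshape(bsz * ho * wo, c * k * k)
        self._cols, self._xshape = cols, x.shape
        self._out_hw = (ho, wo)
        y = cols @ self.w.value.T.astype(dtype, copy=False) + self.b.value
        return np.ascontiguousarray(
            y.reshape(bsz, ho, wo, self.c_out).transpose(0, 3, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        k, s = self.ksize, self.stride
        pad = k // 2
        bsz, c, h, w = self._xshape
        ho, wo = self._out_hw
        dtype = self._cols.dtype
        dyc = np.ascontiguousarray(
            dy.astype(dtype, copy=False).transpose(0, 2, 3, 1)
        ).reshape(bsz * ho * wo, self.c_out)
        self.w.grad += dyc.T @ self._cols
        self.b.grad += dyc.sum(axis=0)
        dcols = (dyc @ self.w.value.astype(dtype, copy=False)).reshape(
            bsz, ho, wo, c, k, k)
        dxp = np.zeros((bsz, c, h + 2 * pad, w + 2 * pad), dtype=dtype)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += \
                    dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, pad:pad + h, pad:pad + w]


class Upsample2x(Module):
    """Nearest-neighbour 2x spatial upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, h, w = dy.shape
        return dy.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class LeakyReLU(Module):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.alpha * dy)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(alpha=0.0)


class Sigmoid(Module):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Adam optimizer; beta1 = 0.5 as customary for adversarial training."""

    def __init__(self, params: Iterable[Param], lr: float,
                 betas: Tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * p.grad
            v[...] = b2 * v + (1 - b2) * p.grad ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Losses (each returns (value, gradient w.r.t. the first argument))
# ---------------------------------------------------------------------------

def l1_loss(pred: np.ndarray, target: np.ndarray) -> Tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size


def mse_loss(pred: np.ndarray, target: np.ndarray) -> Tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(diff ** 2)), 2.0 * diff / diff.size


def bce_with_logits(logits: np.ndarray, label: float) -> Tuple[float, np.ndarray]:
    """Binary cross-entropy against a constant label (0 or 1), from logits."""
    z = np.clip(logits, -60, 60)
    p = 1.0 / (1.0 + np.exp(-z))
    loss = -(label * np.log(p + 1e-12) + (1 - label) * np.log(1 - p + 1e-12))
    return float(np.mean(loss)), (p - label) / logits.size


def tv_loss(maps: np.ndarray) -> Tuple[float, np.ndarray]:
    """Anisotropic total variation of (B, C, H, W) maps.

    Per sample and channel: mean |first difference| along rows plus mean
    |first difference| along columns; summed over channels, averaged over the
    batch.  Positively homogeneous of degree one: tv(a*x) = a*tv(x), a > 0.
    """
    x = np.asarray(maps)
    if x.ndim == 3:
        x = x[None]
    b, c, h, w = x.shape
    dv = np.diff(x, axis=2)
    dh = np.diff(x, axis=3)
    val = (np.abs(dv).mean(axis=(2, 3)) + np.abs(dh).mean(axis=(2, 3))).sum(axis=1)
    grad = np.zeros_like(x)
    sv = np.sign(dv) / ((h - 1) * w)
    sh = np.sign(dh) / (h * (w - 1))
    grad[:, :, 1:, :] += sv
    grad[:, :, :-1, :] -= sv
    grad[:, :, :, 1:] += sh
    grad[:, :, :, :-1] -= sh
    grad /= b
    g = grad if maps.ndim == 4 else grad[0]
    return float(val.mean()), g
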