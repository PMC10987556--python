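"""Minimal numpy convolutional-network core with exact reverse-mode gradients.

Provides just the layers a compact multibox detector needs — 3x3 same
convolutions (im2col + matmul), ReLU, 2x2 max pooling — plus the Adam
optimiser.  Every layer caches what its backward pass needs, and the
backward pass of a stack returns the gradient with respect to each stored
feature map, which is what gradient checking and Grad-CAM both consume.

All math is plain numpy, so runs are bitwise deterministic for a fixed
seed, and dtype is configurable (float32 for training speed, float64 for
finite-difference gradient checks).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["Conv2d", "ReLU", "MaxPool2d", "Sequential", "Adam"]


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, int, int]:
    """Unfold (B,C,H,W) into (B, C*k*k, Ho*Wo) patch columns."""
    B, C, H, W = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    Hp, Wp = x.shape[2], x.shape[3]
    Ho = (Hp - k) // stride + 1
    Wo = (Wp - k) // stride + 1
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(B, C, Ho, Wo, k, k),
        strides=(s0, s1, s2 * stride, s3 * stride, s2, s3),
        writeable=False,
    )
    cols = windows.transpose(0, 1, 4, 5, 2, 3).reshape(B, C * k * k, Ho * Wo)
    return np.ascontiguousarray(cols), Ho, Wo


def _col2im(cols: np.ndarray, x_shape, k: int, stride: int, pad: int,
            Ho: int, Wo: int) -> np.ndarray:
    """Fold (B, C*k*k, Ho*Wo) patch-column gradients back onto the input."""
    B, C, H, W = x_shape
    Hp, Wp = H + 2 * pad, W + 2 * pad
    out = np.zeros((B, C, Hp, Wp), dtype=cols.dtype)
    cols6 = cols.reshape(B, C, k, k, Ho, Wo)
    for ky in range(k):
        y_max = ky + stride * Ho
        for kx in range(k):
            x_max = kx + stride * Wo
            out[:, :, ky:y_max:stride, kx:x_max:stride] += cols6[:, :, ky, kx]
    if pad:
        out = out[:, :, pad:-pad, pad:-pad]
    return out


class Conv2d:
    """k x k convolution with bias; He-normal initialisation."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1,
                 pad: Optional[int] = None, rng: Optional[np.random.Generator] = None,
                 dtype=np.float32):
        if pad is None:
            pad = k // 2
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (c_in * k * k))
        self.W = (rng.standard_normal((c_out, c_in * k * k)) * std).astype(dtype)
        self.b = np.zeros(c_out, dtype=dtype)
        self.k, self.stride, self.pad = k, stride, pad
        self.c_in, self.c_out = c_in, c_out
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cache = None

    def parameters(self):
        return [(self.W, self.gW), (self.b, self.gb)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        cols, Ho, Wo = _im2col(x, self.k, self.stride, self.pad)
        out = np.matmul(self.W[None], cols)  # (B, c_out, Ho*Wo)
        out += self.b[None, :, None]
        self._cache = (x.shape, cols, Ho, Wo)
        return out.reshape(x.shape[0], self.c_out, Ho, Wo)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, cols, Ho, Wo = self._cache
        B = x_shape[0]
        dy2 = np.ascontiguousarray(dy.reshape(B, self.c_out, Ho * Wo), dtype=cols.dtype)
        self.gW += np.matmul(dy2, cols.transpose(0, 2, 1)).sum(axis=0)
        self.gb += dy2.sum(axis=(0, 2))
        dcols = np.matmul(self.W.T[None], dy2)
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad, Ho, Wo)


class ReLU:
    def __init__(self):
        self._mask = None

    def parameters(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2d:
    """Non-overlapping pooling; input spatial dims must be divisible by the size."""

    def __init__(self, size: int = 2):
        self.size = size
        self._cache = None

    def parameters(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        s = self.size
        if H % s or W % s:
            raise ValueError(f"pooling size {s} does not divide input {H}x{W}")
        xr = x.reshape(B, C, H // s, s, W // s, s)
        out = xr.max(axis=(3, 5))
        mask = xr == out[:, :, :, None, :, None]
        # break ties deterministically: keep only the first max per cell
        flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H // s, W // s, s * s)
        first = np.cumsum(flat, axis=-1) == 1
        flat = flat & first
        mask = flat.reshape(B, C, H // s, W // s, s, s).transpose(0, 1, 2, 4, 3, 5)
        self._cache = (x.shape, mask)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, mask = self._cache
        B, C, H, W = x_shape
        s = self.size
        dyr = dy[:, :, :, None, :, None]
        dx = (mask * dyr).reshape(B, C, H // s, s, W // s, s)
        return dx.reshape(B, C, H, W)


@dataclass
class Sequential:
    """A layer stack that records every post-layer activation on forward.

    ``activations[i]`` is the output of layer ``i``; ``backward`` can stop
    early and report the gradient flowing into any recorded activation,
    which Grad-CAM uses to weight feature-map channels.
    """

    layers: list = field(default_factory=list)
    activations: list = field(default_factory=list, repr=False)

    def parameters(self):
        out = []
        for layer in self.layers:
            out.extend(layer.parameters())
        return out

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.activations = []
        for layer in self.layers:
            x = layer.forward(x)
            self.activations.append(x)
        return x

    def backward(self, dy: np.ndarray, stop_at: int = 0) -> np.ndarray:
        """Propagate ``dy`` back to (and including) layer ``stop_at``.

        Returns the gradient with respect to the *input* of layer
        ``stop_at`` (i.e. the output of layer ``stop_at - 1``).
        """
        for i in range(len(self.layers) - 1, stop_at - 1, -1):
            dy = self.layers[i].backward(dy)
        return dy


class Adam:
    """Adam with L2 weight decay added to the gradient."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.wd = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in params]
        self.v = [np.zeros_like(p) for p, _ in params]

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for i, (p, g) in enumerate(self.params):
            grad = g + self.wd * p
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * grad * grad
            p -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)
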