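"""Convolutional layers (NCHW) for the compact counting network.

3x3 same-padding convolutions are evaluated through an im2col lowering so the
inner loop is a single BLAS matmul; the col2im scatter in the backward pass
iterates only over the 9 kernel offsets.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .layers import Layer, Param


class Conv2d(Layer):
    """3x3 convolution, stride 1, zero same-padding."""

    K = 3

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 dtype=np.float32, name: str = "conv"):
        fan_in = c_in * self.K * self.K
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        self.W = Param(rng.normal(0.0, scale,
                                  (c_out, fan_in)).astype(dtype), f"{name}.W")
        self.b = Param(np.zeros(c_out, dtype=dtype), f"{name}.b")
        self.c_in, self.c_out = c_in, c_out

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        pad = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = sliding_window_view(pad, (self.K, self.K), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * 9)
        self._cols, self._shape = cols, (b, c, h, w)
        out = cols @ self.W.value.T + self.b.value
        return out.reshape(b, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        g2 = g.transpose(0, 2, 3, 1).reshape(b * h * w, self.c_out)
        self.W.grad += g2.T @ self._cols
        self.b.grad += g2.sum(axis=0)
        dcols = (g2 @ self.W.value).reshape(b, h, w, c, self.K, self.K)
        dpad = np.zeros((b, c, h + 2, w + 2), dtype=g.dtype)
        for di in range(self.K):
            for dj in range(self.K):
                dpad[:, :, di:di + h, dj:dj + w] += \
                    dcols[:, :, :, :, di, dj].transpose(0, 3, 1, 2)
        return dpad[:, :, 1:-1, 1:-1]


class MaxPool2d(Layer):
    """2x2 max pooling with stride 2; spatial dims must be even."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        win = x.reshape(b, c, h // 2, 2, w // 2, 2)
        flat = win.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h // 2, w // 2, 4)
        self._idx = flat.argmax(axis=-1)
        self._shape = (b, c, h, w)
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        dflat = np.zeros((b, c, h // 2, w // 2, 4), dtype=g.dtype)
        np.put_along_axis(dflat, self._idx[..., None], g[..., None], axis=-1)
        dwin = dflat.reshape(b, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dwin.reshape(b, c, h, w)


class AvgPool2d(Layer):
    """2x2 average pooling with stride 2; preserves local mass, which
    matters when nearby items are separated by sub-cell gaps."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        self._shape = (b, c, h, w)
        return x.reshape(b, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))

    def backward(self, g: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        g = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3)
        return (g / 4.0).reshape(b, c, h, w)


class BatchNorm2d(Layer):
    """Per-channel batch normalisation with learned scale/shift and running
    statistics for inference."""

    def __init__(self, channels: int, dtype=np.float32, momentum: float = 0.1,
                 eps: float = 1e-5, name: str = "bn"):
        self.gamma = Param(np.ones(channels, dtype=dtype), f"{name}.gamma")
        self.beta = Param(np.zeros(channels, dtype=dtype), f"{name}.beta")
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        self._inv = inv
        self._m = x.shape[0] * x.shape[2] * x.shape[3]
        return self.gamma.value[None, :, None, None] * self._xhat \
            + self.beta.value[None, :, None, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv, m = self._xhat, self._inv, self._m
        self.gamma.grad += (g * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += g.sum(axis=(0, 2, 3))
        gx = g * self.gamma.value[None, :, None, None]
        mean_gx = gx.mean(axis=(0, 2, 3), keepdims=True)
        mean_gx_xhat = (gx * xhat).mean(axis=(0, 2, 3), keepdims=True)
        return inv[None, :, None, None] * (gx - mean_gx - xhat * mean_gx_xhat)
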