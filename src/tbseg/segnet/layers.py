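"""Minimal NumPy layers for the 3D encoder-decoder, with hand-written
backward passes.

Tensors are ``(channels, depth, height, width)`` float32.  3x3x3
convolutions are evaluated as 27 channel-mixing matmuls over shifted
views of the zero-padded input, which keeps everything inside BLAS.
"""

from __future__ import annotations

import numpy as np

_OFFSETS = [(dz, dy, dx) for dz in range(3) for dy in range(3) for dx in range(3)]


class Layer:
    """Base: parameterised layers expose params/grads as parallel lists."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def zero_grads(self) -> None:
        for g in self.grads():
            g[...] = 0.0


class Conv3(Layer):
    """3x3x3 convolution, stride 1, zero padding 1 ('same')."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        std = np.sqrt(2.0 / (27 * c_in))  # He init for ReLU nets
        self.w = rng.normal(0.0, std, size=(27, c_out, c_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._xp: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.gw, self.gb]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w_ = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
        self._xp = xp
        n = d * h * w_
        out = np.repeat(self.b[:, None], n, axis=1)
        for k, (dz, dy, dx) in enumerate(_OFFSETS):
            view = xp[:, dz : dz + d, dy : dy + h, dx : dx + w_].reshape(c, n)
            out += self.w[k] @ view
        return out.reshape(self.c_out, d, h, w_)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        _, d, h, w_ = gout.shape
        n = d * h * w_
        g = gout.reshape(self.c_out, n)
        xp = self._xp
        gxp = np.zeros_like(xp)
        for k, (dz, dy, dx) in enumerate(_OFFSETS):
            view = xp[:, dz : dz + d, dy : dy + h, dx : dx + w_].reshape(self.c_in, n)
            self.gw[k] += g @ view.T
            gxp[:, dz : dz + d, dy : dy + h, dx : dx + w_] += (self.w[k].T @ g).reshape(
                self.c_in, d, h, w_
            )
        self.gb += g.sum(axis=1)
        self._xp = None
        return gxp[:, 1:-1, 1:-1, 1:-1]


class Conv1(Layer):
    """1x1x1 convolution (channel mixing only)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.c_in, self.c_out = c_in, c_out
        std = np.sqrt(2.0 / c_in)
        self.w = rng.normal(0.0, std, size=(c_out, c_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.gw = np.zeros_like(self.w)
        self.gb = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.gw, self.gb]

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w_ = x.shape
        self._x = x
        out = self.w @ x.reshape(c, -1) + self.b[:, None]
        return out.reshape(self.c_out, d, h, w_)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        c_out, d, h, w_ = gout.shape
        g = gout.reshape(c_out, -1)
        xf = self._x.reshape(self.c_in, -1)
        self.gw += g @ xf.T
        self.gb += g.sum(axis=1)
        self._x = None
        return (self.w.T @ g).reshape(self.c_in, d, h, w_)


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, np.float32(0.0))

    def backward(self, gout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gout, np.float32(0.0))


class MaxPool2(Layer):
    """2x2x2 max pooling; tied maxima share the gradient equally."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w_ = x.shape
        xr = x.reshape(c, d // 2, 2, h // 2, 2, w_ // 2, 2)
        out = xr.max(axis=(2, 4, 6))
        self._mask = xr == out[:, :, None, :, None, :, None]
        self._shape = x.shape
        return out

    def backward(self, gout: np.ndarray) -> np.ndarray:
        counts = self._mask.sum(axis=(2, 4, 6), keepdims=True)
        g = self._mask * (gout[:, :, None, :, None, :, None] / counts)
        return g.reshape(self._shape).astype(np.float32)


class Upsample2(Layer):
    """Nearest-neighbour x2 upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        c, d, h, w_ = x.shape
        out = np.broadcast_to(
            x[:, :, None, :, None, :, None], (c, d, 2, h, 2, w_, 2)
        ).reshape(c, 2 * d, 2 * h, 2 * w_)
        return np.ascontiguousarray(out)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        c, d2, h2, w2 = gout.shape
        return gout.reshape(c, d2 // 2, 2, h2 // 2, 2, w2 // 2, 2).sum(axis=(2, 4, 6))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out
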