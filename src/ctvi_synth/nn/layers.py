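"""Minimal CPU layers for the 2D U-Net: forward and backward passes in NumPy.

Internally activations are channels-last, (B, H, W, C) float32, which keeps
the per-kernel-offset matrix products contiguous; the UNet wrapper exposes
the conventional (B, C, H, W) interface.  Convolutions are cross-correlations
(the deep-learning convention) with 'same' zero padding and stride 1,
computed by accumulating one (B*H*W, C) @ (C, F) product per kernel offset
instead of materializing an im2col patch matrix.  Downsampling is 2x2 max
pooling with stride 2; upsampling is a 2x2 transposed convolution with
stride 2.  Weights are He-initialized: normal draws scaled by
sqrt(2 / fan_in).
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable tensor with its gradient accumulator."""

    def __init__(self, value: np.ndarray, name: str, trainable: bool = True):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name
        self.trainable = trainable

    @property
    def size(self) -> int:
        return int(self.value.size)


class Conv2D:
    """kxk same-padding convolution with optional activation, stride 1."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 3, activation: str = "relu", name: str = "conv"):
        if activation not in ("relu", "sigmoid", "linear"):
            raise ValueError(f"unknown activation {activation!r}")
        fan_in = kernel * kernel * c_in
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kernel, kernel, c_in, c_out))
        self.w = Param(w, f"{name}.w")
        self.b = Param(np.zeros(c_out), f"{name}.b")
        self.kernel = kernel
        self.c_in, self.c_out = c_in, c_out
        self.activation = activation
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, h, w, _ = x.shape
        k, pad = self.kernel, self.kernel // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0))) if pad else x
        z = np.empty((b, h, w, self.c_out),
                     dtype=np.result_type(x.dtype, self.w.value.dtype))
        z[...] = self.b.value
        wv = self.w.value
        for u in range(k):
            for v in range(k):
                xs = xp[:, u : u + h, v : v + w, :]
                z += np.tensordot(xs, wv[u, v], axes=([3], [0]))
        if self.activation == "relu":
            y = np.maximum(z, 0.0)
        elif self.activation == "sigmoid":
            y = 1.0 / (1.0 + np.exp(-z))
        else:
            y = z
        if train:
            self._cache = (xp, y)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp, y = self._cache
        self._cache = None
        if self.activation == "relu":
            dz = dy * (y > 0)
        elif self.activation == "sigmoid":
            dz = dy * y * (1.0 - y)
        else:
            dz = dy
        b, h, w, _ = dz.shape
        k, pad = self.kernel, self.kernel // 2
        self.b.grad += dz.sum(axis=(0, 1, 2))
        dxp = np.zeros_like(xp)
        wv = self.w.value
        for u in range(k):
            for v in range(k):
                xs = xp[:, u : u + h, v : v + w, :]
                self.w.grad[u, v] += np.tensordot(
                    xs, dz, axes=([0, 1, 2], [0, 1, 2])
                )
                dxp[:, u : u + h, v : v + w, :] += np.tensordot(
                    dz, wv[u, v], axes=([3], [1])
                )
        if pad:
            return dxp[:, pad : pad + h, pad : pad + w, :]
        return dxp


class MaxPool2:
    """2x2 max pooling, stride 2. Ties resolve to the first element."""

    def __init__(self):
        self._cache = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"pooling needs even spatial dims, got {h}x{w}")
        xr = x.reshape(b, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
        flat = np.ascontiguousarray(xr).reshape(b, h // 2, w // 2, c, 4)
        idx = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, (b, h, w, c))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, (b, h, w, c) = self._cache
        self._cache = None
        dflat = np.zeros((b, h // 2, w // 2, c, 4), dtype=dy.dtype)
        np.put_along_axis(dflat, idx[..., None], dy[..., None], axis=-1)
        dx = dflat.reshape(b, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return np.ascontiguousarray(dx).reshape(b, h, w, c)


class ConvTranspose2:
    """2x2 transposed convolution with stride 2 (exact 2x upsampling), ReLU."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 name: str = "up"):
        w = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_in, c_out, 2, 2))
        self.w = Param(w, f"{name}.w")
        self.b = Param(np.zeros(c_out), f"{name}.b")
        self.c_in, self.c_out = c_in, c_out
        self._cache = None

    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, h, w, _ = x.shape
        # (B,H,W,C) x (C,F,2,2) -> (B,H,2,W,2,F) -> (B,2H,2W,F)
        y = np.einsum("bhwc,cfuv->bhuwvf", x, self.w.value, optimize=True)
        y = np.ascontiguousarray(y).reshape(b, 2 * h, 2 * w, self.c_out)
        y += self.b.value
        y = np.maximum(y, 0.0)  # ReLU per the hidden-layer convention
        if train:
            self._cache = (x, y)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, y = self._cache
        self._cache = None
        dz = dy * (y > 0)
        b, h2, w2, f = dz.shape
        dzs = dz.reshape(b, h2 // 2, 2, w2 // 2, 2, f)
        self.w.grad += np.einsum("bhwc,bhuwvf->cfuv", x, dzs, optimize=True)
        self.b.grad += dz.sum(axis=(0, 1, 2))
        dx = np.einsum("bhuwvf,cfuv->bhwc", dzs, self.w.value, optimize=True)
        return dx
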