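"""Layers with explicit forward/backward passes on (N, C, H, W) float32 arrays."""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array and its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray):
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)


class Conv2d:
    """3x3 (or kxk) same-padding convolution, stride 1, via im2col matmul."""

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k * k
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, k, k))
        self.weight = Param(w)
        self.bias = Param(np.zeros(c_out))
        self.k = k
        self.pad = k // 2
        self._cols = None
        self._xshape = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k, p = self.k, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (N, C, H, W, k, k) -> (N*H*W, C*k*k)
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        self._cols = cols
        self._xshape = x.shape
        wmat = self.weight.data.reshape(self.weight.data.shape[0], -1)
        y = cols @ wmat.T + self.bias.data
        return np.ascontiguousarray(
            y.reshape(n, h, w, -1).transpose(0, 3, 1, 2)
        )

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        k, p = self.k, self.pad
        c_out = self.weight.data.shape[0]
        dyf = dy.transpose(0, 2, 3, 1).reshape(n * h * w, c_out)
        self.weight.grad += (dyf.T @ self._cols).reshape(self.weight.data.shape)
        self.bias.grad += dyf.sum(axis=0)
        wmat = self.weight.data.reshape(c_out, -1)
        dcols = (dyf @ wmat).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        self._cols = None
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class ReLU:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2:
    """2x2 max pooling; gradient routed to the argmax (first on exact ties)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        assert h % 2 == 0 and w % 2 == 0, "spatial dims must be even"
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        self._idx = flat.argmax(axis=-1)
        self._xshape = x.shape
        return np.take_along_axis(flat, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        flat = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.float32)
        np.put_along_axis(flat, self._idx[..., None], dy[..., None], axis=-1)
        return (
            flat.reshape(n, c, h // 2, w // 2, 2, 2)
            .transpose(0, 1, 2, 4, 3, 5)
            .reshape(n, c, h, w)
        )


class Upsample2:
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class GlobalAvgPool:
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._xshape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._xshape
        return np.broadcast_to(dy[:, :, None, None], (n, c, h, w)) / (h * w)


class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.weight = Param(rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_out, d_in)))
        self.bias = Param(np.zeros(d_out))

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad += dy.T @ self._x
        self.bias.grad += dy.sum(axis=0)
        return dy @ self.weight.data
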