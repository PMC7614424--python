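"""Compact NumPy neural-network core used by the quality-assessment backbone.

Implements exactly the pieces a VGG-style patch regressor needs — 3x3
same-padding convolution (im2col + BLAS matmul), ReLU, 2x2 max-pooling,
global average pooling, dense layers — together with mean-squared-error
loss and the Adam optimiser.  Everything is float32, single threaded and
deterministic given a ``numpy.random.Generator``.

Layers cache their forward inputs only when ``train=True`` so that large
inference batches (feature precomputation, prediction) carry no memory
overhead.  ``Sequential.backward`` accepts a ``stop_at`` layer index: the
input gradient is not propagated below the deepest frozen prefix, which is
what makes head-only transfer training cheap.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv3x3",
    "ReLU",
    "MaxPool2",
    "GlobalAvgPool",
    "Dense",
    "Sequential",
    "Adam",
    "mse_loss",
]


class Layer:
    """Base layer: parameter dict, gradient dict, forward/backward."""

    trainable: bool = True

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray, need_dx: bool = True) -> np.ndarray | None:
        raise NotImplementedError

    @property
    def n_params(self) -> int:
        return sum(p.size for p in self.params().values())


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*9) patches of a 3x3 same-padded window."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3), axis=(2, 3))  # (N, C, H, W, 3, 3)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * 9)


class Conv3x3(Layer):
    """3x3 convolution, stride 1, same padding, He-normal initialisation."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.W = (rng.standard_normal((c_out, c_in, 3, 3)) * scale).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.c_in, self.c_out = c_in, c_out
        self._col: np.ndarray | None = None
        self._shape: tuple[int, ...] | None = None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        col = _im2col(x)
        if train:
            self._col, self._shape = col, x.shape
        out = col @ self.W.reshape(self.c_out, -1).T + self.b
        return out.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2)

    def backward(self, dout, need_dx=True):
        n, _, h, w = self._shape
        dcol = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.dW[...] = (dcol.T @ self._col).reshape(self.W.shape)
        self.db[...] = dcol.sum(axis=0)
        self._col = None
        if not need_dx:
            return None
        # dx = same-conv of dout with the flipped, channel-transposed kernel
        w_flip = self.W.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1]
        col_out = _im2col(dout)
        dx = col_out @ w_flip.reshape(self.c_in, -1).T
        return dx.reshape(n, h, w, self.c_in).transpose(0, 3, 1, 2)


class ReLU(Layer):
    trainable = False

    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x, train=False):
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout, need_dx=True):
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    trainable = False

    def __init__(self):
        self._arg: np.ndarray | None = None
        self._in_shape: tuple[int, ...] | None = None

    def forward(self, x, train=False):
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :, : 2 * h2, : 2 * w2]
        windows = xc.reshape(n, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h2, w2, 4)
        arg = windows.argmax(axis=-1)
        out = np.take_along_axis(windows, arg[..., None], axis=-1)[..., 0]
        if train:
            self._arg, self._in_shape = arg, x.shape
        return out

    def backward(self, dout, need_dx=True):
        n, c, h, w = self._in_shape
        h2, w2 = h // 2, w // 2
        flat = np.zeros((n, c, h2, w2, 4), dtype=dout.dtype)
        np.put_along_axis(flat, self._arg[..., None], dout[..., None], axis=-1)
        dx = np.zeros((n, c, h, w), dtype=dout.dtype)
        dx[:, :, : 2 * h2, : 2 * w2] = (
            flat.reshape(n, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, 2 * h2, 2 * w2)
        )
        self._arg = None
        return dx


class GlobalAvgPool(Layer):
    trainable = False

    def __init__(self):
        self._in_shape: tuple[int, ...] | None = None

    def forward(self, x, train=False):
        if train:
            self._in_shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout, need_dx=True):
        n, c, h, w = self._in_shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w), (n, c, h, w)).astype(dout.dtype)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias_init: float = 0.0):
        scale = np.sqrt(2.0 / (d_in + d_out))
        self.W = (rng.standard_normal((d_in, d_out)) * scale).astype(np.float32)
        self.b = np.full(d_out, bias_init, dtype=np.float32)
        self._x: np.ndarray | None = None
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x, train=False):
        if train:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout, need_dx=True):
        self.dW[...] = self._x.T @ dout
        self.db[...] = dout.sum(axis=0)
        self._x = None
        if not need_dx:
            return None
        return dout @ self.W.T


class Sequential:
    """An ordered layer stack with named parameter access."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False, start: int = 0) -> np.ndarray:
        for layer in self.layers[start:]:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray, stop_at: int = 0) -> None:
        """Backpropagate; the input gradient of layer ``stop_at`` is not computed."""
        for i in range(len(self.layers) - 1, stop_at - 1, -1):
            dout = self.layers[i].backward(dout, need_dx=(i > stop_at))

    def params(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, p in layer.params().items():
                out[f"{i}.{name}"] = p
        return out

    def trainable_params(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            if layer.trainable:
                for name, p in layer.params().items():
                    out[f"{i}.{name}"] = p
        return out

    def trainable_grads(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            if layer.trainable:
                for name, g in layer.grads().items():
                    out[f"{i}.{name}"] = g
        return out

    def set_params(self, values: dict[str, np.ndarray]) -> None:
        current = self.params()
        for key, val in values.items():
            if key not in current:
                raise KeyError(f"unknown parameter {key!r}")
            if current[key].shape != val.shape:
                raise ValueError(
                    f"shape mismatch for {key!r}: model {current[key].shape}, value {val.shape}"
                )
            current[key][...] = val


class Adam:
    """Adam optimiser over a named parameter dict."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for key, p in self.params.items():
            g = grads[key]
            self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
            self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
            p -= self.lr * (self.m[key] / b1c) / (np.sqrt(self.v[key] / b2c) + self.eps)


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all entries; returns (loss, dpred)."""
    diff = pred - target
    loss = float(np.mean(diff * diff))
    return loss, (2.0 / diff.size) * diff.astype(np.float32)
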