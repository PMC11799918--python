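"""Minimal 3D convolutional-network engine (NumPy, hand-written backprop).

Single-sample layers on channels-first float32 tensors ``(C, D, H, W)``.
Convolutions are realised as im2col matrix products; the input gradient of
a convolution is the correlation of the padded output gradient with the
spatially flipped, channel-transposed kernel.  This is deliberately small:
just the pieces a residual U-Net needs (3x3x3 and 1x1x1 convolutions,
ReLU, 2x max pooling, nearest-neighbour upsampling) plus Adam.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name


def _conv3(x: np.ndarray, weight: np.ndarray, bias: np.ndarray | None):
    """3x3x3 'same' cross-correlation.  Returns (y, cols) with the im2col
    matrix cached for the weight gradient."""
    co, ci, *_ = weight.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    win = sliding_window_view(xp, (3, 3, 3), axis=(1, 2, 3))  # (ci, D, H, W, 3,3,3)
    d, h, w = x.shape[1:]
    cols = win.transpose(1, 2, 3, 0, 4, 5, 6).reshape(d * h * w, ci * 27)
    y = cols @ weight.reshape(co, ci * 27).T
    if bias is not None:
        y += bias
    return np.ascontiguousarray(y.T.reshape(co, d, h, w)), cols


class Conv3d:
    """3x3x3 convolution, stride 1, 'same' padding, He-normal init.

    ``zero_init`` starts the kernel at zero (used for the second conv of
    each residual block and for the heads, keeping the network near the
    identity at initialisation so activations stay well-scaled without
    normalisation layers)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, name: str,
                 zero_init: bool = False):
        scale = 0.0 if zero_init else np.sqrt(2.0 / (c_in * 27))
        self.weight = Param(rng.normal(0.0, 1.0, (c_out, c_in, 3, 3, 3)) * scale, f"{name}.w")
        self.bias = Param(np.zeros(c_out), f"{name}.b")
        self._cols = None
        self._shape = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        y, cols = _conv3(x, self.weight.value, self.bias.value)
        self._cols, self._shape = cols, x.shape
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        co = gy.shape[0]
        g_flat = gy.reshape(co, -1)
        self.weight.grad += (g_flat @ self._cols).reshape(self.weight.value.shape)
        self.bias.grad += g_flat.sum(axis=1)
        w_t = self.weight.value.transpose(1, 0, 2, 3, 4)[:, :, ::-1, ::-1, ::-1]
        gx, _ = _conv3(gy, np.ascontiguousarray(w_t), None)
        self._cols = None
        return gx


class Conv1x1:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, name: str,
                 zero_init: bool = False):
        scale = 0.0 if zero_init else np.sqrt(2.0 / c_in)
        self.weight = Param(rng.normal(0.0, 1.0, (c_out, c_in)) * scale, f"{name}.w")
        self.bias = Param(np.zeros(c_out), f"{name}.b")
        self._x = None

    def params(self):
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = np.tensordot(self.weight.value, x, axes=(1, 0))
        return y + self.bias.value[:, None, None, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        ci = self._x.shape[0]
        self.weight.grad += gy.reshape(gy.shape[0], -1) @ self._x.reshape(ci, -1).T
        self.bias.grad += gy.sum(axis=(1, 2, 3))
        gx = np.tensordot(self.weight.value.T, gy, axes=(1, 0))
        self._x = None
        return gx


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, 0.0)


class MaxPool2x:
    """2x2x2 max pooling (dims must be even)."""

    def __init__(self):
        self._argmask = None
        self._shape = None

    def params(self):
        return []

    @staticmethod
    def _blocks(x):
        c, d, h, w = x.shape
        return x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b = self._blocks(x)
        y = b.max(axis=(2, 4, 6))
        self._argmask = b == y[:, :, None, :, None, :, None]
        self._shape = x.shape
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        # gradient routed to every maximal element of each block (ties share)
        counts = self._argmask.sum(axis=(2, 4, 6))
        spread = (gy / counts)[:, :, None, :, None, :, None] * self._argmask
        return spread.reshape(self._shape)


class Upsample2x:
    """Nearest-neighbour x2 upsampling."""

    def params(self):
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        c, d, h, w = gy.shape
        return gy.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(2, 4, 6))


class ResidualBlock:
    """conv-relu-conv with identity shortcut, ReLU after the addition."""

    def __init__(self, channels: int, rng: np.random.Generator, name: str):
        self.conv1 = Conv3d(channels, channels, rng, f"{name}.c1")
        self.relu1 = ReLU()
        self.conv2 = Conv3d(channels, channels, rng, f"{name}.c2", zero_init=True)
        self.relu2 = ReLU()

    def params(self):
        return self.conv1.params() + self.conv2.params()

    def forward(self, x: np.ndarray) -> np.ndarray:
        h = self.conv2.forward(self.relu1.forward(self.conv1.forward(x)))
        return self.relu2.forward(h + x)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.relu2.backward(gy)
        gx = self.conv1.backward(self.relu1.backward(self.conv2.backward(g)))
        return gx + g


class Adam:
    def __init__(self, params, lr: float = 5e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
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
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m += (1.0 - self.beta1) * (p.grad - m)
            v += (1.0 - self.beta2) * (p.grad**2 - v)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray, axis: int = 0) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
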