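"""Minimal NumPy neural-network engine: 1-D convolution stacks with
ReLU/dropout/max-pooling, dense layers, sigmoid/softmax heads, exact
backpropagation and an Adam optimizer.

The engine is deliberately small: it implements exactly the layer types the
junction-sequence classifiers need, on CPU, in float32.  Sequence tensors
are shaped ``(batch, length, channels)``.  All stochastic behaviour
(dropout masks) flows through an explicit ``numpy.random.Generator`` so
runs are seed-deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1D",
    "ReLU",
    "Dropout",
    "MaxPool1D",
    "Flatten",
    "Dense",
    "Sequential",
    "Adam",
    "sigmoid",
    "softmax",
]


class Param:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """1-D convolution over (batch, length, channels) input.

    ``padding="same"`` zero-pads so the output length equals the input
    length (left pad ``(w-1)//2``); ``padding="valid"`` uses no padding and
    shortens the output by ``width - 1``.
    """

    def __init__(self, in_channels: int, out_channels: int, width: int, padding: str = "same"):
        if padding not in ("same", "valid"):
            raise ValueError("padding must be 'same' or 'valid'")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.width = width
        self.padding = padding
        self.W = Param(np.zeros((width * in_channels, out_channels), dtype=np.float32))
        self.b = Param(np.zeros(out_channels, dtype=np.float32))
        self._cols: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def out_length(self, in_length: int) -> int:
        return in_length if self.padding == "same" else in_length - self.width + 1

    @property
    def kernels(self) -> np.ndarray:
        """Filters as (out_channels, width, in_channels) for motif scanning."""
        return np.transpose(
            self.W.value.reshape(self.width, self.in_channels, self.out_channels), (2, 0, 1)
        )

    def _pad(self, x: np.ndarray) -> np.ndarray:
        if self.padding == "valid":
            return x
        left = (self.width - 1) // 2
        right = self.width - 1 - left
        return np.pad(x, ((0, 0), (left, right), (0, 0)))

    def forward(self, x, training, rng):
        xp = self._pad(x)
        n, lp, c = xp.shape
        lout = lp - self.width + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, self.width, axis=1)
        # (n, lout, c, width) -> (n, lout, width, c) -> (n*lout, width*c)
        cols = np.ascontiguousarray(np.transpose(win, (0, 1, 3, 2))).reshape(
            n * lout, self.width * c
        )
        self._cols = cols
        self._in_shape = x.shape
        y = cols @ self.W.value + self.b.value
        return y.reshape(n, lout, self.out_channels)

    def backward(self, dy):
        n, lout, _ = dy.shape
        dy2 = dy.reshape(n * lout, self.out_channels)
        self.W.grad += self._cols.T @ dy2
        self.b.grad += dy2.sum(axis=0)
        dcols = (dy2 @ self.W.value.T).reshape(n, lout, self.width, self.in_channels)
        lin = self._in_shape[1]
        if self.padding == "same":
            left = (self.width - 1) // 2
            dxp = np.zeros((n, lin + self.width - 1, self.in_channels), dtype=dy.dtype)
            for i in range(self.width):
                dxp[:, i : i + lout, :] += dcols[:, :, i, :]
            return dxp[:, left : left + lin, :]
        dx = np.zeros((n, lin, self.in_channels), dtype=dy.dtype)
        for i in range(self.width):
            dx[:, i : i + lout, :] += dcols[:, :, i, :]
        return dx


class ReLU(Layer):
    def forward(self, x, training, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout: active only in training mode."""

    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0,1)")
        self.p = p

    def forward(self, x, training, rng):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p).astype(x.dtype) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        if self._mask is None:
            return dy
        return dy * self._mask


class MaxPool1D(Layer):
    """Max pooling with equal window size and stride (default 2/2)."""

    def __init__(self, size: int = 2, stride: int | None = None):
        if stride is not None and stride != size:
            raise ValueError("only stride == size pooling is supported")
        self.size = size

    def out_length(self, in_length: int) -> int:
        return (in_length - self.size) // self.size + 1

    def forward(self, x, training, rng):
        n, l, c = x.shape
        nw = self.out_length(l)
        self._in_shape = x.shape
        xt = x[:, : nw * self.size, :].reshape(n, nw, self.size, c)
        self._argmax = xt.argmax(axis=2)
        return xt.max(axis=2)

    def backward(self, dy):
        n, l, c = self._in_shape
        nw = dy.shape[1]
        dxt = np.zeros((n, nw, self.size, c), dtype=dy.dtype)
        np.put_along_axis(dxt, self._argmax[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((n, l, c), dtype=dy.dtype)
        dx[:, : nw * self.size, :] = dxt.reshape(n, nw * self.size, c)
        return dx


class Flatten(Layer):
    def forward(self, x, training, rng):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int):
        self.in_dim = in_dim
        self.out_dim = out_dim
        self.W = Param(np.zeros((in_dim, out_dim), dtype=np.float32))
        self.b = Param(np.zeros(out_dim, dtype=np.float32))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x, training, rng):
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Param], lr: float = 5e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(p.grad)
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
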