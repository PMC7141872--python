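"""Minimal feed-forward neural-network engine on numpy.

Implements exactly the layer set the enrichment predictors need — 1-D
convolution with 'same' length, non-overlapping max-pooling, dense layers,
ReLU and inverted dropout — with hand-written backpropagation and an Adam
optimizer.  Backprop reaches all the way to the input tensor, which is what
gradient-ascent sequence design requires: the same machinery that trains
the weights also supplies d(score)/d(input) for a frozen network.

Conventions: inputs are (batch, length, channels) float64 arrays;
convolution stride is 1 with zero 'same' padding; pooling is window 2,
stride 2, 'valid' (floor division of the length).  All randomness
(initialization, dropout masks, batch shuffling) flows through a single
``numpy.random.Generator``, so training is bit-reproducible given a seed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np


class Layer:
    """Base layer: forward caches what backward needs."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """Length-preserving 1-D convolution, stride 1, zero padding."""

    def __init__(self, in_channels: int, out_channels: int, width: int, rng: np.random.Generator):
        self.width = width
        fan_in = width * in_channels
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(width, in_channels, out_channels))
        self.b = np.zeros(out_channels)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def _pad(self, x: np.ndarray) -> np.ndarray:
        left = (self.width - 1) // 2
        right = self.width - 1 - left
        return np.pad(x, ((0, 0), (left, right), (0, 0)))

    def forward(self, x, training=False):
        self._x = x
        xp = self._pad(x)
        # windows: (batch, length, width, channels)
        win = np.lib.stride_tricks.sliding_window_view(xp, self.width, axis=1)
        self._win = win  # (B, L, C, width)
        return np.einsum("blcw,wco->blo", win, self.W, optimize=True) + self.b

    def backward(self, dy):
        self.dW[...] = np.einsum("blcw,blo->wco", self._win, dy, optimize=True)
        self.db[...] = dy.sum(axis=(0, 1))
        B, L, _ = dy.shape
        left = (self.width - 1) // 2
        dxp = np.zeros((B, L + self.width - 1, self.W.shape[1]))
        for w in range(self.width):
            dxp[:, w : w + L, :] += dy @ self.W[w].T
        return dxp[:, left : left + L, :]


class MaxPool1D(Layer):
    """Non-overlapping max-pooling, window 2, stride 2, 'valid'."""

    def __init__(self, window: int = 2):
        self.window = window

    def forward(self, x, training=False):
        B, L, C = x.shape
        Lp = L // self.window
        xr = x[:, : Lp * self.window, :].reshape(B, Lp, self.window, C)
        self._arg = np.argmax(xr, axis=2)
        self._shape = x.shape
        return np.max(xr, axis=2)

    def backward(self, dy):
        B, Lp, C = dy.shape
        dxr = np.zeros((B, Lp, self.window, C))
        bi, pi, ci = np.ogrid[:B, :Lp, :C]
        dxr[bi, pi, self._arg, ci] = dy
        dx = np.zeros(self._shape)
        dx[:, : Lp * self.window, :] = dxr.reshape(B, Lp * self.window, C)
        return dx


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(in_features, out_features))
        self.b = np.zeros(out_features)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate {rate} outside [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Network:
    """A layer stack with forward, backward and input-gradient passes."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params()))

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def input_gradient(self, x: np.ndarray, output_index: int = 0) -> np.ndarray:
        """d(output[:, output_index]) / d(input), weights frozen, eval mode."""
        out = self.forward(x, training=False)
        dy = np.zeros_like(out)
        dy[:, output_index] = 1.0
        return self.backward(dy)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        params = self.params()
        if len(weights) != len(params):
            raise ValueError("weight list length mismatch")
        for p, w in zip(params, weights):
            if p.shape != w.shape:
                raise ValueError(f"shape mismatch {p.shape} vs {w.shape}")
            p[...] = w


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params: Sequence[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads: Sequence[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
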