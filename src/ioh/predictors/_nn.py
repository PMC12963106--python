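"""Minimal 1-D convolutional network primitives in numpy.

Implements exactly the pieces the hypotension CNN needs: same-padded 1-D
convolution (im2col), batch normalization, ReLU, stride-2 max pooling,
dropout, global average pooling, dense layers, a numerically stable weighted
binary cross-entropy on logits, and Adam. Forward passes cache what the
corresponding backward pass needs; all state lives in plain arrays so models
can be serialized with ``numpy.savez``.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


# ---------------------------------------------------------------------------
# Layers
# ---------------------------------------------------------------------------

class Conv1d:
    """Same-padded, stride-1 1-D convolution: (B, C_in, L) -> (B, C_out, L)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * kernel))
        self.w = (rng.standard_normal((c_out, c_in * kernel)) * scale).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.kernel = kernel
        self.c_in = c_in
        self.c_out = c_out

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        k = self.kernel
        pl, pr = (k - 1) // 2, k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pl, pr)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)  # B,C,L,k
        b_sz, _, length, _ = cols.shape
        cols = cols.transpose(0, 2, 1, 3).reshape(b_sz * length, self.c_in * k)
        self._cols = cols
        self._in_shape = x.shape
        y = cols @ self.w.T + self.b
        return y.reshape(b_sz, length, self.c_out).transpose(0, 2, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b_sz, _, length = dy.shape
        k = self.kernel
        dyf = dy.transpose(0, 2, 1).reshape(b_sz * length, self.c_out)
        self.dw = (dyf.T @ self._cols).astype(DTYPE)
        self.db = dyf.sum(axis=0).astype(DTYPE)
        dcols = (dyf @ self.w).reshape(b_sz, length, self.c_in, k)
        pl, pr = (k - 1) // 2, k // 2
        dxp = np.zeros((b_sz, self.c_in, length + pl + pr), dtype=DTYPE)
        for j in range(k):
            dxp[:, :, j:j + length] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dxp[:, :, pl:pl + length]

    params = property(lambda self: [("w", self.w), ("b", self.b)])


class BatchNorm1d:
    """Per-channel batch normalization over batch and length axes."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=DTYPE)
        self.beta = np.zeros(channels, dtype=DTYPE)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv[None, :, None]
        self._cache = (xhat, inv)
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        n = dy.shape[0] * dy.shape[2]
        self.dgamma = (dy * xhat).sum(axis=(0, 2)).astype(DTYPE)
        self.dbeta = dy.sum(axis=(0, 2)).astype(DTYPE)
        g = self.gamma[None, :, None]
        dxhat = dy * g
        dx = (inv[None, :, None] / n) * (
            n * dxhat
            - dxhat.sum(axis=(0, 2), keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=(0, 2), keepdims=True))
        return dx.astype(DTYPE)

    params = property(lambda self: [("gamma", self.gamma), ("beta", self.beta)])


class ReLU:
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask

    params = property(lambda self: [])


class MaxPool2:
    """Non-overlapping stride-2 max pooling; an odd trailing element is dropped."""

    def forward(self, x, train):
        if x.shape[2] < 2:
            raise ValueError("sequence too short for the pooling depth")
        length = (x.shape[2] // 2) * 2
        self._in_len = x.shape[2]
        a, b = x[:, :, 0:length:2], x[:, :, 1:length:2]
        self._take_first = a >= b
        return np.where(self._take_first, a, b)

    def backward(self, dy):
        b_sz, c, half = dy.shape
        dx = np.zeros((b_sz, c, self._in_len), dtype=DTYPE)
        dx[:, :, 0:2 * half:2] = np.where(self._take_first, dy, 0)
        dx[:, :, 1:2 * half:2] = np.where(self._take_first, 0, dy)
        return dx

    params = property(lambda self: [])


class Dropout:
    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask

    params = property(lambda self: [])


class GlobalAvgPool:
    def forward(self, x, train):
        self._len = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dy):
        return np.repeat(dy[:, :, None], self._len, axis=2) / self._len

    params = property(lambda self: [])


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(DTYPE)
        self.b = np.zeros(n_out, dtype=DTYPE)

    def forward(self, x, train):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw = (self._x.T @ dy).astype(DTYPE)
        self.db = dy.sum(axis=0).astype(DTYPE)
        return dy @ self.w.T

    params = property(lambda self: [("w", self.w), ("b", self.b)])


# ---------------------------------------------------------------------------
# Loss and optimizer
# ---------------------------------------------------------------------------

def weighted_bce_with_logits(logits: np.ndarray, labels: np.ndarray,
                             weights: np.ndarray):
    """Mean weighted binary cross-entropy on logits; returns (loss, dlogits)."""
    z = logits.astype(np.float64)
    loss_i = np.maximum(z, 0) - z * labels + np.log1p(np.exp(-np.abs(z)))
    loss = float(np.mean(weights * loss_i))
    p = 1.0 / (1.0 + np.exp(-z))
    dz = weights * (p - labels) / len(z)
    return loss, dz.astype(DTYPE)


class Adam:
    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{name: np.zeros_like(p) for name, p in l.params} for l in self.layers]
        self.v = [{name: np.zeros_like(p) for name, p in l.params} for l in self.layers]

    def step(self) -> None:
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for i, layer in enumerate(self.layers):
            for name, p in layer.params:
                g = getattr(layer, "d" + name)
                m = self.m[i][name]
                v = self.v[i][name]
                m[:] = self.b1 * m + (1 - self.b1) * g
                v[:] = self.b2 * v + (1 - self.b2) * g * g
                p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)


class Sequential:
    def __init__(self, layers):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def state_dict(self) -> dict:
        state = {}
        for i, layer in enumerate(self.layers):
            for name, p in layer.params:
                state[f"{i}.{name}"] = p.copy()
            if isinstance(layer, BatchNorm1d):
                state[f"{i}.running_mean"] = layer.running_mean.copy()
                state[f"{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        for i, layer in enumerate(self.layers):
            for name, p in layer.params:
                p[:] = state[f"{i}.{name}"]
            if isinstance(layer, BatchNorm1d):
                layer.running_mean[:] = state[f"{i}.running_mean"]
                layer.running_var[:] = state[f"{i}.running_var"]
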