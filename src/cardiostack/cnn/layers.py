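"""Minimal NumPy layers with forward/backward passes and an Adam optimizer.

Everything runs in float32. Convolutions are stride-1, zero-padded to "same"
size via im2col; max-pooling is 2x2 stride 2 with odd trailing rows/columns
truncated.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "BatchNorm2d", "ReLU", "MaxPool2", "GlobalAvgPool", "Linear", "softmax", "cross_entropy", "Adam"]


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.k = k
        fan_in = c_in * k * k
        self.w = (rng.standard_normal((c_out, c_in, k, k)) * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(c_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None
        self._xshape: tuple | None = None

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x, train):
        n, c, h, w = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (N, C, H, W, k, k) -> (N*H*W, C*k*k)
        cols = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))
        cols = cols.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * self.k * self.k)
        self._cols = cols if train else None
        self._xshape = x.shape
        wmat = self.w.reshape(self.w.shape[0], -1)
        y = cols @ wmat.T + self.b
        return np.ascontiguousarray(y.reshape(n, h, w, -1).transpose(0, 3, 1, 2))

    def backward(self, dy):
        n, c, h, w = self._xshape
        k = self.k
        dymat = dy.transpose(0, 2, 3, 1).reshape(n * h * w, -1)
        self.dw[...] = (dymat.T @ self._cols).reshape(self.w.shape)
        self.db[...] = dymat.sum(axis=0)
        dcols = dymat @ self.w.reshape(self.w.shape[0], -1)
        dcols = dcols.reshape(n, h, w, c, k, k)
        p = k // 2
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w]


class BatchNorm2d(Layer):
    def __init__(self, c: int, eps: float = 1e-5):
        self.gamma = np.ones(c, dtype=np.float32)
        self.beta = np.zeros(c, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.n_batches = 0
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def forward(self, x, train):
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            # cumulative moving average: calibrates eval statistics quickly
            # even after only a handful of optimizer steps
            t = self.n_batches
            self.running_mean = (self.running_mean * t + mean) / (t + 1)
            self.running_var = (self.running_var * t + var) / (t + 1)
            self.n_batches = t + 1
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return (self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]).astype(np.float32)

    def backward(self, dy):
        xhat, inv = self._cache
        m = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.dgamma[...] = (dy * xhat).sum(axis=(0, 2, 3))
        self.dbeta[...] = dy.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None] * inv[None, :, None, None]
        term = dy - self.dbeta[None, :, None, None] / m - xhat * self.dgamma[None, :, None, None] / m
        return (g * term).astype(np.float32)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class MaxPool2(Layer):
    """2x2 stride-2 max pooling; odd trailing rows/columns are dropped."""

    def forward(self, x, train):
        n, c, h, w = x.shape
        ho, wo = h // 2, w // 2
        xt = x[:, :, : ho * 2, : wo * 2].reshape(n, c, ho, 2, wo, 2)
        patches = xt.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, 4)
        self._arg = patches.argmax(axis=-1)
        self._xshape = x.shape
        return patches.max(axis=-1)

    def backward(self, dy):
        n, c, h, w = self._xshape
        ho, wo = h // 2, w // 2
        dpatch = np.zeros((n, c, ho, wo, 4), dtype=np.float32)
        np.put_along_axis(dpatch, self._arg[..., None], dy[..., None].astype(np.float32), axis=-1)
        dx = np.zeros((n, c, h, w), dtype=np.float32)
        dx[:, :, : ho * 2, : wo * 2] = (
            dpatch.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho * 2, wo * 2)
        )
        return dx


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._xshape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy):
        n, c, h, w = self._xshape
        return np.broadcast_to(dy[:, :, None, None] / (h * w), self._xshape).astype(np.float32)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.w = (rng.standard_normal((d_out, d_in)) * np.sqrt(2.0 / d_in)).astype(np.float32)
        self.b = np.zeros(d_out, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x, train):
        self._x = x if train else None
        return x @ self.w.T + self.b

    def backward(self, dy):
        self.dw[...] = dy.T @ self._x
        self.db[...] = dy.sum(axis=0)
        return dy @ self.w


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, soft_labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy against (possibly soft) labels and dL/dlogits."""
    n = probs.shape[0]
    loss = float(-(soft_labels * np.log(probs + 1e-12)).sum() / n)
    dlogits = ((probs - soft_labels) / n).astype(np.float32)
    return loss, dlogits


class Adam:
    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params, self.grad_refs = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.b2**self.t) / (1 - self.b1**self.t)
        for p, g, m, v in zip(self.params, self.grad_refs, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)
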