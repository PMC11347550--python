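"""Minimal neural-network layers on numpy with explicit backpropagation.

Only what the risk model needs: 3x3 same-padding convolution (im2col), ReLU, 2x2
max pooling, global average pooling, dense layers, a single-cell LSTM unrolled
over a short sequence, and Adam. Every layer caches its forward activations and
exposes ``backward`` returning the input gradient while accumulating parameter
gradients in ``Param.grad``.
"""

from __future__ import annotations

import numpy as np


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []


class Conv2d(Layer):
    """3x3 convolution, stride 1, zero padding 1 (spatial shape preserved)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float32):
        scale = np.sqrt(2.0 / (c_in * 9))
        self.W = Param((rng.standard_normal((c_out, c_in, 3, 3)) * scale).astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
        # (n, c, h, w, 3, 3) -> (n, c*9, h*w)
        return np.ascontiguousarray(win.transpose(0, 1, 4, 5, 2, 3)).reshape(n, c * 9, h * w)

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = self._im2col(x)
        Wm = self.W.value.reshape(self.W.value.shape[0], -1)
        out = np.einsum("ok,nkp->nop", Wm, cols, optimize=True)
        out += self.b.value[None, :, None]
        self._cache = (cols, x.shape)
        return out.reshape(n, -1, h, w)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, c, h, w = xshape
        c_out = dout.shape[1]
        dflat = dout.reshape(n, c_out, h * w)
        Wm = self.W.value.reshape(c_out, -1)
        self.W.grad += np.einsum("nop,nkp->ok", dflat, cols, optimize=True).reshape(
            self.W.value.shape)
        self.b.grad += dflat.sum(axis=(0, 2))
        dcols = np.einsum("ok,nop->nkp", Wm, dflat, optimize=True)
        dcols = dcols.reshape(n, c, 3, 3, h, w)
        dxp = np.zeros((n, c, h + 2, w + 2), dtype=dout.dtype)
        for i in range(3):
            for j in range(3):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, i, j]
        return dxp[:, :, 1:-1, 1:-1]


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class LeakyReLU(Layer):
    """max(x, slope*x); the small negative slope keeps gradients alive even when
    a unit's pre-activations are negative for every sample in a batch."""

    def __init__(self, slope: float = 0.1):
        self.slope = slope

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; spatial dims must be even."""

    def forward(self, x):
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        # duplicate maxima share the gradient equally (see backward)
        self._mask = xr == out[:, :, :, None, :, None]
        self._xshape = x.shape
        return out

    def backward(self, dout):
        n, c, h, w = self._xshape
        mask = self._mask
        counts = mask.sum(axis=(3, 5), keepdims=True)
        d = (mask / counts) * dout[:, :, :, None, :, None]
        return d.reshape(n, c, h, w)


class GlobalAvgPool(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w), self._shape).astype(dout.dtype)


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, dtype=np.float32):
        scale = np.sqrt(2.0 / d_in)
        self.W = Param((rng.standard_normal((d_in, d_out)) * scale).astype(dtype))
        self.b = Param(np.zeros(d_out, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class LSTM(Layer):
    """Single-layer LSTM returning the last hidden state.

    Input (N, T, d_in); gates ordered (input, forget, cell, output). T is short
    (two timepoints), so the sequence is unrolled explicitly.
    """

    def __init__(self, d_in: int, d_hidden: int, rng: np.random.Generator, dtype=np.float32):
        h = d_hidden
        scale = 1.0 / np.sqrt(max(d_in, h))
        self.W_ih = Param((rng.standard_normal((d_in, 4 * h)) * scale).astype(dtype))
        self.W_hh = Param((rng.standard_normal((h, 4 * h)) * scale).astype(dtype))
        self.b = Param(np.zeros(4 * h, dtype=dtype))
        self.h = h

    def params(self):
        return [self.W_ih, self.W_hh, self.b]

    def forward(self, x):
        n, T, _ = x.shape
        h = self.h
        h_t = np.zeros((n, h), dtype=x.dtype)
        c_t = np.zeros((n, h), dtype=x.dtype)
        self._x = x
        self._caches = []
        for t in range(T):
            z = x[:, t] @ self.W_ih.value + h_t @ self.W_hh.value + self.b.value
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h:2 * h])
            g = np.tanh(z[:, 2 * h:3 * h])
            o = _sigmoid(z[:, 3 * h:])
            c_new = f * c_t + i * g
            tanh_c = np.tanh(c_new)
            self._caches.append((h_t, c_t, i, f, g, o, c_new, tanh_c))
            h_t, c_t = o * tanh_c, c_new
        return h_t

    def backward(self, dh_last):
        x = self._x
        n, T, _ = x.shape
        h = self.h
        dx = np.zeros_like(x)
        dh = dh_last
        dc = np.zeros_like(dh_last)
        for t in reversed(range(T)):
            h_prev, c_prev, i, f, g, o, c_new, tanh_c = self._caches[t]
            do = dh * tanh_c
            dc = dc + dh * o * (1 - tanh_c**2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([
                di * i * (1 - i), df * f * (1 - f),
                dg * (1 - g**2), do * o * (1 - o),
            ], axis=1)
            self.W_ih.grad += x[:, t].T @ dz
            self.W_hh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, t] = dz @ self.W_ih.value.T
            dh = dz @ self.W_hh.value.T
            dc = dc * f
        return dx


class Adam:
    """Adam with optional decoupled weight decay (AdamW-style)."""

    def __init__(self, params: list[Param], lr: float, beta1=0.9, beta2=0.999,
                 eps=1e-8, weight_decay: float = 0.0):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            if self.weight_decay:
                p.value -= self.lr * self.weight_decay * p.value
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
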