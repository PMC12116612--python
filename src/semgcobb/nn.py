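"""Minimal NumPy neural-network engine for the sequence-regression models.

Implements exactly the layers the model zoo needs — dilated causal 1-D
convolution, batch normalisation, ReLU, dropout, temporal pooling, LSTM
and dense layers — each with an explicit hand-written backward pass, plus
the Adam optimiser.  Tensors are [batch, time, channels]; gradients are
checked against finite differences in the test suite.

The engine is deliberately small and CPU-oriented: float32 by default,
no graph compiler, caches held on the layer between forward and backward
(so a layer instance is not re-entrant across concurrent training steps).
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    train_mode: bool = False

    def params(self) -> list[Param]:
        return []

    def set_mode(self, train: bool) -> None:
        self.train_mode = train

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32):
        scale = np.sqrt(2.0 / n_in)  # He initialisation (ReLU networks)
        self.W = Param(rng.normal(0.0, scale, (n_in, n_out)).astype(dtype))
        self.b = Param(np.zeros(n_out, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    def forward(self, x):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy):
        self.W.grad += self._x.reshape(-1, self._x.shape[-1]).T @ dy.reshape(-1, dy.shape[-1])
        self.b.grad += dy.reshape(-1, dy.shape[-1]).sum(axis=0)
        return dy @ self.W.value.T


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0 <= p < 1:
            raise ValueError("dropout must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x):
        if not self.train_mode or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        self._mask = self._mask.astype(x.dtype)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class CausalConv1d(Layer):
    """Dilated causal convolution on [B, T, C] tensors.

    Output at time t depends on inputs t, t-d, ..., t-(k-1)d; left
    zero-padding keeps the length unchanged.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, dilation: int,
                 rng: np.random.Generator, dtype=np.float32):
        if kernel < 1 or dilation < 1:
            raise ValueError("kernel and dilation must be >= 1")
        self.k, self.d, self.c_in = kernel, dilation, c_in
        scale = np.sqrt(2.0 / (kernel * c_in))
        self.W = Param(rng.normal(0.0, scale, (kernel * c_in, c_out)).astype(dtype))
        self.b = Param(np.zeros(c_out, dtype=dtype))

    def params(self):
        return [self.W, self.b]

    @property
    def reach(self) -> int:
        """Number of past steps the output can see beyond the current one."""
        return (self.k - 1) * self.d

    def _cols(self, x):
        B, T, C = x.shape
        pad = self.reach
        xp = np.concatenate([np.zeros((B, pad, C), dtype=x.dtype), x], axis=1)
        return np.concatenate(
            [xp[:, j * self.d : j * self.d + T, :] for j in range(self.k)], axis=-1
        )

    def forward(self, x):
        self._shape = x.shape
        self._cols_cache = self._cols(x)
        return self._cols_cache @ self.W.value + self.b.value

    def backward(self, dy):
        B, T, C = self._shape
        kc = self.k * C
        self.W.grad += (
            self._cols_cache.reshape(-1, kc).T @ dy.reshape(-1, dy.shape[-1])
        )
        self.b.grad += dy.reshape(-1, dy.shape[-1]).sum(axis=0)
        dcols = dy @ self.W.value.T
        pad = self.reach
        dxp = np.zeros((B, T + pad, C), dtype=dy.dtype)
        for j in range(self.k):
            dxp[:, j * self.d : j * self.d + T, :] += dcols[..., j * C : (j + 1) * C]
        return dxp[:, pad:, :]


class BatchNorm(Layer):
    """Per-channel batch normalisation over all leading axes of [.., C]."""

    def __init__(self, c: int, momentum: float = 0.9, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Param(np.ones(c, dtype=dtype))
        self.beta = Param(np.zeros(c, dtype=dtype))
        self.momentum, self.eps = momentum, eps
        self.run_mean = np.zeros(c, dtype=np.float64)
        self.run_var = np.ones(c, dtype=np.float64)

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        flat = x.reshape(-1, x.shape[-1])
        if self.train_mode:
            mu = flat.mean(axis=0)
            var = flat.var(axis=0)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mu
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mu, var = self.run_mean.astype(x.dtype), self.run_var.astype(x.dtype)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv.astype(x.dtype), flat.shape[0])
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy):
        xhat, inv, n = self._cache
        dflat = dy.reshape(-1, dy.shape[-1])
        xflat = xhat.reshape(-1, xhat.shape[-1])
        self.gamma.grad += (dflat * xflat).sum(axis=0)
        self.beta.grad += dflat.sum(axis=0)
        if not self.train_mode:
            return dy * (self.gamma.value * inv)
        dxhat = dflat * self.gamma.value
        dx = (
            dxhat
            - dxhat.mean(axis=0)
            - xflat * (dxhat * xflat).mean(axis=0)
        ) * inv
        return dx.reshape(dy.shape)


class AvgPoolTime(Layer):
    """Non-overlapping temporal average pooling on [B, T, C]."""

    def __init__(self, stride: int):
        if stride < 1:
            raise ValueError("stride must be >= 1")
        self.stride = stride

    def forward(self, x):
        B, T, C = x.shape
        s = self.stride
        self._T = T
        if s == 1:
            return x
        Tp = T // s
        self._Tp = Tp
        return x[:, : Tp * s, :].reshape(B, Tp, s, C).mean(axis=2)

    def backward(self, dy):
        if self.stride == 1:
            return dy
        B, Tp, C = dy.shape
        s = self.stride
        dx = np.zeros((B, self._T, C), dtype=dy.dtype)
        dx[:, : Tp * s, :] = np.repeat(dy / s, s, axis=1)
        return dx


class GlobalAvgPoolTime(Layer):
    def forward(self, x):
        self._T = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy):
        return np.repeat(dy[:, None, :] / self._T, self._T, axis=1)


class StrideTime(Layer):
    """Plain temporal subsampling x[:, ::stride, :]."""

    def __init__(self, stride: int):
        self.stride = stride

    def forward(self, x):
        self._shape = x.shape
        return x[:, :: self.stride, :]

    def backward(self, dy):
        dx = np.zeros(self._shape, dtype=dy.dtype)
        dx[:, :: self.stride, :] = dy
        return dx


class LSTM(Layer):
    """Single LSTM layer (gate order i, f, g, o; forget-gate bias 1)."""

    def __init__(self, n_in: int, units: int, rng: np.random.Generator,
                 return_sequences: bool, dtype=np.float32):
        self.units = units
        self.return_sequences = return_sequences
        scale = np.sqrt(1.0 / units)
        self.Wx = Param(rng.uniform(-scale, scale, (n_in, 4 * units)).astype(dtype))
        self.Wh = Param(rng.uniform(-scale, scale, (units, 4 * units)).astype(dtype))
        b = np.zeros(4 * units, dtype=dtype)
        b[units : 2 * units] = 1.0
        self.b = Param(b)

    def params(self):
        return [self.Wx, self.Wh, self.b]

    @staticmethod
    def _sigmoid(z):
        return expit(z)

    def forward(self, x):
        B, T, _ = x.shape
        u = self.units
        dtype = x.dtype
        h = np.zeros((B, u), dtype=dtype)
        c = np.zeros((B, u), dtype=dtype)
        self._x = x
        self._cache = []
        ys = np.empty((B, T, u), dtype=dtype) if self.return_sequences else None
        for t in range(T):
            z = x[:, t, :] @ self.Wx.value + h @ self.Wh.value + self.b.value
            i = self._sigmoid(z[:, :u])
            f = self._sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = self._sigmoid(z[:, 3 * u :])
            c_new = f * c + i * g
            tc = np.tanh(c_new)
            h_new = o * tc
            self._cache.append((h, c, i, f, g, o, tc))
            h, c = h_new, c_new
            if self.return_sequences:
                ys[:, t, :] = h
        self._h_last = h
        return ys if self.return_sequences else h

    def backward(self, dy):
        x = self._x
        B, T, _ = x.shape
        u = self.units
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, u), dtype=x.dtype)
        dc_next = np.zeros((B, u), dtype=x.dtype)
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tc = self._cache[t]
            if self.return_sequences:
                dh = dy[:, t, :] + dh_next
            else:
                dh = (dy + dh_next) if t == T - 1 else dh_next
            dc = dc_next + dh * o * (1.0 - tc**2)
            do = dh * tc
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g**2),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            self.Wx.grad += x[:, t, :].T @ dz
            self.Wh.grad += h_prev.T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.Wx.value.T
            dh_next = dz @ self.Wh.value.T
            dc_next = dc * f
        return dx


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def set_mode(self, train):
        for l in self.layers:
            l.set_mode(train)

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


class Residual(Layer):
    """y = inner(x) + skip(x); skip is identity or a 1x1 projection."""

    def __init__(self, inner: Sequential, skip: Layer | None):
        self.inner = inner
        self.skip = skip

    def params(self):
        return self.inner.params() + (self.skip.params() if self.skip else [])

    def set_mode(self, train):
        self.inner.set_mode(train)
        if self.skip:
            self.skip.set_mode(train)

    def forward(self, x):
        y = self.inner.forward(x)
        return y + (self.skip.forward(x) if self.skip else x)

    def backward(self, dy):
        dx = self.inner.backward(dy)
        return dx + (self.skip.backward(dy) if self.skip else dy)


class Adam:
    """Adam optimiser over a flat parameter list."""

    def __init__(self, params: list[Param], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
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
            m[...] = self.b1 * m + (1 - self.b1) * p.grad
            v[...] = self.b2 * v + (1 - self.b2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
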