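"""Minimal feed-forward layer zoo with reverse-mode gradients (numpy).

Covers exactly what the genotype-to-phenotype architectures need: dense,
1-D convolution, 1-D locally connected (unshared filters per genome window),
batch normalization, dropout, max pooling, and ReLU/tanh activations, plus an
Adam optimizer.  Convolution-style layers take input of shape
(batch, channels, length); dense layers take (batch, features).
"""

from __future__ import annotations

import numpy as np

EPS = 1e-5


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.dW[...] = self._x.T @ g
        self.db[...] = g.sum(axis=0)
        return g @ self.W.T


class BatchNorm(Layer):
    """Normalizes per feature (2-D input) or per channel (3-D input)."""

    def __init__(self, dim: int, momentum: float = 0.9) -> None:
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.dgamma = np.zeros(dim)
        self.dbeta = np.zeros(dim)
        self.run_mean = np.zeros(dim)
        self.run_var = np.ones(dim)
        self.momentum = momentum

    def params(self):
        return [self.gamma, self.beta]

    def grads(self):
        return [self.dgamma, self.dbeta]

    def _axes(self, x):
        return (0,) if x.ndim == 2 else (0, 2)

    def _shape(self, x):
        return (1, -1) if x.ndim == 2 else (1, -1, 1)

    def forward(self, x, train):
        ax, sh = self._axes(x), self._shape(x)
        if train:
            mean = x.mean(axis=ax)
            var = x.var(axis=ax)
            self.run_mean = self.momentum * self.run_mean + (1 - self.momentum) * mean
            self.run_var = self.momentum * self.run_var + (1 - self.momentum) * var
        else:
            mean, var = self.run_mean, self.run_var
        self._std = np.sqrt(var + EPS)
        self._xhat = (x - mean.reshape(sh)) / self._std.reshape(sh)
        self._train_n = x.size // x.shape[1] if x.ndim == 3 else x.shape[0]
        return self.gamma.reshape(sh) * self._xhat + self.beta.reshape(sh)

    def backward(self, g):
        ax, sh = self._axes(g), self._shape(g)
        n = self._train_n
        self.dgamma[...] = (g * self._xhat).sum(axis=ax)
        self.dbeta[...] = g.sum(axis=ax)
        gx = g * self.gamma.reshape(sh)
        return (gx - gx.mean(axis=ax).reshape(sh)
                - self._xhat * (gx * self._xhat).mean(axis=ax).reshape(sh)) / self._std.reshape(sh)


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        if not (0 <= rate < 1):
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class ReLU(Layer):
    def forward(self, x, train):
        self._pos = x > 0
        return np.where(self._pos, x, 0.0)

    def backward(self, g):
        return g * self._pos


class Tanh(Layer):
    def forward(self, x, train):
        self._y = np.tanh(x)
        return self._y

    def backward(self, g):
        return g * (1.0 - self._y**2)


def _windows(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    # (N, C, L) -> (N, C, L', k)
    return np.lib.stride_tricks.sliding_window_view(x, k, axis=2)[:, :, ::stride]


def conv_out_len(length: int, kernel: int, stride: int) -> int:
    if kernel > length:
        raise ValueError(f"kernel {kernel} exceeds input length {length}")
    return (length - kernel) // stride + 1


class Conv1d(Layer):
    def __init__(self, in_ch: int, filters: int, kernel: int, stride: int,
                 rng: np.random.Generator) -> None:
        self.kernel, self.stride = kernel, stride
        self.W = rng.normal(0.0, np.sqrt(2.0 / (in_ch * kernel)), size=(filters, in_ch, kernel))
        self.b = np.zeros(filters)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train):
        self._x_shape = x.shape
        self._win = _windows(x, self.kernel, self.stride)
        return np.einsum("nclk,fck->nfl", self._win, self.W) + self.b[None, :, None]

    def backward(self, g):
        self.dW[...] = np.einsum("nfl,nclk->fck", g, self._win)
        self.db[...] = g.sum(axis=(0, 2))
        dx = np.zeros(self._x_shape)
        lp = g.shape[2]
        pos = self.stride * np.arange(lp)
        for kk in range(self.kernel):
            dx[:, :, pos + kk] += np.einsum("nfl,fc->ncl", g, self.W[:, :, kk])
        return dx


class LocallyConnected1d(Layer):
    """Convolution with position-specific (unshared) filters along the genome."""

    def __init__(self, in_ch: int, filters: int, kernel: int, stride: int,
                 length: int, rng: np.random.Generator) -> None:
        self.kernel, self.stride = kernel, stride
        lp = conv_out_len(length, kernel, stride)
        self.W = rng.normal(0.0, np.sqrt(2.0 / (in_ch * kernel)),
                            size=(lp, filters, in_ch, kernel))
        self.b = np.zeros((filters, lp))
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x, train):
        self._x_shape = x.shape
        self._win = _windows(x, self.kernel, self.stride)
        return np.einsum("nclk,lfck->nfl", self._win, self.W) + self.b[None]

    def backward(self, g):
        self.dW[...] = np.einsum("nfl,nclk->lfck", g, self._win)
        self.db[...] = g.sum(axis=0)
        dx = np.zeros(self._x_shape)
        lp = g.shape[2]
        pos = self.stride * np.arange(lp)
        for kk in range(self.kernel):
            dx[:, :, pos + kk] += np.einsum("nfl,lfc->ncl", g, self.W[:, :, :, kk])
        return dx


class MaxPool1d(Layer):
    def __init__(self, pool: int) -> None:
        self.pool = pool

    def forward(self, x, train):
        n, c, length = x.shape
        lp = length // self.pool
        if lp == 0:
            raise ValueError(f"pool size {self.pool} exceeds length {length}")
        self._trim = x.shape
        xr = x[:, :, : lp * self.pool].reshape(n, c, lp, self.pool)
        self._arg = xr.argmax(axis=3)
        return xr.max(axis=3)

    def backward(self, g):
        n, c, lp = g.shape
        dx = np.zeros((n, c, lp, self.pool))
        idx_n, idx_c, idx_l = np.ogrid[:n, :c, :lp]
        dx[idx_n, idx_c, idx_l, self._arg] = g
        out = np.zeros(self._trim)
        out[:, :, : lp * self.pool] = dx.reshape(n, c, lp * self.pool)
        return out


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Sequential:
    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, g: np.ndarray) -> None:
        for layer in reversed(self.layers):
            g = layer.backward(g)

    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def state(self) -> list[np.ndarray]:
        out = [p.copy() for p in self.params()]
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                out.extend([layer.run_mean.copy(), layer.run_var.copy()])
        return out

    def load_state(self, state: list[np.ndarray]) -> None:
        ps = self.params()
        for p, s in zip(ps, state[: len(ps)]):
            p[...] = s
        extra = iter(state[len(ps):])
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.run_mean[...] = next(extra)
                layer.run_var[...] = next(extra)


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g**2
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
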