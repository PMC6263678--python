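"""Minimal NumPy neural-network engine for the LSTM-FCN classifier.

Implements exactly the layers the architecture needs — 1-D 'same'
convolution (one BLAS matmul per kernel tap), batch normalization, ReLU, global
average pooling, a single-time-step LSTM (the dimension shuffle presents a
length-L univariate series as one step of L features, so no recurrence
unrolling is needed), inverted dropout, a dense softmax head — together
with their gradients and an Adam optimizer.  Everything is seeded and
pure NumPy, so training is bit-reproducible across runs.
"""

from __future__ import annotations

import numpy as np

#: working precision of the network (single precision, the conventional
#: choice for neural-network training)
DTYPE = np.float32


class Param:
    """A trainable tensor with its gradient and Adam state."""

    __slots__ = ("value", "grad", "m", "v")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)
        self.m = np.zeros_like(value)
        self.v = np.zeros_like(value)


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: list[Param], lr: float = 1e-3):
        self.params = params
        self.lr = lr
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for p in self.params:
            p.m = b1 * p.m + (1 - b1) * p.grad
            p.v = b2 * p.v + (1 - b2) * p.grad ** 2
            mhat = p.m / (1 - b1 ** self.t)
            vhat = p.v / (1 - b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class Conv1D:
    """1-D convolution, stride 1, 'same' zero padding (left (k-1)//2).

    Computed as a sum of k shifted matrix products — one BLAS call per
    kernel tap — which avoids materializing im2col windows.
    """

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (k * c_in))               # He init for ReLU nets
        self.W = Param(rng.normal(0.0, scale,
                                  size=(k, c_in, c_out)).astype(DTYPE))
        self.b = Param(np.zeros(c_out, dtype=DTYPE))
        self.k, self.c_in, self.c_out = k, c_in, c_out
        self.pad_left = (k - 1) // 2
        self.pad_right = k - 1 - self.pad_left
        self._x_padded: np.ndarray | None = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, l, _ = x.shape
        xp = np.pad(x, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        if train:
            self._x_padded = xp
        out = np.broadcast_to(self.b.value, (n, l, self.c_out)).copy()
        for j in range(self.k):
            # tap j sees x[t + j - pad_left]
            out += xp[:, j:j + l, :] @ self.W.value[j]
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._x_padded
        n, l, _ = dy.shape
        self.b.grad += dy.sum(axis=(0, 1))
        dxp = np.zeros_like(xp)
        dy2 = dy.reshape(n * l, self.c_out)
        for j in range(self.k):
            xj = xp[:, j:j + l, :].reshape(n * l, self.c_in)
            self.W.grad[j] += xj.T @ dy2
            dxp[:, j:j + l, :] += (dy2 @ self.W.value[j].T).reshape(
                n, l, self.c_in)
        if self.pad_right:
            return dxp[:, self.pad_left:-self.pad_right, :]
        return dxp[:, self.pad_left:, :]


class BatchNorm1D:
    """Per-channel batch normalization over the batch and time axes."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels, dtype=DTYPE))
        self.beta = Param(np.zeros(channels, dtype=DTYPE))
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    @property
    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        if train:
            self._cache = (xhat, inv_std, x.shape[0] * x.shape[1])
        return self.gamma.value * xhat + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, m = self._cache
        self.gamma.grad += (dy * xhat).sum(axis=(0, 1))
        self.beta.grad += dy.sum(axis=(0, 1))
        dxhat = dy * self.gamma.value
        return (inv_std / m) * (m * dxhat
                                - dxhat.sum(axis=(0, 1))
                                - xhat * (dxhat * xhat).sum(axis=(0, 1)))


class ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


class LSTMSingleStep:
    """One LSTM step over a single time step of L features (h0 = c0 = 0).

    With zero initial state the forget gate has no effect, leaving
    c = i * g and h = o * tanh(c); the gate weights are still all present
    so the parameterization matches a standard LSTM cell.
    """

    def __init__(self, n_features: int, units: int, rng: np.random.Generator):
        scale = np.sqrt(1.0 / n_features)               # Glorot-style
        self.W = Param(rng.normal(0.0, scale,
                                  size=(n_features, 4 * units)).astype(DTYPE))
        self.b = Param(np.zeros(4 * units, dtype=DTYPE))
        self.units = units
        self._cache = None

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        z = x @ self.W.value + self.b.value
        u = self.units
        i = _sigmoid(z[:, :u])
        g = np.tanh(z[:, 2 * u:3 * u])
        o = _sigmoid(z[:, 3 * u:])
        c = i * g
        tc = np.tanh(c)
        h = o * tc
        if train:
            self._cache = (x, i, g, o, c, tc)
        return h

    def backward(self, dh: np.ndarray) -> np.ndarray:
        x, i, g, o, c, tc = self._cache
        u = self.units
        do = dh * tc
        dc = dh * o * (1.0 - tc ** 2)
        di = dc * g
        dg = dc * i
        dz = np.zeros((x.shape[0], 4 * u), dtype=x.dtype)
        dz[:, :u] = di * i * (1.0 - i)
        dz[:, 2 * u:3 * u] = dg * (1.0 - g ** 2)
        dz[:, 3 * u:] = do * o * (1.0 - o)
        self.W.grad += x.T @ dz
        self.b.grad += dz.sum(axis=0)
        return dz @ self.W.value.T


class Dropout:
    """Inverted dropout with drop probability ``p``."""

    def __init__(self, p: float, rng: np.random.Generator):
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.p <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = ((self.rng.random(x.shape) < keep)
                      .astype(x.dtype) / x.dtype.type(keep))
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.W = Param(rng.normal(0.0, scale,
                                  size=(n_in, n_out)).astype(DTYPE))
        self.b = Param(np.zeros(n_out, dtype=DTYPE))

    @property
    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, y: np.ndarray) -> float:
    n = len(y)
    return float(-np.log(np.clip(probs[np.arange(n), y], 1e-12, None)).mean())
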