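"""Minimal NumPy neural-network backend for the hybrid CNN-LSTM decoder.

Implements exactly the layers the decoder needs — 1-D convolution along
time, exponential-linear-unit activation, average pooling, LSTM,
dropout, a dense softmax head — with reverse-mode gradients and an Adam
optimizer.  Everything is deterministic given the RNG passed in, and
all state lives in plain ndarrays, which keeps training reproducible
and portable (a model archive is a flat NPZ of weight arrays).

The LSTM layer follows the standard gate equations

    i_t = sigmoid(W_i x_t + U_i h_{t-1} + b_i)
    f_t = sigmoid(W_f x_t + U_f h_{t-1} + b_f)
    o_t = sigmoid(W_o x_t + U_o h_{t-1} + b_o)
    c~  = tanh   (W_c x_t + U_c h_{t-1} + b_c)
    c_t = f_t * c_{t-1} + i_t * c~
    h_t = o_t * tanh(c_t)

with gates packed in (i, f, o, c~) order along the last weight axis.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ShapeError


def sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


class Layer:
    """Base: parameters as a list of [value, grad] pairs."""

    def __init__(self):
        self.params = []

    def param(self, arr):
        pair = [arr, np.zeros_like(arr)]
        self.params.append(pair)
        return pair

    def forward(self, x, train=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv1d(Layer):
    """Same-padded 1-D convolution along the time axis.

    Input (B, C_in, T) -> output (B, C_out, T); odd kernel width.
    """

    def __init__(self, c_in, c_out, k, rng):
        super().__init__()
        if k % 2 == 0:
            raise ShapeError("kernel width must be odd for same padding")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        scale = np.sqrt(2.0 / (c_in * k))
        self.W = self.param(rng.standard_normal((c_in * k, c_out)) * scale)
        self.b = self.param(np.zeros(c_out))

    def forward(self, x, train=False):
        B, C, T = x.shape
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, self.k, axis=2)
        # cols: (B, C, T, k) -> (B, T, C*k)
        cols = cols.transpose(0, 2, 1, 3).reshape(B, T, C * self.k)
        self._cols, self._shape = cols, (B, C, T)
        y = cols @ self.W[0] + self.b[0]
        return y.transpose(0, 2, 1)          # (B, C_out, T)

    def backward(self, dy):
        B, C, T = self._shape
        dyt = dy.transpose(0, 2, 1)           # (B, T, C_out)
        self.W[1] += np.einsum("btk,btc->kc", self._cols, dyt)
        self.b[1] += dyt.sum(axis=(0, 1))
        dcols = dyt @ self.W[0].T             # (B, T, C*k)
        dcols = dcols.reshape(B, T, C, self.k)
        p = self.k // 2
        dxp = np.zeros((B, C, T + 2 * p))
        for j in range(self.k):
            dxp[:, :, j:j + T] += dcols[:, :, :, j].transpose(0, 2, 1)
        return dxp[:, :, p:p + T]


class ELU(Layer):
    def __init__(self, alpha=1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x, train=False):
        y = np.where(x > 0, x, self.alpha * (np.exp(np.minimum(x, 0.0)) - 1.0))
        self._x, self._y = x, y
        return y

    def backward(self, dy):
        return dy * np.where(self._x > 0, 1.0, self._y + self.alpha)


class AvgPool1d(Layer):
    """Non-overlapping average pooling; trailing remainder truncated."""

    def __init__(self, width):
        super().__init__()
        self.width = width

    def forward(self, x, train=False):
        B, C, T = x.shape
        n = T // self.width
        self._shape = (B, C, T, n)
        return x[:, :, :n * self.width].reshape(B, C, n, self.width).mean(-1)

    def backward(self, dy):
        B, C, T, n = self._shape
        dx = np.zeros((B, C, T))
        dx[:, :, :n * self.width] = np.repeat(dy, self.width, axis=2) / self.width
        return dx


class Fold(Layer):
    """(B, C, T) feature maps -> (B, T, C) sequence for the LSTM."""

    def forward(self, x, train=False):
        return x.transpose(0, 2, 1)

    def backward(self, dy):
        return dy.transpose(0, 2, 1)


class LSTMLayer(Layer):
    """Single LSTM layer over a (B, T, D) sequence, zero initial state."""

    def __init__(self, d_in, hidden, rng):
        super().__init__()
        self.d_in, self.hidden = d_in, hidden
        s_x = np.sqrt(1.0 / d_in)
        s_h = np.sqrt(1.0 / hidden)
        self.Wx = self.param(rng.standard_normal((d_in, 4 * hidden)) * s_x)
        self.Wh = self.param(rng.standard_normal((hidden, 4 * hidden)) * s_h)
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0            # forget-gate bias: remember by default
        self.b = self.param(b)

    def step(self, x_t, h_prev, c_prev):
        H = self.hidden
        a = x_t @ self.Wx[0] + h_prev @ self.Wh[0] + self.b[0]
        i = sigmoid(a[:, :H])
        f = sigmoid(a[:, H:2 * H])
        o = sigmoid(a[:, 2 * H:3 * H])
        g = np.tanh(a[:, 3 * H:])
        c = f * c_prev + i * g
        h = o * np.tanh(c)
        return h, c, (x_t, h_prev, c_prev, i, f, o, g, c)

    def forward(self, x, train=False):
        B, T, D = x.shape
        H = self.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._cache = []
        out = np.empty((B, T, H))
        for t in range(T):
            h, c, cache = self.step(x[:, t], h, c)
            self._cache.append(cache)
            out[:, t] = h
        return out

    def backward(self, dy):
        B, T, H = dy.shape
        dx = np.empty((B, T, self.d_in))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, o, g, c = self._cache[t]
            dh = dy[:, t] + dh_next
            tc = np.tanh(c)
            do = dh * tc
            dc = dc_next + dh * o * (1.0 - tc * tc)
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dc_next = dc * f
            da = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 do * o * (1 - o), dg * (1 - g * g)], axis=1)
            self.Wx[1] += x_t.T @ da
            self.Wh[1] += h_prev.T @ da
            self.b[1] += da.sum(axis=0)
            dx[:, t] = da @ self.Wx[0].T
            dh_next = da @ self.Wh[0].T
        return dx


class Dropout(Layer):
    def __init__(self, p, rng):
        super().__init__()
        self.p, self.rng = p, rng

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class LastStep(Layer):
    """Keep only the final time step of a (B, T, H) sequence."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x[:, -1]

    def backward(self, dy):
        dx = np.zeros(self._shape)
        dx[:, -1] = dy
        return dx


class Dense(Layer):
    def __init__(self, d_in, d_out, rng):
        super().__init__()
        scale = np.sqrt(2.0 / d_in)
        self.W = self.param(rng.standard_normal((d_in, d_out)) * scale)
        self.b = self.param(np.zeros(d_out))

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W[0] + self.b[0]

    def backward(self, dy):
        self.W[1] += self._x.T @ dy
        self.b[1] += dy.sum(axis=0)
        return dy @ self.W[0].T


class Sequential:
    def __init__(self, layers):
        self.layers = layers

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self):
        for value, grad in self.params:
            grad[...] = 0.0

    def state_arrays(self):
        return [value for value, _ in self.params]


def softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_grad(logits, targets):
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = -np.mean(np.log(p[np.arange(n), targets] + 1e-12))
    dlogits = p.copy()
    dlogits[np.arange(n), targets] -= 1.0
    return loss, dlogits / n


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(v) for v, _ in params]
        self.v = [np.zeros_like(v) for v, _ in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for (value, grad), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * grad
            v *= self.b2
            v += (1 - self.b2) * grad * grad
            value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
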