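"""Minimal reverse-mode layers for temporal sequence models.

Every layer implements ``forward(x, train)`` and ``backward(grad_out)``; the
backward pass consumes the cache stored by the most recent forward call and
accumulates parameter gradients in ``Parameter.grad``. Arrays are
``(batch, time, channels)`` throughout. Gradients are hand-derived and checked
against finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Dense",
    "Conv1d",
    "ReLU",
    "Dropout",
    "BatchNorm1d",
    "LayerNorm",
    "softmax",
    "scaled_dot_attention",
    "MultiHeadAttention",
    "LSTM",
    "BiLSTM",
]


class Parameter:
    """A trainable array with an accumulated gradient."""

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value)
        self.grad = np.zeros_like(self.value)

    @property
    def shape(self):
        return self.value.shape


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, x, train=False):
        return self.forward(x, train=train)


def _glorot(rng: np.random.Generator, shape, dtype) -> np.ndarray:
    fan_in, fan_out = shape[-2], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Dense(Layer):
    """Per-timestep affine map ``(B, T, Cin) -> (B, T, Cout)``."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, dtype=np.float32):
        self.W = Parameter(_glorot(rng, (c_in, c_out), dtype))
        self.b = Parameter(np.zeros(c_out, dtype=dtype))
        self._x = None

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        x = self._x
        self.W.grad += np.tensordot(x, grad, axes=([0, 1], [0, 1]))
        self.b.grad += grad.sum(axis=(0, 1))
        return grad @ self.W.value.T


class Conv1d(Layer):
    """Temporal 1-D convolution with 'same' zero padding, stride 1.

    ``y[b, t, d] = sum_k sum_c W[k, c, d] * x[b, t + k - pad, c] + b[d]``
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 dtype=np.float32):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same-length padding")
        fan_in = c_in * kernel
        limit = np.sqrt(6.0 / (fan_in + c_out))
        self.W = Parameter(rng.uniform(-limit, limit, size=(kernel, c_in, c_out)).astype(dtype))
        self.b = Parameter(np.zeros(c_out, dtype=dtype))
        self.kernel = kernel
        self.pad = kernel // 2
        self._cols = None

    def parameters(self):
        return [self.W, self.b]

    def _im2col(self, x):
        # (B, T + 2p, C) -> sliding view (B, T, K, C)
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0)))
        return np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=1).transpose(0, 1, 3, 2)

    def forward(self, x, train=False):
        cols = self._im2col(x)
        self._cols = cols
        self._in_shape = x.shape
        return np.einsum("btkc,kcd->btd", cols, self.W.value, optimize=True) + self.b.value

    def backward(self, grad):
        self.W.grad += np.einsum("btkc,btd->kcd", self._cols, grad, optimize=True)
        self.b.grad += grad.sum(axis=(0, 1))
        # full correlation of grad with the flipped kernel recovers dL/dx
        B, T, _ = self._in_shape
        gp = np.pad(grad, ((0, 0), (self.pad, self.pad), (0, 0)))
        gcols = np.lib.stride_tricks.sliding_window_view(gp, self.kernel, axis=1).transpose(0, 1, 3, 2)
        W_flip = self.W.value[::-1]  # (K, Cin, Cout)
        return np.einsum("btkd,kcd->btc", gcols, W_flip, optimize=True)


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class BatchNorm1d(Layer):
    """Per-channel normalization over the (batch, time) axes.

    Evaluation mode uses running statistics frozen during training, so
    inference is a deterministic per-sample map.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(x.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(x.dtype)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv, train, x.shape[0] * x.shape[1])
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad):
        xhat, inv, train, n = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 1))
        self.beta.grad += grad.sum(axis=(0, 1))
        g = grad * self.gamma.value
        if not train:
            return g * inv
        # standard batch-norm gradient with batch statistics
        return (inv / n) * (n * g - g.sum(axis=(0, 1))
                            - xhat * (g * xhat).sum(axis=(0, 1)))


class LayerNorm(Layer):
    """Normalization over the channel axis of each (batch, time) position."""

    def __init__(self, channels: int, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Parameter(np.ones(channels, dtype=dtype))
        self.beta = Parameter(np.zeros(channels, dtype=dtype))
        self.eps = eps

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        self._cache = (xhat, inv)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad):
        xhat, inv = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 1))
        self.beta.grad += grad.sum(axis=(0, 1))
        g = grad * self.gamma.value
        n = xhat.shape[-1]
        return (inv / n) * (n * g - g.sum(axis=-1, keepdims=True)
                            - xhat * (g * xhat).sum(axis=-1, keepdims=True))


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def scaled_dot_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray) -> np.ndarray:
    """softmax(Q K^T / sqrt(d_k)) V over the last two axes."""
    d_k = Q.shape[-1]
    A = softmax(Q @ np.swapaxes(K, -1, -2) * (1.0 / float(np.sqrt(d_k))), axis=-1)
    return A @ V


class MultiHeadAttention(Layer):
    """Multi-head self-attention with residual connection and layer norm.

    ``x -> LayerNorm(x + Dropout(W_o concat_h(softmax(Q_h K_h^T / sqrt(d_k)) V_h)))``
    """

    def __init__(self, d_model: int, n_heads: int, dropout: float,
                 rng: np.random.Generator, dtype=np.float32):
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.h = n_heads
        self.d_k = d_model // n_heads
        self.Wq = Dense(d_model, d_model, rng, dtype)
        self.Wk = Dense(d_model, d_model, rng, dtype)
        self.Wv = Dense(d_model, d_model, rng, dtype)
        self.Wo = Dense(d_model, d_model, rng, dtype)
        self.drop = Dropout(dropout, rng)
        self.ln = LayerNorm(d_model, dtype=dtype)

    def parameters(self):
        return (self.Wq.parameters() + self.Wk.parameters() + self.Wv.parameters()
                + self.Wo.parameters() + self.ln.parameters())

    def _split(self, x):
        B, T, _ = x.shape
        return x.reshape(B, T, self.h, self.d_k).transpose(0, 2, 1, 3)  # (B, h, T, dk)

    def _merge(self, x):
        B, h, T, dk = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, T, h * dk)

    def forward(self, x, train=False):
        Q = self._split(self.Wq.forward(x, train))
        K = self._split(self.Wk.forward(x, train))
        V = self._split(self.Wv.forward(x, train))
        scale = 1.0 / float(np.sqrt(self.d_k))
        A = softmax(np.einsum("bhtd,bhsd->bhts", Q, K, optimize=True) * scale, axis=-1)
        ctx = np.einsum("bhts,bhsd->bhtd", A, V, optimize=True)
        out = self.Wo.forward(self._merge(ctx), train)
        out = self.drop.forward(out, train)
        self._cache = (Q, K, V, A, scale)
        return self.ln.forward(x + out, train)

    def attention_weights(self, x) -> np.ndarray:
        """Evaluation-mode attention matrices ``(B, h, T, T)`` for inspection."""
        Q = self._split(self.Wq.forward(x))
        K = self._split(self.Wk.forward(x))
        return softmax(np.einsum("bhtd,bhsd->bhts", Q, K, optimize=True)
                       * (1.0 / float(np.sqrt(self.d_k))))

    def backward(self, grad):
        Q, K, V, A, scale = self._cache
        g = self.ln.backward(grad)
        g_out = self.drop.backward(g)
        g_ctx = self._split(self.Wo.backward(g_out))
        gA = np.einsum("bhtd,bhsd->bhts", g_ctx, V, optimize=True)
        gV = np.einsum("bhts,bhtd->bhsd", A, g_ctx, optimize=True)
        # softmax backward, rows of A
        gS = A * (gA - (gA * A).sum(axis=-1, keepdims=True))
        gQ = np.einsum("bhts,bhsd->bhtd", gS, K, optimize=True) * scale
        gK = np.einsum("bhts,bhtd->bhsd", gS, Q, optimize=True) * scale
        gx = (self.Wq.backward(self._merge(gQ)) + self.Wk.backward(self._merge(gK))
              + self.Wv.backward(self._merge(gV)))
        return gx + g  # residual branch


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


class LSTM(Layer):
    """Single-direction LSTM over (B, T, Cin) -> (B, T, H).

    Gate order in the packed weight matrix is [input, forget, cell, output]:
    ``[i, f, g, o] = W [x_t, h_{t-1}] + b`` with sigmoid gates, tanh cell
    candidate, ``c_t = f c_{t-1} + i g`` and ``h_t = o tanh(c_t)``.
    """

    def __init__(self, c_in: int, hidden: int, rng: np.random.Generator,
                 reverse: bool = False, dtype=np.float32):
        self.H = hidden
        self.reverse = reverse
        self.W = Parameter(_glorot(rng, (c_in + hidden, 4 * hidden), dtype))
        b = np.zeros(4 * hidden, dtype=dtype)
        b[hidden:2 * hidden] = 1.0  # forget-gate bias init
        self.b = Parameter(b)

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        if self.reverse:
            x = x[:, ::-1]
        B, T, _ = x.shape
        H = self.H
        dtype = x.dtype
        h = np.zeros((B, H), dtype=dtype)
        c = np.zeros((B, H), dtype=dtype)
        out = np.empty((B, T, H), dtype=dtype)
        cache = []
        W, bias = self.W.value, self.b.value
        for t in range(T):
            z = np.concatenate([x[:, t], h], axis=1) @ W + bias
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            out[:, t] = h
            cache.append((x[:, t], h_prev, c_prev, i, f, g, o, tc))
        self._cache = cache
        if self.reverse:
            return out[:, ::-1]
        return out

    def backward(self, grad):
        if self.reverse:
            grad = grad[:, ::-1]
        cache = self._cache
        T = len(cache)
        B = grad.shape[0]
        H = self.H
        c_in = self.W.shape[0] - H
        gx = np.empty((B, T, c_in), dtype=grad.dtype)
        dh_next = np.zeros((B, H), dtype=grad.dtype)
        dc_next = np.zeros((B, H), dtype=grad.dtype)
        gW = np.zeros_like(self.W.value)
        gb = np.zeros_like(self.b.value)
        Wx = self.W.value[:c_in]
        Wh = self.W.value[c_in:]
        for t in range(T - 1, -1, -1):
            x_t, h_prev, c_prev, i, f, g, o, tc = cache[t]
            dh = grad[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc ** 2) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            inp = np.concatenate([x_t, h_prev], axis=1)
            gW += inp.T @ dz
            gb += dz.sum(axis=0)
            gx[:, t] = dz @ Wx.T
            dh_next = dz @ Wh.T
            dc_next = dc * f
        self.W.grad += gW
        self.b.grad += gb
        if self.reverse:
            return gx[:, ::-1]
        return gx


class BiLSTM(Layer):
    """Bidirectional LSTM: per-timestep concatenation of both directions."""

    def __init__(self, c_in: int, hidden: int, rng: np.random.Generator, dtype=np.float32):
        self.fw = LSTM(c_in, hidden, rng, reverse=False, dtype=dtype)
        self.bw = LSTM(c_in, hidden, rng, reverse=True, dtype=dtype)
        self.H = hidden

    def parameters(self):
        return self.fw.parameters() + self.bw.parameters()

    def forward(self, x, train=False):
        return np.concatenate([self.fw.forward(x, train), self.bw.forward(x, train)], axis=-1)

    def backward(self, grad):
        return self.fw.backward(grad[..., :self.H]) + self.bw.backward(grad[..., self.H:])
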