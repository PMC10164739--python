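"""Neural-network building blocks with explicit forward/backward passes.

Each layer caches what its backward pass needs during forward and accumulates
parameter gradients into ``Param.grad``. Shapes follow the (batch, time,
feature) convention throughout. All layers support float32 (training default)
and float64 (used by the numerical gradient checks in the test suite).
"""

from __future__ import annotations

import numpy as np

NEG_INF = -1e9  # additive mask value; large enough to zero softmax weight


class Param:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)

    def zero_grad(self):
        self.grad[...] = 0.0


class Layer:
    def params(self) -> list[Param]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Param):
                out.append(v)
            elif isinstance(v, Layer):
                out.extend(v.params())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Layer):
                        out.extend(item.params())
        return out


class Dense(Layer):
    """Affine map over the last axis: y = x W + b."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, dtype):
        scale = np.sqrt(2.0 / (d_in + d_out))
        self.W = Param(rng.normal(0.0, scale, size=(d_in, d_out)).astype(dtype))
        self.b = Param(np.zeros(d_out, dtype=dtype))
        self._x = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, d: np.ndarray) -> np.ndarray:
        x = self._x
        self.W.grad += x.reshape(-1, x.shape[-1]).T @ d.reshape(-1, d.shape[-1])
        self.b.grad += d.reshape(-1, d.shape[-1]).sum(axis=0)
        return d @ self.W.value.T


class Embedding(Layer):
    def __init__(self, n_tokens: int, d_model: int, rng: np.random.Generator, dtype):
        self.table = Param(rng.normal(0.0, 0.02, size=(n_tokens, d_model)).astype(dtype))
        self._ids = None

    def forward(self, ids: np.ndarray) -> np.ndarray:
        self._ids = ids
        return self.table.value[ids]

    def backward(self, d: np.ndarray) -> None:
        np.add.at(self.table.grad, self._ids.reshape(-1),
                  d.reshape(-1, d.shape[-1]))


class LayerNorm(Layer):
    def __init__(self, d: int, dtype, eps: float = 1e-5):
        self.gamma = Param(np.ones(d, dtype=dtype))
        self.beta = Param(np.zeros(d, dtype=dtype))
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat, inv)
        return xhat * self.gamma.value + self.beta.value

    def backward(self, d: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self.gamma.grad += (d * xhat).reshape(-1, d.shape[-1]).sum(axis=0)
        self.beta.grad += d.reshape(-1, d.shape[-1]).sum(axis=0)
        dxhat = d * self.gamma.value
        n = d.shape[-1]
        return inv / n * (
            n * dxhat
            - dxhat.sum(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True)
        )


class Dropout(Layer):
    """Inverted dropout; identity when rate is 0 or in eval mode."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng
        self._mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate <= 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, d: np.ndarray) -> np.ndarray:
        return d if self._mask is None else d * self._mask


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


class MultiHeadAttention(Layer):
    """Scaled dot-product attention with h heads.

    ``forward(q_in, kv_in, mask)`` attends from q_in to kv_in; self-attention
    passes the same tensor twice. ``mask`` broadcasts against the score tensor
    of shape (batch, heads, len_q, len_k); True marks *allowed* positions.
    """

    def __init__(self, d_model: int, n_heads: int, rng, dtype, dropout: float = 0.0):
        if d_model % n_heads:
            raise ValueError(f"d_model {d_model} not divisible by n_heads {n_heads}")
        self.h = n_heads
        self.dk = d_model // n_heads
        self.wq = Dense(d_model, d_model, rng, dtype)
        self.wk = Dense(d_model, d_model, rng, dtype)
        self.wv = Dense(d_model, d_model, rng, dtype)
        self.wo = Dense(d_model, d_model, rng, dtype)
        self.drop = Dropout(dropout, rng)
        self._cache = None

    def _split(self, x: np.ndarray) -> np.ndarray:
        b, t, _ = x.shape
        return x.reshape(b, t, self.h, self.dk).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        b, h, t, dk = x.shape
        return x.transpose(0, 2, 1, 3).reshape(b, t, h * dk)

    def forward(self, q_in, kv_in, mask, train: bool) -> np.ndarray:
        q = self._split(self.wq.forward(q_in))
        k = self._split(self.wk.forward(kv_in))
        v = self._split(self.wv.forward(kv_in))
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(self.dk)
        if mask is not None:
            scores = np.where(mask, scores, NEG_INF)
        attn = softmax(scores)
        attn_d = self.drop.forward(attn, train)
        ctx = attn_d @ v
        self._cache = (q, k, v, attn, attn_d)
        return self.wo.forward(self._merge(ctx))

    def backward(self, d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Returns (d_q_in, d_kv_in)."""
        q, k, v, attn, attn_d = self._cache
        d_ctx = self._split(self.wo.backward(d))
        d_attn_d = d_ctx @ v.transpose(0, 1, 3, 2)
        dv = attn_d.transpose(0, 1, 3, 2) @ d_ctx
        d_attn = self.drop.backward(d_attn_d)
        # softmax backward per row
        d_scores = attn * (d_attn - (d_attn * attn).sum(axis=-1, keepdims=True))
        d_scores /= np.sqrt(self.dk)
        dq = d_scores @ k
        dk_ = d_scores.transpose(0, 1, 3, 2) @ q
        d_q_in = self.wq.backward(self._merge(dq))
        d_kv = self.wk.backward(self._merge(dk_)) + self.wv.backward(self._merge(dv))
        return d_q_in, d_kv


class FeedForward(Layer):
    """Position-wise two-layer network with ReLU."""

    def __init__(self, d_model: int, d_ff: int, rng, dtype, dropout: float = 0.0):
        self.lin1 = Dense(d_model, d_ff, rng, dtype)
        self.lin2 = Dense(d_ff, d_model, rng, dtype)
        self.drop = Dropout(dropout, rng)
        self._relu_mask = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        h = self.lin1.forward(x)
        self._relu_mask = h > 0
        h = h * self._relu_mask
        h = self.drop.forward(h, train)
        return self.lin2.forward(h)

    def backward(self, d: np.ndarray) -> np.ndarray:
        dh = self.lin2.backward(d)
        dh = self.drop.backward(dh)
        dh = dh * self._relu_mask
        return self.lin1.backward(dh)


def sinusoidal_encoding(max_len: int, d_model: int, dtype) -> np.ndarray:
    pos = np.arange(max_len)[:, None]
    i = np.arange(d_model // 2)[None, :]
    angles = pos / np.power(10000.0, 2 * i / d_model)
    pe = np.zeros((max_len, d_model))
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles)
    return pe.astype(dtype)


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params: list[Param], lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad ** 2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()
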