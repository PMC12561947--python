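"""Multi-head self-attention encoder blocks (post-norm ordering)."""

from __future__ import annotations

import numpy as np

from .core import Module
from .layers import LayerNorm, Linear, ReLU


def _softmax_lastaxis(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class MultiHeadAttention(Module):
    """Scaled dot-product attention over the time axis, ``heads`` parallel subspaces."""

    def __init__(self, dim, num_heads, rng, dtype=np.float32):
        super().__init__()
        if dim % num_heads:
            raise ValueError(f"dim {dim} not divisible by num_heads {num_heads}")
        self.dim = dim
        self.num_heads = num_heads
        self.head_dim = dim // num_heads
        self.wq = Linear(dim, dim, rng, dtype=dtype)
        self.wk = Linear(dim, dim, rng, dtype=dtype)
        self.wv = Linear(dim, dim, rng, dtype=dtype)
        self.wo = Linear(dim, dim, rng, dtype=dtype)

    def _split(self, x):
        B, T, _ = x.shape
        return x.reshape(B, T, self.num_heads, self.head_dim).transpose(0, 2, 1, 3)

    def _merge(self, x):
        B, h, T, dh = x.shape
        return np.ascontiguousarray(x.transpose(0, 2, 1, 3)).reshape(B, T, h * dh)

    def forward(self, x):
        q = self._split(self.wq.forward(x))
        k = self._split(self.wk.forward(x))
        v = self._split(self.wv.forward(x))
        scale = 1.0 / np.sqrt(self.head_dim)
        scores = (q @ k.transpose(0, 1, 3, 2)) * scale
        att = _softmax_lastaxis(scores)
        ctx = att @ v
        self._cache = (q, k, v, att, scale)
        return self.wo.forward(self._merge(ctx))

    def backward(self, grad):
        q, k, v, att, scale = self._cache
        dctx = self._split(self.wo.backward(grad))
        datt = dctx @ v.transpose(0, 1, 3, 2)
        dv = att.transpose(0, 1, 3, 2) @ dctx
        dscores = att * (datt - (datt * att).sum(axis=-1, keepdims=True))
        dscores *= scale
        dq = dscores @ k
        dk = dscores.transpose(0, 1, 3, 2) @ q
        dx = self.wq.backward(self._merge(dq))
        dx = dx + self.wk.backward(self._merge(dk))
        dx = dx + self.wv.backward(self._merge(dv))
        return dx


class FeedForward(Module):
    """Position-wise two-layer MLP with ReLU."""

    def __init__(self, dim, hidden_dim, rng, dtype=np.float32):
        super().__init__()
        self.fc1 = Linear(dim, hidden_dim, rng, dtype=dtype)
        self.act = ReLU()
        self.fc2 = Linear(hidden_dim, dim, rng, dtype=dtype)

    def forward(self, x):
        return self.fc2.forward(self.act.forward(self.fc1.forward(x)))

    def backward(self, grad):
        return self.fc1.backward(self.act.backward(self.fc2.backward(grad)))


class TransformerEncoderLayer(Module):
    """attention -> add&norm -> feed-forward -> add&norm."""

    def __init__(self, dim, num_heads, ffn_hidden_dim, rng, dtype=np.float32):
        super().__init__()
        self.attn = MultiHeadAttention(dim, num_heads, rng, dtype=dtype)
        self.norm1 = LayerNorm(dim, dtype=dtype)
        self.ffn = FeedForward(dim, ffn_hidden_dim, rng, dtype=dtype)
        self.norm2 = LayerNorm(dim, dtype=dtype)

    def forward(self, x):
        a = self.norm1.forward(x + self.attn.forward(x))
        return self.norm2.forward(a + self.ffn.forward(a))

    def backward(self, grad):
        g = self.norm2.backward(grad)
        ga = g + self.ffn.backward(g)
        g1 = self.norm1.backward(ga)
        return g1 + self.attn.backward(g1)


class SinusoidalPositionalEncoding(Module):
    """Adds the fixed sin/cos position table; parameter-free."""

    def __init__(self, dim, max_len=512):
        super().__init__()
        pos = np.arange(max_len)[:, None]
        i = np.arange(dim)[None, :]
        angle = pos / np.power(10000.0, (2 * (i // 2)) / dim)
        table = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
        self.table = table
        self.dim = dim

    def forward(self, x):
        T = x.shape[-2]
        return x + self.table[:T].astype(x.dtype)

    def backward(self, grad):
        return grad
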