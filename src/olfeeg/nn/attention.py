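"""Multi-head self-attention and pre-norm transformer encoder blocks."""

from __future__ import annotations

import numpy as np

from .layers import Dense, Dropout, GELU, Layer, LayerNorm, softmax

__all__ = ["MultiHeadSelfAttention", "TransformerEncoderLayer"]


class MultiHeadSelfAttention(Layer):
    """Standard scaled dot-product self-attention over (B, S, D) tokens."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        if dim % n_heads:
            raise ValueError(f"embed dim {dim} not divisible by {n_heads} heads")
        self.dim, self.n_heads, self.dh = dim, n_heads, dim // n_heads
        self.q = Dense(dim, dim, rng, dtype)
        self.k = Dense(dim, dim, rng, dtype)
        self.v = Dense(dim, dim, rng, dtype)
        self.out = Dense(dim, dim, rng, dtype)
        self.sub = [self.q, self.k, self.v, self.out]

    def _split(self, x: np.ndarray) -> np.ndarray:
        b, s, _ = x.shape
        return x.reshape(b, s, self.n_heads, self.dh).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        b, h, s, dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(b, s, h * dh)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        q = self._split(self.q.forward(x, training))
        k = self._split(self.k.forward(x, training))
        v = self._split(self.v.forward(x, training))
        scores = q @ k.transpose(0, 1, 3, 2) / np.sqrt(self.dh)
        attn = softmax(scores)
        ctx = attn @ v
        self._q, self._k, self._v, self._attn = q, k, v, attn
        return self.out.forward(self._merge(ctx), training)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g_ctx = self._split(self.out.backward(gy))
        attn, q, k, v = self._attn, self._q, self._k, self._v
        g_attn = g_ctx @ v.transpose(0, 1, 3, 2)
        g_v = attn.transpose(0, 1, 3, 2) @ g_ctx
        g_scores = attn * (g_attn - (g_attn * attn).sum(axis=-1, keepdims=True))
        g_scores /= np.sqrt(self.dh)
        g_q = g_scores @ k
        g_k = g_scores.transpose(0, 1, 3, 2) @ q
        gx = self.q.backward(self._merge(g_q))
        gx = gx + self.k.backward(self._merge(g_k))
        gx = gx + self.v.backward(self._merge(g_v))
        self._q = self._k = self._v = self._attn = None
        return gx


class TransformerEncoderLayer(Layer):
    """Pre-norm block: x + MHA(LN(x)); x + FF(LN(x)) with a 4x GELU MLP."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 ff_mult: int = 4, dropout: float = 0.0,
                 dropout_rng: np.random.Generator | None = None,
                 dtype=np.float32) -> None:
        super().__init__()
        self.ln1 = LayerNorm(dim, dtype=dtype)
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng, dtype)
        self.ln2 = LayerNorm(dim, dtype=dtype)
        self.ff1 = Dense(dim, ff_mult * dim, rng, dtype)
        self.act = GELU()
        self.ff2 = Dense(ff_mult * dim, dim, rng, dtype)
        self.drop1 = Dropout(dropout, dropout_rng or rng)
        self.drop2 = Dropout(dropout, dropout_rng or rng)
        self.sub = [self.ln1, self.attn, self.ln2, self.ff1, self.act, self.ff2,
                    self.drop1, self.drop2]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = self.drop1.forward(self.attn.forward(self.ln1.forward(x, training), training),
                               training)
        x = x + h
        h = self.ff1.forward(self.ln2.forward(x, training), training)
        h = self.drop2.forward(self.ff2.forward(self.act.forward(h, training), training),
                               training)
        return x + h

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.drop2.backward(gy)
        g = self.ff1.backward(self.act.backward(self.ff2.backward(g)))
        g = gy + self.ln2.backward(g)
        g2 = self.attn.backward(self.drop1.backward(g))
        return g + self.ln1.backward(g2)
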