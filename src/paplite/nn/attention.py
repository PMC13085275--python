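"""Multi-head scaled dot-product self-attention on CNN feature maps.

A spatial activation block ``F`` of shape ``H x W x C`` is reshaped into a
sequence ``X`` of ``N = H*W`` rows (one per spatial location, channels
preserved), projected to queries/keys/values, attended per head, and
projected back to ``C`` channels:

    Q = X W_Q,  K = X W_K,  V = X W_V          (N x d,  d = h * d_k)
    head_i     = softmax(Q_i K_i^T / sqrt(d_k)) V_i
    SA(X)      = concat(head_1 .. head_h) W_O   (N x C)

No positional encoding is used, so the map is permutation-equivariant in
the sequence dimension.  These functions are single-sample and written to
be directly checkable against hand-evaluated small cases; the batched
training layer in :mod:`paplite.nn.layers` reuses the same conventions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class AttentionConfig:
    """Head/embedding bookkeeping: ``embed_dim = n_heads * head_dim``."""

    n_heads: int = 8
    channels: int = 1280
    embed_dim: int | None = None  # defaults to channels (d = C)
    head_dim: int = field(init=False)

    def __post_init__(self) -> None:
        if self.embed_dim is None:
            self.embed_dim = self.channels
        if self.channels <= 0 or self.n_heads <= 0:
            raise ValueError("channels and n_heads must be positive")
        if self.embed_dim % self.n_heads != 0:
            raise ValueError(
                f"embed_dim {self.embed_dim} not divisible by "
                f"n_heads {self.n_heads}"
            )
        self.head_dim = self.embed_dim // self.n_heads
        if self.head_dim < 1:
            raise ValueError("head_dim must be >= 1")


@dataclass
class AttentionWeights:
    """Projection matrices W_Q, W_K, W_V (C x d) and W_O (d x C)."""

    w_q: np.ndarray
    w_k: np.ndarray
    w_v: np.ndarray
    w_o: np.ndarray

    def __post_init__(self) -> None:
        c, d = self.w_q.shape
        for name in ("w_k", "w_v"):
            if getattr(self, name).shape != (c, d):
                raise ValueError(f"{name} shape mismatch with w_q")
        if self.w_o.shape != (d, c):
            raise ValueError("w_o must be (d, C)")

    @classmethod
    def init(cls, cfg: AttentionConfig, rng: np.random.Generator
             ) -> "AttentionWeights":
        c, d = cfg.channels, cfg.embed_dim
        s = 1.0 / np.sqrt(c)
        return cls(
            w_q=rng.normal(0, s, (c, d)), w_k=rng.normal(0, s, (c, d)),
            w_v=rng.normal(0, s, (c, d)), w_o=rng.normal(0, 1 / np.sqrt(d),
                                                         (d, c)),
        )


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax; rows sum to 1 along ``axis``."""
    z = x - np.max(x, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def flatten_map(f: np.ndarray) -> np.ndarray:
    """H x W x C activation block -> N x C sequence, row r = i*W + j."""
    if f.ndim != 3:
        raise ValueError("expected an H x W x C array")
    h, w, c = f.shape
    return f.reshape(h * w, c)


def unflatten_map(x: np.ndarray, h: int, w: int) -> np.ndarray:
    """Inverse of :func:`flatten_map`; exact round trip."""
    n, c = x.shape
    if n != h * w:
        raise ValueError(f"sequence length {n} != {h}*{w}")
    return x.reshape(h, w, c)


def project_qkv(x: np.ndarray, weights: AttentionWeights):
    """Linear projections Q = X W_Q, K = X W_K, V = X W_V."""
    if x.shape[1] != weights.w_q.shape[0]:
        raise ValueError(
            f"sequence has {x.shape[1]} channels but projections expect "
            f"{weights.w_q.shape[0]}"
        )
    return x @ weights.w_q, x @ weights.w_k, x @ weights.w_v


def scaled_dot_attention(q: np.ndarray, k: np.ndarray, v: np.ndarray,
                         return_weights: bool = False):
    """softmax(Q K^T / sqrt(d_k)) V for one head.

    Attention weights are row-stochastic; with K = 0 they are uniform and
    the output is the column mean of V.
    """
    if q.shape != k.shape or q.shape[0] != v.shape[0]:
        raise ValueError("Q, K, V must share N and Q/K must share d_k")
    d_k = q.shape[1]
    if d_k == 0:
        raise ValueError("d_k must be >= 1")
    a = softmax(q @ k.T / np.sqrt(d_k), axis=-1)
    out = a @ v
    return (out, a) if return_weights else out


def multi_head_attention(x: np.ndarray, weights: AttentionWeights,
                         n_heads: int) -> np.ndarray:
    """SA(X): per-head attention on contiguous d_k column slices, concat,
    then output projection.  Input and output are both N x C."""
    q, k, v = project_qkv(x, weights)
    d = q.shape[1]
    if d % n_heads != 0:
        raise ValueError(f"embed dim {d} not divisible by {n_heads} heads")
    d_k = d // n_heads
    heads = [
        scaled_dot_attention(
            q[:, i * d_k:(i + 1) * d_k],
            k[:, i * d_k:(i + 1) * d_k],
            v[:, i * d_k:(i + 1) * d_k],
        )
        for i in range(n_heads)
    ]
    return np.concatenate(heads, axis=1) @ weights.w_o
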