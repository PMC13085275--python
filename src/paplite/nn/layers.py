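"""Minimal NumPy neural-network layers with hand-written backprop.

Only what the attention CNNs need: strided 2-D convolution (im2col), ReLU,
multi-head self-attention over the flattened feature map, global average
pooling and a dense head.  Data layout is NHWC throughout, matching the
``H x W x C`` feature-map convention used elsewhere in the package.

Each layer caches its forward activations and exposes ``backward`` for the
upstream gradient; parameters and their gradients live in ``params`` /
``grads`` dicts keyed by name so the SGDM optimiser can walk them.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .attention import AttentionConfig, softmax

EPS = 1e-12  # documented numeric floor for log/softmax


class Layer:
    """Base class: stateless layers leave params empty."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution with stride and zero padding, He-initialised."""

    def __init__(self, c_in: int, c_out: int, ksize: int = 3, stride: int = 1,
                 pad: int = 1, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = ksize * ksize * c_in
        self.ksize, self.stride, self.pad = ksize, stride, pad
        self.c_in, self.c_out = c_in, c_out
        self.params = {
            "w": rng.normal(0, np.sqrt(2.0 / fan_in), (fan_in, c_out)),
            "b": np.zeros(c_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, h, w, c = x.shape
        k, s, p = self.ksize, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = sliding_window_view(xp, (k, k), axis=(1, 2))  # B,Ho',Wo',C,k,k
        win = win[:, ::s, ::s]
        self._out_hw = win.shape[1:3]
        ho, wo = self._out_hw
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(b * ho * wo, k * k * c)
        self._cols = cols
        self._in_shape = x.shape
        y = cols @ self.params["w"] + self.params["b"]
        return y.reshape(b, ho, wo, self.c_out)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, h, w, c = self._in_shape
        k, s, p = self.ksize, self.stride, self.pad
        ho, wo = self._out_hw
        d2 = dout.reshape(b * ho * wo, self.c_out)
        self.grads["w"][...] = self._cols.T @ d2
        self.grads["b"][...] = d2.sum(axis=0)
        dcols = (d2 @ self.params["w"].T).reshape(b, ho, wo, k, k, c)
        dxp = np.zeros((b, h + 2 * p, w + 2 * p, c))
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + ho * s:s, j:j + wo * s:s, :] += dcols[:, :, :, i, j, :]
        return dxp[:, p:p + h, p:p + w, :]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class GlobalAvgPool(Layer):
    """(B, H, W, C) -> (B, C); the network's final pooling layer."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, h, w, c = self._in_shape
        return np.broadcast_to(dout[:, None, None, :], self._in_shape) / (h * w)


class Dense(Layer):
    def __init__(self, c_in: int, c_out: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params = {
            "w": rng.normal(0, np.sqrt(2.0 / c_in), (c_in, c_out)),
            "b": np.zeros(c_out),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads["w"][...] = self._x.T @ dout
        self.grads["b"][...] = dout.sum(axis=0)
        return dout @ self.params["w"].T


class MultiHeadSelfAttention(Layer):
    """Batched multi-head self-attention over the flattened feature map.

    Input (B, H, W, C) is flattened to (B, N, C) with N = H*W, attended with
    the conventions of :mod:`paplite.nn.attention` (d = h * d_k, contiguous
    head slices, output projection W_O), and reshaped back to (B, H, W, C).
    """

    def __init__(self, cfg: AttentionConfig,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        c, d = cfg.channels, cfg.embed_dim
        s = 1.0 / np.sqrt(c)
        self.params = {
            "w_q": rng.normal(0, s, (c, d)), "w_k": rng.normal(0, s, (c, d)),
            "w_v": rng.normal(0, s, (c, d)),
            "w_o": rng.normal(0, 1.0 / np.sqrt(d), (d, c)),
        }
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}

    def _split(self, m: np.ndarray) -> np.ndarray:
        """(B, N, d) -> (B, h, N, d_k), contiguous column slices per head."""
        b, n, d = m.shape
        h, dk = self.cfg.n_heads, self.cfg.head_dim
        return m.reshape(b, n, h, dk).transpose(0, 2, 1, 3)

    def _merge(self, m: np.ndarray) -> np.ndarray:
        b, h, n, dk = m.shape
        return m.transpose(0, 2, 1, 3).reshape(b, n, h * dk)

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, hh, ww, c = x.shape
        n = hh * ww
        xs = x.reshape(b, n, c)
        self._xs, self._hw = xs, (hh, ww)
        p = self.params
        q, k, v = xs @ p["w_q"], xs @ p["w_k"], xs @ p["w_v"]
        qh, kh, vh = self._split(q), self._split(k), self._split(v)
        scale = 1.0 / np.sqrt(self.cfg.head_dim)
        a = softmax(np.einsum("bhnd,bhmd->bhnm", qh, kh) * scale, axis=-1)
        heads = np.einsum("bhnm,bhmd->bhnd", a, vh)
        hcat = self._merge(heads)
        self._cache = (qh, kh, vh, a, hcat)
        y = hcat @ p["w_o"]
        return y.reshape(b, hh, ww, c)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, hh, ww, c = dout.shape
        n = hh * ww
        dy = dout.reshape(b, n, c)
        p, (qh, kh, vh, a, hcat) = self.params, self._cache
        xs = self._xs
        self.grads["w_o"][...] = np.einsum("bnd,bnc->dc", hcat, dy)
        dhcat = dy @ p["w_o"].T
        dheads = self._split(dhcat)
        da = np.einsum("bhnd,bhmd->bhnm", dheads, vh)
        dvh = np.einsum("bhnm,bhnd->bhmd", a, dheads)
        # softmax backward, row-wise over the key axis
        ds = a * (da - np.sum(da * a, axis=-1, keepdims=True))
        scale = 1.0 / np.sqrt(self.cfg.head_dim)
        dqh = np.einsum("bhnm,bhmd->bhnd", ds, kh) * scale
        dkh = np.einsum("bhnm,bhnd->bhmd", ds, qh) * scale
        dq, dk, dv = self._merge(dqh), self._merge(dkh), self._merge(dvh)
        self.grads["w_q"][...] = np.einsum("bnc,bnd->cd", xs, dq)
        self.grads["w_k"][...] = np.einsum("bnc,bnd->cd", xs, dk)
        self.grads["w_v"][...] = np.einsum("bnc,bnd->cd", xs, dv)
        dxs = dq @ p["w_q"].T + dk @ p["w_k"].T + dv @ p["w_v"].T
        return dxs.reshape(b, hh, ww, c)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean categorical cross-entropy and its gradient w.r.t. logits."""
    probs = softmax(logits, axis=-1)
    b = logits.shape[0]
    picked = np.clip(probs[np.arange(b), labels], EPS, None)
    loss = -np.mean(np.log(picked))
    dlogits = probs.copy()
    dlogits[np.arange(b), labels] -= 1.0
    return loss, probs, dlogits / b
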