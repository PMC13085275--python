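"""Attention-augmented CNN models.

Wiring (identical for every backbone): the backbone's convolutional stack
runs through its last convolutional stage, the resulting ``H x W x C`` map
is flattened to a length ``N = H*W`` sequence, passed through an 8-head
self-attention block (embed dim equal to the channel count, so the
attention output is again ``N x C``), reshaped back to a spatial map,
globally average-pooled, and classified by a dense softmax head.

Backbones
---------
``toy_cnn``
    A small 3-block CNN (8/16/16 channels) used throughout the test suite.
``resnet18`` / ``mobilenet`` / ``efficientnetb0``
    Compact randomly initialised strided conv stacks whose final channel
    widths match the published architectures (512 for ResNet-18, 1280 for
    MobileNet and EfficientNetB0), so every downstream dimension contract
    holds.  They are random-init stand-ins built in this package, not the
    pretrained ImageNet networks.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .attention import AttentionConfig
from .layers import (Conv2d, Dense, GlobalAvgPool, Layer,
                     MultiHeadSelfAttention, ReLU, softmax_cross_entropy)
from .attention import softmax

# name -> (list of (c_out, ksize, stride) conv blocks, final channel count)
BACKBONE_DEFS: dict[str, tuple[list[tuple[int, int, int]], int]] = {
    "toy_cnn": ([(8, 3, 2), (16, 3, 2), (16, 3, 2)], 16),
    "resnet18": ([(32, 7, 4), (64, 3, 2), (128, 3, 2), (256, 3, 2),
                  (512, 3, 2)], 512),
    "mobilenet": ([(32, 7, 4), (64, 3, 2), (128, 3, 2), (256, 3, 2),
                   (1280, 3, 2)], 1280),
    "efficientnetb0": ([(32, 7, 4), (64, 3, 2), (128, 3, 2), (256, 3, 2),
                        (1280, 3, 2)], 1280),
}

ENDPOINTS = ("last_conv", "attention_seq", "attention_pooled",
             "global_pool", "logits")


class AttentionCNN:
    """Backbone -> flatten -> multi-head attention -> GAP -> FC -> softmax."""

    def __init__(self, backbone: str, n_classes: int, n_heads: int = 8,
                 seed: int = 0, in_channels: int = 3):
        if backbone not in BACKBONE_DEFS:
            raise ValueError(
                f"unknown backbone {backbone!r}; "
                f"choose from {sorted(BACKBONE_DEFS)}"
            )
        defs, channels = BACKBONE_DEFS[backbone]
        if channels % n_heads != 0:
            raise ValueError(
                f"channel count {channels} not divisible by {n_heads} heads"
            )
        self.backbone_name = backbone
        self.n_classes = n_classes
        self.seed = seed
        self.attn_cfg = AttentionConfig(n_heads=n_heads, channels=channels)
        rng = np.random.default_rng(seed)
        self.conv_layers: list[Layer] = []
        c_in = in_channels
        for c_out, k, s in defs:
            self.conv_layers.append(
                Conv2d(c_in, c_out, ksize=k, stride=s, pad=k // 2, rng=rng))
            self.conv_layers.append(ReLU())
            c_in = c_out
        self.attention = MultiHeadSelfAttention(self.attn_cfg, rng=rng)
        self.pool = GlobalAvgPool()
        self.head = Dense(channels, n_classes, rng=rng)
        self._layers: list[Layer] = [*self.conv_layers, self.attention,
                                     self.pool, self.head]

    # ------------------------------------------------------------- forward
    @property
    def channels(self) -> int:
        return self.attn_cfg.channels

    @staticmethod
    def _prepare(images: np.ndarray) -> np.ndarray:
        """uint8 HWC or NHWC images -> zero-centred float batch.

        Pixels are scaled to [0, 1] and shifted by -0.5; centring keeps the
        first conv layer's pre-activations balanced around zero, which the
        small-scale SGDM runs need for usable convergence.
        """
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 3:
            x = x[None]
        if x.max() > 1.5:
            x = x / 255.0
        return x - 0.5

    def forward(self, images: np.ndarray, collect: bool = False):
        """Forward pass to logits; optionally returns endpoint activations.

        Endpoints: ``last_conv`` (B,H,W,C), ``attention_seq`` (B,N,C),
        ``attention_pooled`` (B,C), ``global_pool`` (B,C), ``logits`` (B,K).
        """
        x = self._prepare(images)
        for layer in self.conv_layers:
            x = layer.forward(x)
        last_conv = x
        att = self.attention.forward(x)
        pooled = self.pool.forward(att)
        logits = self.head.forward(pooled)
        if collect:
            b, h, w, c = att.shape
            return logits, {
                "last_conv": last_conv,
                "attention_seq": att.reshape(b, h * w, c),
                "attention_pooled": att.reshape(b, h * w, c).mean(axis=1),
                "global_pool": pooled,
                "logits": logits,
            }
        return logits

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        return softmax(self.forward(images), axis=-1)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return np.argmax(self.forward(images), axis=-1)

    # ------------------------------------------------------------ training
    def train_step_grads(self, images: np.ndarray, labels: np.ndarray):
        """Forward + backward on one mini-batch; fills every layer's grads.

        Returns (mean cross-entropy loss, class probabilities).
        """
        logits = self.forward(images)
        loss, probs, dlogits = softmax_cross_entropy(logits, labels)
        d = self.head.backward(dlogits)
        d = self.pool.backward(d)
        d = self.attention.backward(d)
        for layer in reversed(self.conv_layers):
            d = layer.backward(d)
        return loss, probs

    def parameters(self):
        """Yields (layer, name, param, grad) over all trainables."""
        for layer in self._layers:
            for name, p in layer.params.items():
                yield layer, name, p, layer.grads[name]

    # ---------------------------------------------------------- grad taps
    def input_class_gradient(self, images: np.ndarray, target_class: int,
                             wrt: str = "last_conv"):
        """Gradient of the target-class logit w.r.t. a named endpoint.

        Used by Grad-CAM: returns (activations, gradient) both shaped
        (B, H, W, C) for ``wrt='last_conv'`` or ``'attention_seq'`` (the
        latter reshaped spatially).
        """
        if wrt not in ("last_conv", "attention_seq"):
            raise ValueError(f"gradient tap not supported for {wrt!r}")
        x = self._prepare(images)
        for layer in self.conv_layers:
            x = layer.forward(x)
        last_conv = x
        att = self.attention.forward(x)
        pooled = self.pool.forward(att)
        logits = self.head.forward(pooled)
        dlogits = np.zeros_like(logits)
        dlogits[:, target_class] = 1.0
        d = self.head.backward(dlogits)
        d = self.pool.backward(d)
        if wrt == "attention_seq":
            return att, d, logits
        d = self.attention.backward(d)
        return last_conv, d, logits

    # ------------------------------------------------------------ save/load
    def save(self, path: str | Path) -> None:
        """Single-file .npz checkpoint with an embedded JSON config header."""
        header = json.dumps({
            "backbone": self.backbone_name, "n_classes": self.n_classes,
            "n_heads": self.attn_cfg.n_heads, "seed": self.seed,
        })
        arrays = {"__config__": np.str_(header)}
        for i, layer in enumerate(self._layers):
            for name, p in layer.params.items():
                arrays[f"layer{i}.{name}"] = p
        np.savez_compressed(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "AttentionCNN":
        with np.load(path, allow_pickle=False) as z:
            cfg = json.loads(str(z["__config__"]))
            model = cls(cfg["backbone"], cfg["n_classes"],
                        n_heads=cfg["n_heads"], seed=cfg["seed"])
            for i, layer in enumerate(model._layers):
                for name in layer.params:
                    layer.params[name][...] = z[f"layer{i}.{name}"]
        return model


def build_attention_model(backbone: str, n_classes: int, n_heads: int = 8,
                          seed: int = 0) -> AttentionCNN:
    """Construct an attention-augmented CNN for the named backbone."""
    return AttentionCNN(backbone, n_classes, n_heads=n_heads, seed=seed)
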