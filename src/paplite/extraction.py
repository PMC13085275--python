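"""Dual deep-layer feature extraction.

After training, each attention CNN is used as a fixed feature extractor at
two named endpoints: the final (global average) pooling layer, and the
self-attention layer, whose ``N x C`` output sequence is aggregated to a
single length-``C`` vector by the arithmetic mean over spatial positions —
the same aggregation the model's own downstream pooling applies.  Both
endpoints therefore yield one ``C``-vector per image (512 for the
ResNet-18-width backbone, 1280 for the MobileNet/EfficientNetB0 widths).

Extraction runs the model in evaluation mode only (no dropout/augmentation
anywhere in the forward pass), so repeated extraction is bit-identical.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage.transform import resize

from .features import FeatureMatrix
from .nn.models import AttentionCNN


def _endpoint_features(model: AttentionCNN, images: np.ndarray,
                       endpoint: str, batch_size: int = 32) -> np.ndarray:
    images = np.asarray(images)
    if images.ndim == 3:
        images = images[None]
    out = []
    for start in range(0, len(images), batch_size):
        batch = images[start:start + batch_size]
        _, taps = model.forward(batch, collect=True)
        out.append(taps[endpoint])
    return np.concatenate(out, axis=0)


def _check_images(model: AttentionCNN, images: np.ndarray) -> np.ndarray:
    images = np.asarray(images)
    if images.ndim == 3:
        images = images[None]
    if len(images) == 0:
        raise ValueError("image set is empty")
    return images


def extract_pooling_features(model: AttentionCNN, images: np.ndarray,
                             labels: np.ndarray,
                             batch_size: int = 32) -> FeatureMatrix:
    """One row per image from the final pooling layer; p = backbone channels."""
    images = _check_images(model, images)
    feats = _endpoint_features(model, images, "global_pool", batch_size)
    return FeatureMatrix(
        values=feats, labels=labels, source="pooling",
        network=model.backbone_name,
        feature_names=[f"{model.backbone_name}.pool.{j}"
                       for j in range(feats.shape[1])],
    )


def extract_attention_features(model: AttentionCNN, images: np.ndarray,
                               labels: np.ndarray,
                               batch_size: int = 32) -> FeatureMatrix:
    """One row per image: SA(X) mean-pooled over the N sequence positions."""
    images = _check_images(model, images)
    feats = _endpoint_features(model, images, "attention_pooled", batch_size)
    return FeatureMatrix(
        values=feats, labels=labels, source="attention",
        network=model.backbone_name,
        feature_names=[f"{model.backbone_name}.attn.{j}"
                       for j in range(feats.shape[1])],
    )


def resize_images(images: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Resize a batch to (H, W), warning — extraction expects uniform sizes."""
    if images.shape[1:3] == tuple(size):
        return images
    warnings.warn(f"resizing images from {images.shape[1:3]} to {size}")
    out = np.stack([
        resize(im, size, order=1, preserve_range=True, anti_aliasing=True)
        for im in images
    ])
    return out.astype(images.dtype)
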