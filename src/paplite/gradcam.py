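"""Grad-CAM heatmaps and jet-colormap overlays.

For a target class ``c`` and a spatial endpoint with activations
``A^k`` (channel k), the channel weights are the spatial means of
``d score_c / d A^k``; the raw map is ``ReLU(sum_k w_k A^k)``, bilinearly
upsampled to the image size and divided by its maximum so values lie in
[0, 1] (an identically-zero map stays zero and is flagged).  The class
score is the pre-softmax logit.

The jet colormap is the fixed piecewise-linear map

    r(v) = clip(1.5 - |4v - 3|, 0, 1)
    g(v) = clip(1.5 - |4v - 2|, 0, 1)
    b(v) = clip(1.5 - |4v - 1|, 0, 1)

so v = 0 is blue-dominant, v = 0.5 green, v = 1 red-dominant, and overlays
are bit-reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.transform import resize

from .nn.models import AttentionCNN


@dataclass
class Heatmap:
    """H x W class-activation map in [0, 1] plus provenance."""

    map: np.ndarray
    target_class: int
    target_layer: str
    all_zero: bool = False


def gradcam(model: AttentionCNN, image: np.ndarray, target_class: int,
            target_layer: str = "last_conv") -> Heatmap:
    """Gradient-weighted class activation map for one image."""
    if not 0 <= target_class < model.n_classes:
        raise ValueError(f"target_class {target_class} out of range")
    acts, grads, _logits = model.input_class_gradient(
        image, target_class, wrt=target_layer)
    a, g = acts[0], grads[0]  # (H, W, C)
    weights = g.mean(axis=(0, 1))
    raw = np.maximum(a @ weights, 0.0)
    h, w = np.asarray(image).shape[:2]
    up = resize(raw, (h, w), order=1, preserve_range=True)
    m = up.max()
    if m <= 0:
        return Heatmap(map=np.zeros((h, w)), target_class=target_class,
                       target_layer=target_layer, all_zero=True)
    return Heatmap(map=np.clip(up / m, 0, 1), target_class=target_class,
                   target_layer=target_layer)


def jet(v: np.ndarray) -> np.ndarray:
    """Piecewise-linear jet colormap; input in [0, 1], output (..., 3)."""
    v = np.asarray(v, dtype=np.float64)
    r = np.clip(1.5 - np.abs(4 * v - 3), 0, 1)
    g = np.clip(1.5 - np.abs(4 * v - 2), 0, 1)
    b = np.clip(1.5 - np.abs(4 * v - 1), 0, 1)
    return np.stack([r, g, b], axis=-1)


def overlay_jet(image: np.ndarray, heat: np.ndarray, alpha: float = 0.4
                ) -> np.ndarray:
    """Pixelwise blend ``alpha * jet(map) + (1 - alpha) * image`` (uint8)."""
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    img = np.asarray(image, dtype=np.float64)
    if img.max() > 1.5:
        img = img / 255.0
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if heat.shape != img.shape[:2]:
        raise ValueError("heatmap and image spatial sizes differ")
    blend = alpha * jet(heat) + (1 - alpha) * img
    return np.clip(np.rint(blend * 255), 0, 255).astype(np.uint8)


def explain_batch(model: AttentionCNN, images: np.ndarray,
                  out_dir: str | Path, target_classes=None,
                  target_layer: str = "last_conv", alpha: float = 0.4
                  ) -> pd.DataFrame:
    """Write one (grayscale map, overlay) PNG pair per image + manifest CSV.

    ``target_classes`` defaults to the model's own predictions.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images = np.asarray(images)
    if images.ndim == 3:
        images = images[None]
    if target_classes is None:
        target_classes = model.predict(images)
    rows = []
    for i, (img, cls) in enumerate(zip(images, target_classes)):
        hm = gradcam(model, img, int(cls), target_layer)
        map_name = f"map_{i:04d}.png"
        ovl_name = f"overlay_{i:04d}.png"
        iio.imwrite(out_dir / map_name,
                    np.clip(np.rint(hm.map * 255), 0, 255).astype(np.uint8))
        iio.imwrite(out_dir / ovl_name, overlay_jet(img, hm.map, alpha))
        rows.append({"index": i, "target_class": int(cls),
                     "map": map_name, "overlay": ovl_name,
                     "all_zero": hm.all_zero})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
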