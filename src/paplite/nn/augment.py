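"""On-the-fly geometric augmentation for training mini-batches.

All transforms are purely geometric (scale, shear, translation, rotation,
axis reflection) — no colour jitter — with parameters drawn uniformly from
the configured ranges.  Out-of-frame pixels are filled by reflect padding
to avoid black-corner artefacts that would contaminate downstream
explanation heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import AffineTransform, warp


@dataclass
class AugmentationRanges:
    """Uniform sampling ranges for the geometric augmentation policy.

    Defaults: scale 0.6–2.6, shear ±59°, translation ±46 px (applied in x
    and y, alongside random axis reflection when ``flip`` is on), rotation
    ±90°.
    """

    scale: tuple[float, float] = (0.6, 2.6)
    shear_deg: tuple[float, float] = (-59.0, 59.0)
    reflect_xy: tuple[float, float] = (-46.0, 46.0)
    rotation_deg: tuple[float, float] = (-90.0, 90.0)
    flip: bool = True

    def __post_init__(self) -> None:
        for name in ("scale", "shear_deg", "reflect_xy", "rotation_deg"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range has low > high")

    def is_identity(self) -> bool:
        return (self.scale == (1.0, 1.0) and self.shear_deg == (0.0, 0.0)
                and self.reflect_xy == (0.0, 0.0)
                and self.rotation_deg == (0.0, 0.0) and not self.flip)


def augment_image(img: np.ndarray, ranges: AugmentationRanges,
                  rng: np.random.Generator) -> np.ndarray:
    """Apply one random geometric transform; output size and dtype preserved.

    The affine part is composed about the image centre; reflection flips
    each axis independently with probability 1/2 when enabled.
    """
    if ranges.is_identity():
        return img.copy()
    out = img
    if ranges.flip:
        if rng.random() < 0.5:
            out = out[::-1]
        if rng.random() < 0.5:
            out = out[:, ::-1]
    s = rng.uniform(*ranges.scale)
    shear = np.deg2rad(rng.uniform(*ranges.shear_deg))
    tx = rng.uniform(*ranges.reflect_xy)
    ty = rng.uniform(*ranges.reflect_xy)
    rot = np.deg2rad(rng.uniform(*ranges.rotation_deg))
    h, w = img.shape[:2]
    centre = np.array([w / 2, h / 2])
    tf = (AffineTransform(translation=-centre)
          + AffineTransform(scale=(s, s), rotation=rot, shear=shear)
          + AffineTransform(translation=centre + [tx, ty]))
    warped = warp(out.astype(np.float64), tf.inverse, mode="reflect",
                  order=1, preserve_range=True)
    if np.issubdtype(img.dtype, np.integer):
        return np.clip(np.rint(warped), 0, 255).astype(img.dtype)
    return warped.astype(img.dtype)
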