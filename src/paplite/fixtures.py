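"""Synthetic cytology-like fixtures.

Real Pap-smear collections (single-cell morphology sets with five classes,
liquid-based cytology sets with four) are large external downloads, so every
downstream stage of this package is exercised instead on generated images
that keep the *structure* that matters for testing: one elliptical nucleus
inside an elliptical cytoplasm, per-class morphology (nucleus size,
nucleus-to-cytoplasm area ratio, chromatin texture noise, stain hue), and
exact per-class counts.  A companion generator produces feature matrices
with a known informative-column subset so selection and classification can
be validated against planted ground truth.

All generators are pure functions of their seed: a top-level seed is
spawned into per-sample substreams, so regenerating any single image
reproduces it bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.color import hsv2rgb

from .features import FeatureMatrix

# class counts of the two study dataset shapes, usable as presets
MENDELEY_LBC_COUNTS = [613, 113, 163, 74]
SIPAKMED_COUNTS = [813, 825, 793, 787, 813]


@dataclass
class ClassMorphology:
    """Per-class geometry/appearance parameters, in pixels on a 224 px frame."""

    nucleus_radius_mean: float
    nucleus_radius_sd: float
    nc_area_ratio: float  # nucleus area : cytoplasm area, in (0, 1)
    texture_noise: float  # chromatin noise amplitude in [0, 1] value units
    stain_hue: float  # HSV hue of the cytoplasm stain in [0, 1]

    def __post_init__(self) -> None:
        if self.nucleus_radius_mean <= 0 or self.nucleus_radius_sd < 0:
            raise ValueError("nucleus radius parameters must be positive")
        if not 0 < self.nc_area_ratio < 1:
            raise ValueError("nc_area_ratio must be in (0, 1)")


def default_morphologies(n_classes: int) -> list[ClassMorphology]:
    """Well-separated per-class morphologies (radius and hue both vary)."""
    morphs = []
    for c in range(n_classes):
        frac = c / max(n_classes - 1, 1)
        morphs.append(
            ClassMorphology(
                nucleus_radius_mean=14.0 + 22.0 * frac,
                nucleus_radius_sd=1.5,
                nc_area_ratio=0.08 + 0.35 * frac,
                texture_noise=0.02 + 0.08 * frac,
                stain_hue=(0.55 + 0.35 * frac) % 1.0,
            )
        )
    return morphs


def high_separability_morphologies(n_classes: int) -> list[ClassMorphology]:
    """Strongly separated classes (wide hue and nucleus-size spread).

    Intended for desk-scale end-to-end runs where the point is to verify
    the pipeline recovers an easily separable class structure.
    """
    return [
        ClassMorphology(
            nucleus_radius_mean=8.0 + 7.0 * c,
            nucleus_radius_sd=1.0,
            nc_area_ratio=min(0.08 + 0.18 * c, 0.9),
            texture_noise=0.02,
            stain_hue=(0.05 + 0.2 * c) % 1.0,
        )
        for c in range(n_classes)
    ]


@dataclass
class FixtureSpec:
    """Specification of a synthetic labelled image set."""

    n_classes: int
    per_class_counts: list[int]
    image_size: tuple[int, int] = (224, 224)
    class_morphology: list[ClassMorphology] = field(default_factory=list)
    class_names: list[str] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.per_class_counts) != self.n_classes:
            raise ValueError("per_class_counts length must equal n_classes")
        if any(c <= 0 for c in self.per_class_counts):
            raise ValueError("per_class_counts must all be > 0")
        if self.image_size[0] <= 0 or self.image_size[1] <= 0:
            raise ValueError("image_size must be positive")
        if not self.class_morphology:
            self.class_morphology = default_morphologies(self.n_classes)
        if len(self.class_morphology) != self.n_classes:
            raise ValueError("class_morphology length must equal n_classes")
        if not self.class_names:
            self.class_names = [f"class_{c}" for c in range(self.n_classes)]

    @property
    def n_images(self) -> int:
        return int(sum(self.per_class_counts))


def mendeley_shaped_spec(seed: int = 0, image_size=(224, 224)) -> FixtureSpec:
    """Four-class fixture with the liquid-based-cytology class imbalance."""
    return FixtureSpec(
        n_classes=4,
        per_class_counts=list(MENDELEY_LBC_COUNTS),
        image_size=image_size,
        seed=seed,
    )


def _ellipse_mask(h, w, cy, cx, ry, rx, theta):
    yy, xx = np.mgrid[0:h, 0:w]
    y = yy - cy
    x = xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = x * ct + y * st
    v = -x * st + y * ct
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _sample_geometry(class_id: int, spec: FixtureSpec, rng: np.random.Generator):
    """Draw nucleus/cytoplasm geometry for one cell of ``class_id``.

    The nucleus is an ellipse with axes ``(r*s, r/s)`` so its area is exactly
    ``pi * r**2`` regardless of the sampled aspect ``s``; the cytoplasm
    ellipse is scaled so area(nucleus)/area(cytoplasm) = nc_area_ratio.
    """
    h, w = spec.image_size
    scale = min(h, w) / 224.0  # morphology parameters are stated on 224 px
    m = spec.class_morphology[class_id]
    r = m.nucleus_radius_mean + m.nucleus_radius_sd * rng.standard_normal()
    r = max(r, 2.0) * scale
    aspect = rng.uniform(0.85, 1.18)
    theta = rng.uniform(0, np.pi)
    r_cyt = r / np.sqrt(m.nc_area_ratio)
    # keep the cytoplasm inside the frame
    r_cyt = min(r_cyt, 0.48 * min(h, w))
    r = min(r, 0.95 * r_cyt)
    jitter = 0.05 * min(h, w)
    cy = h / 2 + rng.uniform(-jitter, jitter)
    cx = w / 2 + rng.uniform(-jitter, jitter)
    return {
        "nucleus_radius": r,
        "aspect": aspect,
        "theta": theta,
        "cytoplasm_radius": r_cyt,
        "center": (cy, cx),
    }


def generate_cell_image(
    class_id: int,
    spec: FixtureSpec,
    rng: np.random.Generator,
    return_meta: bool = False,
):
    """Render one synthetic cell image (8-bit RGB, H x W x 3).

    Two concentric filled ellipses (nucleus inside cytoplasm) on a pale
    background, with per-class stain hue and Gaussian chromatin texture in
    the nucleus.  Deterministic given the rng state.

    When ``return_meta`` is true, also returns a dict with the sampled
    geometry and boolean ``nucleus_mask`` / ``cytoplasm_mask`` arrays
    (used e.g. for localisation sanity checks of the explanation maps).
    """
    if not 0 <= class_id < spec.n_classes:
        raise ValueError(f"unknown class_id {class_id}")
    h, w = spec.image_size
    m = spec.class_morphology[class_id]
    geo = _sample_geometry(class_id, spec, rng)
    cy, cx = geo["center"]
    r, s, th = geo["nucleus_radius"], geo["aspect"], geo["theta"]
    nuc = _ellipse_mask(h, w, cy, cx, r * s, r / s, th)
    cyt = _ellipse_mask(h, w, cy, cx, geo["cytoplasm_radius"] * s,
                        geo["cytoplasm_radius"] / s, th)

    hsv = np.zeros((h, w, 3), dtype=np.float64)
    hsv[..., 0] = m.stain_hue
    hsv[..., 1] = 0.04  # near-white slide background
    hsv[..., 2] = 0.96
    hsv[..., 1][cyt] = 0.45
    hsv[..., 2][cyt] = 0.80
    hsv[..., 1][nuc] = 0.75
    hsv[..., 2][nuc] = 0.40
    # chromatin texture: Gaussian value noise inside the nucleus
    noise = m.texture_noise * rng.standard_normal((h, w))
    hsv[..., 2][nuc] += noise[nuc]
    # mild global acquisition noise
    hsv[..., 2] += 0.01 * rng.standard_normal((h, w))
    hsv[..., 2] = np.clip(hsv[..., 2], 0, 1)
    rgb = (hsv2rgb(hsv) * 255).round().astype(np.uint8)
    if return_meta:
        meta = dict(geo)
        meta["nucleus_mask"] = nuc
        meta["cytoplasm_mask"] = cyt
        return rgb, meta
    return rgb


def generate_image_array(spec: FixtureSpec):
    """In-memory variant: returns (images (n,H,W,3) uint8, labels (n,))."""
    ss = np.random.SeedSequence(spec.seed)
    child = ss.spawn(spec.n_images)
    images, labels = [], []
    i = 0
    for c, count in enumerate(spec.per_class_counts):
        for _ in range(count):
            rng = np.random.Generator(np.random.PCG64(child[i]))
            images.append(generate_cell_image(c, spec, rng))
            labels.append(c)
            i += 1
    return np.stack(images), np.asarray(labels, dtype=np.int64)


def generate_image_dataset(spec: FixtureSpec, out_dir: str | Path) -> pd.DataFrame:
    """Write a class-per-subdirectory PNG tree plus a manifest CSV.

    Returns the manifest with columns ``path, class_index, class_name, seed``;
    total image count equals ``sum(per_class_counts)``.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as e:  # unwritable target
        raise OSError(f"cannot create output directory {out_dir}: {e}") from e
    ss = np.random.SeedSequence(spec.seed)
    child = ss.spawn(spec.n_images)
    rows = []
    i = 0
    for c, count in enumerate(spec.per_class_counts):
        cls_dir = out_dir / spec.class_names[c]
        cls_dir.mkdir(exist_ok=True)
        for j in range(count):
            rng = np.random.Generator(np.random.PCG64(child[i]))
            img = generate_cell_image(c, spec, rng)
            rel = f"{spec.class_names[c]}/img_{j:05d}.png"
            iio.imwrite(out_dir / rel, img)
            rows.append(
                {"path": rel, "class_index": c,
                 "class_name": spec.class_names[c], "seed": int(child[i].entropy)
                 if isinstance(child[i].entropy, int) else spec.seed}
            )
            i += 1
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_image_dataset(root: str | Path):
    """Read a class-per-subdirectory image tree back into arrays."""
    root = Path(root)
    manifest = pd.read_csv(root / "manifest.csv")
    images = np.stack([iio.imread(root / p) for p in manifest["path"]])
    return images, manifest["class_index"].to_numpy(dtype=np.int64)


# ---------------------------------------------------------------- features
@dataclass
class SyntheticFeatureSpec:
    """Feature matrix with a planted informative-column subset.

    ``k_informative`` columns carry class-dependent means spaced
    ``effect_size * noise_sd`` apart between consecutive classes; the
    remaining columns are exchangeable N(0, noise_sd) noise.
    """

    n_samples: int
    p_features: int
    k_informative: int
    effect_size: float = 1.0
    noise_sd: float = 1.0
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_informative > self.p_features:
            raise ValueError("k_informative must be <= p_features")
        if self.n_samples < self.n_classes:
            raise ValueError("need at least one sample per class")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")


def generate_feature_matrix(spec: SyntheticFeatureSpec):
    """Returns ``(FeatureMatrix, labels, informative_indices)``.

    Labels are balanced as evenly as ``n_samples`` allows.  For each
    informative column the class means are ``effect_size * noise_sd`` apart,
    with the class-to-mean assignment permuted per column so no single
    direction dominates.
    """
    rng = np.random.default_rng(spec.seed)
    n, p, k = spec.n_samples, spec.p_features, spec.k_informative
    base = n // spec.n_classes
    counts = [base + (1 if c < n % spec.n_classes else 0)
              for c in range(spec.n_classes)]
    labels = np.repeat(np.arange(spec.n_classes), counts)
    X = rng.normal(0.0, spec.noise_sd, size=(n, p))
    informative = np.sort(rng.choice(p, size=k, replace=False))
    offsets = np.arange(spec.n_classes, dtype=np.float64)
    offsets -= offsets.mean()
    for col in informative:
        perm = rng.permutation(spec.n_classes)
        shift = spec.effect_size * spec.noise_sd * offsets[perm]
        X[:, col] += shift[labels]
    fm = FeatureMatrix(values=X, labels=labels, source="synthetic",
                       network="none")
    return fm, labels, informative
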