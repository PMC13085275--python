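"""Haar-wavelet fusion of dual-layer deep features.

Per network, the pooling-layer and attention-layer feature vectors are
concatenated (length 2C) and compressed by a 1-D Haar discrete wavelet
transform applied row-wise: each decomposition level halves the length,
and only the approximation coefficients (CA) are retained.  With the
orthonormal two-tap Haar filter

    CA_i = (v_{2i} + v_{2i+1}) / sqrt(2),   CD_i = (v_{2i} - v_{2i+1}) / sqrt(2),

energy is conserved (||CA||^2 + ||CD||^2 = ||v||^2), so the retained CA
energy can never exceed the input energy.  Level 1 on a 2C-length vector
yields C coefficients; level 2 yields C/2 — e.g. 1024 -> 512 -> 256 for
the 512-channel backbone and 2560 -> 1280 -> 640 for the 1280-channel
backbones.

Every in-scope length is divisible by 4 so padding never triggers, but for
generality odd-length inputs are symmetric-padded by one reflected trailing
sample before pairing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureMatrix

SQRT2 = np.sqrt(2.0)


def concat_dual(pool_f: FeatureMatrix, attn_f: FeatureMatrix) -> FeatureMatrix:
    """Column-concatenate pooling then attention features of one network."""
    if pool_f.n_samples != attn_f.n_samples:
        raise ValueError("sample counts differ")
    if not np.array_equal(pool_f.labels, attn_f.labels):
        raise ValueError("label vectors differ between the two layers")
    if pool_f.network != attn_f.network:
        raise ValueError(
            f"cannot concat features of networks {pool_f.network!r} "
            f"and {attn_f.network!r}"
        )
    return FeatureMatrix(
        values=np.concatenate([pool_f.values, attn_f.values], axis=1),
        labels=pool_f.labels.copy(),
        source="fused",
        network=pool_f.network,
        feature_names=pool_f.feature_names + attn_f.feature_names,
    )


def haar_step(v: np.ndarray):
    """One orthonormal Haar analysis step on the last axis.

    Returns ``(CA, CD)``; works on vectors or row-wise on matrices.  Odd
    lengths are extended by repeating the final sample (symmetric padding).
    """
    v = np.asarray(v, dtype=np.float64)
    m = v.shape[-1]
    if m < 2:
        raise ValueError("haar_step needs length >= 2")
    if m % 2 == 1:
        v = np.concatenate([v, v[..., -1:]], axis=-1)
    even = v[..., 0::2]
    odd = v[..., 1::2]
    return (even + odd) / SQRT2, (even - odd) / SQRT2


@dataclass
class FusedFeatureSet:
    """DWT-fused features tagged with decomposition level and provenance."""

    matrix: FeatureMatrix
    level: int
    parent_network: str
    wavelet: str = "haar"


def dwt_fuse(concat_f: FeatureMatrix, level: int) -> FusedFeatureSet:
    """Recursive Haar CA extraction: ``level`` analysis steps row-wise.

    Detail coefficients are computed and discarded at every step; only the
    final approximation band is kept as the fused feature set.
    """
    if level not in (1, 2):
        raise ValueError("decomposition level must be 1 or 2")
    ca = concat_f.values
    for _ in range(level):
        ca, _cd = haar_step(ca)
    names = [f"{concat_f.network}.dwt{level}.{j}" for j in range(ca.shape[1])]
    matrix = FeatureMatrix(
        values=ca, labels=concat_f.labels.copy(), source="fused",
        network=concat_f.network, feature_names=names,
    )
    return FusedFeatureSet(matrix=matrix, level=level,
                           parent_network=concat_f.network)
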