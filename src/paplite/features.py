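"""Feature-matrix container shared by every stage of the pipeline.

A :class:`FeatureMatrix` is the currency passed between deep-feature
extraction, wavelet fusion, ANOVA selection and the classifier harness:
an ``n_samples x p`` real matrix plus an aligned integer label vector,
tagged with the layer it came from (``source``) and the backbone that
produced it (``network``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VALID_SOURCES = ("pooling", "attention", "fused", "ensemble", "synthetic")


@dataclass
class FeatureMatrix:
    """Deep-feature matrix with aligned class labels.

    Parameters
    ----------
    values : ndarray of shape (n_samples, p)
        Real-valued features; non-finite entries are rejected.
    labels : ndarray of shape (n_samples,)
        Dense integer class labels ``0..K-1``.
    source : str
        One of ``pooling | attention | fused | ensemble | synthetic``.
    network : str
        Name of the backbone the features came from ("mixed" for
        cross-network concatenations).
    feature_names : list of str, optional
        One identifier per column; defaults to ``f0..f{p-1}``.
    """

    values: np.ndarray
    labels: np.ndarray
    source: str = "synthetic"
    network: str = "none"
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if p < 1:
            raise ValueError("feature matrix needs at least one column")
        if self.labels.shape != (n,):
            raise ValueError(
                f"labels length {self.labels.shape} does not match n={n}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature matrix contains non-finite entries")
        if self.source not in VALID_SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if not self.feature_names:
            self.feature_names = [f"f{j}" for j in range(p)]
        if len(self.feature_names) != p:
            raise ValueError("feature_names length must equal column count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0

    # ------------------------------------------------------------------ IO
    def to_csv(self, path: str | Path) -> None:
        """Write ``feature_names...,label`` CSV plus a ``.meta.json`` sidecar."""
        path = Path(path)
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df["label"] = self.labels
        df.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(
            json.dumps({"source": self.source, "network": self.network})
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        df = pd.read_csv(path)
        if "label" not in df.columns:
            raise ValueError("feature CSV must contain a 'label' column")
        meta = {"source": "synthetic", "network": "none"}
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        if sidecar.exists():
            meta.update(json.loads(sidecar.read_text()))
        labels = df.pop("label").to_numpy()
        return cls(
            values=df.to_numpy(dtype=np.float64),
            labels=labels,
            source=meta["source"],
            network=meta["network"],
            feature_names=list(df.columns),
        )

    def to_npz(self, path: str | Path) -> None:
        """Lossless binary round-trip (NumPy .npz container)."""
        np.savez_compressed(
            path,
            values=self.values,
            labels=self.labels,
            source=np.str_(self.source),
            network=np.str_(self.network),
            feature_names=np.array(self.feature_names),
        )

    @classmethod
    def from_npz(cls, path: str | Path) -> "FeatureMatrix":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                values=z["values"],
                labels=z["labels"],
                source=str(z["source"]),
                network=str(z["network"]),
                feature_names=[str(s) for s in z["feature_names"]],
            )
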