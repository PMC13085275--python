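"""Cross-network ensembling and ANOVA F-ratio feature selection.

The fused feature sets of the individual networks are concatenated (fixed
column order: efficientnetb0, mobilenet, resnet18, then any others in input
order) and each column is scored by the one-way ANOVA F-ratio —
between-class mean square over within-class mean square with degrees of
freedom (K-1, n-K).  Selection is purely rank-based (top-k by descending
F); p-values are computed for inspection but no multiple-testing
correction is applied since no threshold is ever placed on them.

Degenerate columns: zero within-class variance with unequal class means
gives F = +inf (ranked first); a globally constant column gives F = 0
(ranked last).  Ties break toward the lower column index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureMatrix
from .fusion import FusedFeatureSet

CANONICAL_NETWORK_ORDER = ("efficientnetb0", "mobilenet", "resnet18")


def concat_networks(sets: list[FusedFeatureSet]) -> FeatureMatrix:
    """Concatenate fused sets across networks into one ensemble matrix."""
    if not sets:
        raise ValueError("need at least one fused feature set")
    ref = sets[0].matrix
    for s in sets[1:]:
        if s.matrix.n_samples != ref.n_samples:
            raise ValueError("sample counts differ across networks")
        if not np.array_equal(s.matrix.labels, ref.labels):
            raise ValueError("label vectors differ across networks")

    def order_key(i_s):
        i, s = i_s
        try:
            return (CANONICAL_NETWORK_ORDER.index(s.parent_network), i)
        except ValueError:
            return (len(CANONICAL_NETWORK_ORDER), i)

    ordered = [s for _, s in sorted(enumerate(sets), key=order_key)]
    values = np.concatenate([s.matrix.values for s in ordered], axis=1)
    names = [n for s in ordered for n in s.matrix.feature_names]
    return FeatureMatrix(values=values, labels=ref.labels.copy(),
                         source="ensemble", network="mixed",
                         feature_names=names)


@dataclass
class FeatureRanking:
    """Per-column F-ratios, p-values and the descending-F permutation."""

    f_scores: np.ndarray
    p_values: np.ndarray
    order: np.ndarray
    feature_names: list[str]
    tie_policy: str = "lower-index-first"

    def to_frame(self) -> pd.DataFrame:
        ranks = np.empty(len(self.order), dtype=int)
        ranks[self.order] = np.arange(len(self.order))
        return pd.DataFrame({
            "feature_name": self.feature_names,
            "F": self.f_scores,
            "p": self.p_values,
            "rank": ranks,
        })


def anova_f_scores(x: FeatureMatrix) -> FeatureRanking:
    """One-way ANOVA F-ratio per column against the class labels."""
    labels = x.labels
    classes, counts = np.unique(labels, return_counts=True)
    k = len(classes)
    n = x.n_samples
    if k < 2:
        raise ValueError("ANOVA needs at least 2 classes")
    if counts.min() < 2:
        bad = classes[counts.argmin()]
        raise ValueError(f"class {bad} has fewer than 2 samples")
    v = x.values
    grand = v.mean(axis=0)
    ss_between = np.zeros(v.shape[1])
    ss_within = np.zeros(v.shape[1])
    for c, nc in zip(classes, counts):
        sub = v[labels == c]
        mc = sub.mean(axis=0)
        ss_between += nc * (mc - grand) ** 2
        ss_within += ((sub - mc) ** 2).sum(axis=0)
    df_b, df_w = k - 1, n - k
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ms_between / ms_within
    # within-MS = 0: perfect separation (F = inf) unless the column is
    # globally constant, in which case F is defined as 0.
    degenerate = ms_within <= 0
    f[degenerate & (ss_between > 0)] = np.inf
    f[degenerate & (ss_between <= 0)] = 0.0
    p = np.where(np.isfinite(f), stats.f.sf(np.where(np.isfinite(f), f, 0),
                                            df_b, df_w), 0.0)
    p[f == 0] = 1.0
    order = np.lexsort((np.arange(len(f)), -f))
    return FeatureRanking(f_scores=f, p_values=p, order=order,
                          feature_names=list(x.feature_names))


def select_top_k(ranking: FeatureRanking, k: int) -> np.ndarray:
    """First k column indices of the descending-F order (deterministic)."""
    p = len(ranking.order)
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}], got {k}")
    return ranking.order[:k].copy()


def sweep_k(x: FeatureMatrix, classifier_specs, grid: list[int],
            n_folds: int = 5, seed: int = 0):
    """Cross-validated accuracy for each (classifier, k) on the grid.

    The ranking is computed once on the full matrix and the top-k columns
    are re-evaluated per grid point with stratified k-fold CV.  Returns
    ``(accuracy DataFrame indexed by classifier name, best-k Series)``.
    """
    from .evaluation import cross_val_accuracy  # deferred: avoids cycle

    p = x.n_features
    for k in grid:
        if not 1 <= k <= p:
            raise ValueError(f"grid value {k} outside [1, {p}]")
    ranking = anova_f_scores(x)
    table = pd.DataFrame(index=[s.name for s in classifier_specs],
                         columns=list(grid), dtype=float)
    for k in grid:
        cols = select_top_k(ranking, k)
        sub = FeatureMatrix(values=x.values[:, cols], labels=x.labels.copy(),
                            source=x.source, network=x.network,
                            feature_names=[x.feature_names[j] for j in cols])
        for spec in classifier_specs:
            table.loc[spec.name, k] = cross_val_accuracy(
                sub, spec, n_folds=n_folds, seed=seed)
    best_k = table.astype(float).idxmax(axis=1)
    return table, best_k
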