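"""End-to-end orchestration of the four experimental settings.

Setting 1  end-to-end softmax classification of each attention CNN
Setting 2  per-layer deep features (pooling / attention) -> classifiers
Setting 3  per-network Haar-DWT fusion of the two layers -> classifiers
Setting 4  cross-network concatenation -> ANOVA top-k sweep -> classifiers

CNN training uses a stratified 70/30 train/test split; classifier
evaluation uses stratified k-fold cross-validation on the extracted
features.  Every stage's outputs are persisted under ``output_dir`` and a
run manifest records the config hash, seed and library versions, so a run
is reproducible from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from . import __version__
from .evaluation import (ClassifierSpec, default_classifiers,
                         evaluate_classifiers)
from .extraction import extract_attention_features, extract_pooling_features
from .features import FeatureMatrix
from .fixtures import (FixtureSpec, generate_image_array,
                       high_separability_morphologies, load_image_dataset)
from .fusion import concat_dual, dwt_fuse
from .nn.augment import AugmentationRanges
from .nn.models import BACKBONE_DEFS, build_attention_model
from .nn.train import TrainingConfig, train_model
from .selection import anova_f_scores, concat_networks, select_top_k, sweep_k

log = logging.getLogger("paplite")

_TRAINING_KEYS = {"minibatch", "epochs", "learning_rate", "momentum",
                  "weight_decay", "lr_schedule", "validation_frequency",
                  "seed"}
_FIXTURE_KEYS = {"n_classes", "per_class_counts", "image_size", "seed",
                 "separability"}
_TOP_KEYS = {"setting", "dataset_dir", "fixture", "backbones", "dwt_level",
             "k_grid", "classifiers", "n_folds", "n_repeats", "seed",
             "output_dir", "training", "augment"}


@dataclass
class RunConfig:
    setting: int
    seed: int
    output_dir: str = "paplite_run"
    dataset_dir: str | None = None
    fixture: dict = field(default_factory=dict)
    backbones: list[str] = field(default_factory=lambda: ["toy_cnn"])
    dwt_level: int = 2
    k_grid: list[int] | None = None
    classifiers: list[str] | None = None
    n_folds: int = 5
    n_repeats: int = 5
    training: TrainingConfig = field(default_factory=TrainingConfig)
    augment: bool = True

    def classifier_specs(self) -> list[ClassifierSpec]:
        if self.classifiers is None:
            return default_classifiers()
        return [ClassifierSpec(name=n, standardize=(n != "CKNN"))
                for n in self.classifiers]


def validate_config(raw: dict) -> RunConfig:
    """Validate a raw (e.g. YAML-parsed) config and fill the defaults.

    Unknown keys are rejected with a field-level message; training
    defaults are batch 5 / 50 epochs / lr 1e-3 / momentum 0.9 /
    decay 1e-4 / no schedule.
    """
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "setting" not in raw or raw["setting"] not in (1, 2, 3, 4):
        raise ValueError("setting must be one of 1, 2, 3, 4")
    if "seed" not in raw:
        raise ValueError("seed is mandatory")
    tr = dict(raw.get("training", {}))
    unknown_tr = set(tr) - _TRAINING_KEYS
    if unknown_tr:
        raise ValueError(f"unknown training keys: {sorted(unknown_tr)}")
    tr.setdefault("seed", raw["seed"])
    training = TrainingConfig(**tr)  # dataclass validates positivity
    fx = dict(raw.get("fixture", {}))
    unknown_fx = set(fx) - _FIXTURE_KEYS
    if unknown_fx:
        raise ValueError(f"unknown fixture keys: {sorted(unknown_fx)}")
    backbones = list(raw.get("backbones", ["toy_cnn"]))
    for b in backbones:
        if b not in BACKBONE_DEFS:
            raise ValueError(f"unknown backbone {b!r}")
    cfg = RunConfig(
        setting=raw["setting"], seed=int(raw["seed"]),
        output_dir=raw.get("output_dir", "paplite_run"),
        dataset_dir=raw.get("dataset_dir"), fixture=fx,
        backbones=backbones, dwt_level=int(raw.get("dwt_level", 2)),
        k_grid=raw.get("k_grid"), classifiers=raw.get("classifiers"),
        n_folds=int(raw.get("n_folds", 5)),
        n_repeats=int(raw.get("n_repeats", 5)),
        training=training, augment=bool(raw.get("augment", True)),
    )
    if cfg.dwt_level not in (1, 2):
        raise ValueError("dwt_level must be 1 or 2")
    if cfg.n_folds < 2 or cfg.n_repeats < 1:
        raise ValueError("n_folds must be >= 2 and n_repeats >= 1")
    return cfg


def default_k_grid(pool_size: int) -> list[int]:
    """Selection sweep grid: 100..1500 step 100, clipped to the pool size."""
    grid = [k for k in range(100, 1501, 100) if k <= pool_size]
    return grid or [pool_size]


def _config_hash(cfg: RunConfig) -> str:
    d = asdict(cfg)
    return hashlib.sha256(
        json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:16]


def _load_images(cfg: RunConfig):
    if cfg.dataset_dir is not None:
        log.info("stage=data source=dir path=%s", cfg.dataset_dir)
        return load_image_dataset(cfg.dataset_dir)
    fx = dict(cfg.fixture)
    fx.setdefault("n_classes", 5)
    fx.setdefault("per_class_counts", [50] * fx["n_classes"])
    fx.setdefault("image_size", (32, 32))
    fx.setdefault("seed", cfg.seed)
    morphs = []
    if fx.get("separability", "default") == "high":
        morphs = high_separability_morphologies(fx["n_classes"])
    spec = FixtureSpec(n_classes=fx["n_classes"],
                       per_class_counts=list(fx["per_class_counts"]),
                       image_size=tuple(fx["image_size"]),
                       class_morphology=morphs, seed=fx["seed"])
    log.info("stage=data source=fixture n=%d", spec.n_images)
    return generate_image_array(spec)


def _train_backbones(cfg: RunConfig, images, labels, out: Path):
    """70/30 stratified split, train each backbone, return models + split."""
    idx_train, idx_test = train_test_split(
        np.arange(len(labels)), test_size=0.3, stratify=labels,
        random_state=cfg.seed)
    models = {}
    setting1 = {}
    ranges = AugmentationRanges() if cfg.augment else None
    n_classes = int(labels.max()) + 1
    for b in cfg.backbones:
        log.info("stage=train backbone=%s epochs=%d", b, cfg.training.epochs)
        model = build_attention_model(b, n_classes, seed=cfg.seed)
        history = train_model(model, images[idx_train], labels[idx_train],
                              cfg.training, augment=ranges,
                              val_images=images[idx_test],
                              val_labels=labels[idx_test])
        model.save(out / f"model_{b}.npz")
        train_acc = float(np.mean(model.predict(images[idx_train])
                                  == labels[idx_train]))
        test_acc = float(np.mean(model.predict(images[idx_test])
                                 == labels[idx_test]))
        models[b] = model
        setting1[b] = {"train_accuracy": train_acc, "test_accuracy": test_acc,
                       "final_epoch_loss": history["epoch_loss"][-1]}
    return models, setting1, (idx_train, idx_test)


def run_setting(cfg: RunConfig, cache: dict | None = None) -> dict:
    """Execute the configured setting end to end; returns a result dict.

    ``cache`` (optional) may carry intermediates from a previous call
    (keys ``images``/``labels``, ``models``, ``features``, ``fused``) so a
    later setting can be rerun without retraining; cached stages are used
    bit-identically.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cache = cache if cache is not None else {}
    result: dict = {"setting": cfg.setting}

    if "images" not in cache:
        cache["images"], cache["labels"] = _load_images(cfg)
    images, labels = cache["images"], cache["labels"]

    if "models" not in cache:
        cache["models"], cache["setting1"], cache["split"] = _train_backbones(
            cfg, images, labels, out)
    models = cache["models"]
    result["setting1"] = cache["setting1"]
    pd.DataFrame(cache["setting1"]).T.to_csv(out / "setting1_accuracy.csv")
    if cfg.setting == 1:
        _write_manifest(cfg, out)
        return result

    specs = cfg.classifier_specs()
    if "features" not in cache:
        cache["features"] = {
            b: (extract_pooling_features(m, images, labels),
                extract_attention_features(m, images, labels))
            for b, m in models.items()
        }
    features = cache["features"]

    if cfg.setting == 2:
        result["setting2"] = {}
        for b, (pool_f, attn_f) in features.items():
            for tag, fm in (("pooling", pool_f), ("attention", attn_f)):
                log.info("stage=evaluate setting=2 backbone=%s layer=%s",
                         b, tag)
                rep = evaluate_classifiers(fm, specs, n_folds=cfg.n_folds,
                                           n_repeats=cfg.n_repeats,
                                           seed=cfg.seed)
                rep.metric_means.to_csv(out / f"setting2_{b}_{tag}.csv")
                result["setting2"][f"{b}.{tag}"] = rep
        _write_manifest(cfg, out)
        return result

    if "fused" not in cache:
        cache["fused"] = {}
        for b, (pool_f, attn_f) in features.items():
            cat = concat_dual(pool_f, attn_f)
            cache["fused"][b] = {lvl: dwt_fuse(cat, lvl) for lvl in (1, 2)}
    fused = cache["fused"]
    result["fused_lengths"] = {
        b: {lvl: fs.matrix.n_features for lvl, fs in by_level.items()}
        for b, by_level in fused.items()
    }

    if cfg.setting == 3:
        result["setting3"] = {}
        for b, by_level in fused.items():
            fm = by_level[cfg.dwt_level].matrix
            log.info("stage=evaluate setting=3 backbone=%s level=%d p=%d",
                     b, cfg.dwt_level, fm.n_features)
            rep = evaluate_classifiers(fm, specs, n_folds=cfg.n_folds,
                                       n_repeats=cfg.n_repeats, seed=cfg.seed)
            rep.metric_means.to_csv(out / f"setting3_{b}.csv")
            result["setting3"][b] = rep
        _write_manifest(cfg, out)
        return result

    # ---- Setting 4: ensemble + ANOVA selection sweep -------------------
    ensemble = concat_networks(
        [fused[b][cfg.dwt_level] for b in cfg.backbones])
    ranking = anova_f_scores(ensemble)
    ranking.to_frame().to_csv(out / "setting4_ranking.csv", index=False)
    grid = cfg.k_grid or default_k_grid(ensemble.n_features)
    grid = [k for k in grid if k <= ensemble.n_features]
    log.info("stage=sweep setting=4 p=%d grid=%s", ensemble.n_features, grid)
    sweep_table, best_k = sweep_k(ensemble, specs, grid,
                                  n_folds=cfg.n_folds, seed=cfg.seed)
    sweep_table.to_csv(out / "setting4_sweep.csv")
    k_star = int(best_k.map(int).loc[
        sweep_table.max(axis=1).astype(float).idxmax()])
    cols = select_top_k(ranking, k_star)
    selected = FeatureMatrix(
        values=ensemble.values[:, cols], labels=ensemble.labels.copy(),
        source="ensemble", network="mixed",
        feature_names=[ensemble.feature_names[j] for j in cols])
    (out / "setting4_selected.json").write_text(
        json.dumps({"k": k_star, "columns": [int(c) for c in cols]}))
    rep = evaluate_classifiers(selected, specs, n_folds=cfg.n_folds,
                               n_repeats=cfg.n_repeats, seed=cfg.seed)
    rep.selected_k = k_star
    rep.metric_means.to_csv(out / "setting4_metrics.csv")
    rep.metric_variances.to_csv(out / "setting4_metric_variances.csv")
    if rep.anova is not None:
        rep.anova.to_frame().to_csv(out / "setting4_anova.csv", index=False)
    result["setting4"] = rep
    result["sweep"] = sweep_table
    result["best_k"] = k_star
    _write_manifest(cfg, out)
    return result


def _write_manifest(cfg: RunConfig, out: Path) -> None:
    import sklearn

    manifest = {
        "config": asdict(cfg),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "versions": {"paplite": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__, "sklearn": sklearn.__version__},
    }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
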