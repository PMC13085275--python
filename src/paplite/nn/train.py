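"""SGDM training loop for the attention CNNs.

Hyperparameter defaults follow the study configuration: mini-batch 5,
50 epochs, fixed learning rate 1e-3 (no schedule), momentum 0.9 and L2
weight decay 1e-4, with on-the-fly geometric augmentation applied to
training mini-batches only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .augment import AugmentationRanges, augment_image
from .layers import EPS
from .models import AttentionCNN


@dataclass
class TrainingConfig:
    minibatch: int = 5
    epochs: int = 50
    learning_rate: float = 0.001
    momentum: float = 0.9
    weight_decay: float = 0.0001
    lr_schedule: str = "none"
    validation_frequency: int = 50  # iterations between history records
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.minibatch, self.epochs, self.validation_frequency) <= 0:
            raise ValueError("minibatch, epochs, validation_frequency must be > 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.lr_schedule != "none":
            raise ValueError("only lr_schedule='none' is supported")


def cross_entropy(y: np.ndarray, yhat: np.ndarray, eps: float = EPS) -> float:
    """Categorical cross-entropy  -sum_c y_c log(yhat_c)  for one sample.

    ``y`` is a one-hot vector, ``yhat`` a probability vector (entries in
    (0, 1], summing to 1 within tolerance).  Zero probability at the true
    class is clamped to ``eps``.
    """
    y = np.asarray(y, dtype=np.float64)
    yhat = np.asarray(yhat, dtype=np.float64)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have the same length")
    if not np.isclose(yhat.sum(), 1.0, atol=1e-6):
        raise ValueError("yhat must sum to 1")
    return float(-np.sum(y * np.log(np.clip(yhat, eps, None))))


def train_model(model: AttentionCNN, images: np.ndarray, labels: np.ndarray,
                cfg: TrainingConfig,
                augment: AugmentationRanges | None = None,
                val_images: np.ndarray | None = None,
                val_labels: np.ndarray | None = None) -> dict:
    """Train in place with SGD-with-momentum; returns the run history.

    History lists ``(iteration, loss, train_batch_accuracy)`` every
    ``validation_frequency`` iterations plus per-epoch means, and
    validation accuracy per epoch when a validation set is given.
    Deterministic for a fixed config seed.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < model.n_classes or counts.min() < 1:
        raise ValueError("every class needs at least one training sample")
    rng = np.random.default_rng(cfg.seed)
    velocity = {id(p): np.zeros_like(p)
                for _, _, p, _ in model.parameters()}
    n = len(labels)
    history = {"iter": [], "loss": [], "batch_acc": [],
               "epoch_loss": [], "epoch_acc": [], "val_acc": []}
    it = 0
    for _epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_losses, ep_accs = [], []
        for start in range(0, n, cfg.minibatch):
            idx = order[start:start + cfg.minibatch]
            batch = images[idx]
            if augment is not None and not augment.is_identity():
                batch = np.stack(
                    [augment_image(im, augment, rng) for im in batch])
            loss, probs = model.train_step_grads(batch, labels[idx])
            acc = float(np.mean(np.argmax(probs, axis=1) == labels[idx]))
            for layer, name, p, g in model.parameters():
                v = velocity[id(p)]
                v *= cfg.momentum
                v -= cfg.learning_rate * (g + cfg.weight_decay * p)
                p += v
            it += 1
            ep_losses.append(loss)
            ep_accs.append(acc)
            if it % cfg.validation_frequency == 0:
                history["iter"].append(it)
                history["loss"].append(loss)
                history["batch_acc"].append(acc)
        history["epoch_loss"].append(float(np.mean(ep_losses)))
        history["epoch_acc"].append(float(np.mean(ep_accs)))
        if val_images is not None:
            history["val_acc"].append(
                float(np.mean(model.predict(val_images) == val_labels)))
    return history
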