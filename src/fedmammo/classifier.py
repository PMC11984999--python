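"""BIRADS classification: normalization, model, centralized training, F1.

Intensity normalization is min/max computed on the *training partition only*
and applied to every partition (values outside the training range clamp to
[0, 1]); the classifier is a communication-light convolutional network; the
evaluation surface is macro-averaged F1 reported per named (per-hospital)
test set alongside the confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix, f1_score

from .nn import Adam, SmallCNN, predict_batched, run_epochs, softmax_cross_entropy
from .nn.train import evaluate_loss


@dataclass
class TrainConfig:
    """Hyperparameters of the classification training loop.

    The documented defaults mirror a tuned clinical-scale configuration
    (cross-entropy loss, Adam, batch size 10, 100 epochs, learning rate
    1e-8); note that a 1e-8 learning rate is impractically small for the
    desk-scale synthetic runs in this repository, which pass 1e-3 instead.
    """

    learning_rate: float = 1e-8
    batch_size: int = 10
    epochs: int = 100
    seed: int = 0
    loss: str = "cross_entropy"

    def __post_init__(self) -> None:
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class NormStats:
    """Global pixel min/max of the training set."""

    pixel_min: float
    pixel_max: float

    def __post_init__(self) -> None:
        if not self.pixel_min < self.pixel_max:
            raise ValueError(
                f"need pixel_min < pixel_max, got ({self.pixel_min}, {self.pixel_max})"
            )


def compute_norm_stats(train_images) -> NormStats:
    """Min/max over all pixels of the training partition (and nothing else)."""
    arrays = [np.asarray(im) for im in train_images]
    if not arrays:
        raise ValueError("training set is empty")
    lo = min(float(a.min()) for a in arrays)
    hi = max(float(a.max()) for a in arrays)
    if lo == hi:
        raise ValueError(f"constant training set (min == max == {lo})")
    return NormStats(pixel_min=lo, pixel_max=hi)


def normalize(image: np.ndarray, stats: NormStats) -> np.ndarray:
    """``(x - min) / (max - min)``, clamped to [0, 1] for out-of-range pixels."""
    x = (np.asarray(image, dtype=np.float64) - stats.pixel_min) / (
        stats.pixel_max - stats.pixel_min
    )
    return np.clip(x, 0.0, 1.0)


def build_model(
    n_classes: int = 5,
    input_size: tuple[int, int] = (256, 256),
    base_channels: int = 8,
    n_blocks: int = 3,
    seed: int = 0,
) -> SmallCNN:
    """The classification network; parameter count stays under 2 million.

    Small models keep every federated round's parameter transfer cheap.
    """
    if min(input_size) % 2**n_blocks:
        raise ValueError(
            f"input_size {input_size} must be divisible by {2**n_blocks}"
        )
    model = SmallCNN(
        n_classes=n_classes, base=base_channels, n_blocks=n_blocks, seed=seed
    )
    assert model.n_parameters() < 2_000_000
    return model


@dataclass
class TrainResult:
    model: SmallCNN
    best_state: dict
    history: list[dict] = field(default_factory=list)


def train_centralized(
    model: SmallCNN,
    train: tuple[np.ndarray, np.ndarray],
    val: tuple[np.ndarray, np.ndarray],
    cfg: TrainConfig,
    epoch_offset: int = 0,
    opt: Adam | None = None,
) -> TrainResult:
    """The epoch loop: train one epoch, validate, repeat ``cfg.epochs`` times.

    Returns the final model together with the best-validation-loss state
    dict and a history entry per epoch. ``epoch_offset`` and ``opt`` let a
    federated client continue its global epoch schedule across rounds.
    """
    Xtr, ytr = train
    Xva, yva = val
    opt = opt or Adam(cfg.learning_rate)
    history = []
    best = {"val_loss": np.inf, "state": model.state_dict()}
    for epoch in range(cfg.epochs):
        tr = run_epochs(
            model, opt, softmax_cross_entropy, Xtr, ytr,
            epochs=1, batch_size=cfg.batch_size,
            base_seed=cfg.seed, epoch_offset=epoch_offset + epoch,
        )
        val_loss = evaluate_loss(model, softmax_cross_entropy, Xva, yva)
        history.append(
            {"epoch": epoch_offset + epoch, "train_loss": tr[0], "val_loss": val_loss}
        )
        if val_loss < best["val_loss"]:
            best = {"val_loss": val_loss, "state": model.state_dict()}
    return TrainResult(model=model, best_state=best["state"], history=history)


def predict_classes(model: SmallCNN, X: np.ndarray, batch_size: int = 32) -> np.ndarray:
    """Predicted class indices (0-based) for a stack of images."""
    return predict_batched(model, X, batch_size).argmax(axis=1)


def evaluate_f1(model: SmallCNN, test_sets: dict[str, tuple[np.ndarray, np.ndarray]]) -> dict:
    """Macro F1 and confusion matrix per named test set.

    Macro averaging (the unweighted mean of per-class F1 over the classes
    present in the test set's truth) is robust to the strong class imbalance
    typical of BIRADS cohorts.
    """
    results = {}
    for name, (X, y) in test_sets.items():
        if len(y) == 0:
            raise ValueError(f"test set {name!r} is empty")
        pred = predict_classes(model, X)
        labels = np.unique(y)
        results[name] = {
            "f1": float(f1_score(y, pred, labels=labels, average="macro", zero_division=0)),
            "confusion": confusion_matrix(y, pred, labels=labels),
            "labels": labels,
        }
    return results
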