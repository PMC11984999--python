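"""Supervised breast-area detection: UNet training, metrics, and cleaning.

The segmenter is trained on the bootstrapped corpus (all variants of one
source image kept in the same split to avoid leakage), evaluated with
Dice/IoU, and applied to harmonized mammograms to zero out everything outside
the breast — printed labels above all — before peripheral cropping down to
the classifier input size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as cc_label

from .bootstrap import MaskedMammogram
from .nn import Adam, UNet, bce_dice_loss, predict_batched, run_epochs, sigmoid
from .preprocess import _resize


@dataclass
class SegMetrics:
    dice: float
    iou: float


@dataclass
class SegTrainConfig:
    """Training configuration for the breast-area UNet."""

    n_train: int = 1000
    n_val: int = 300
    epochs: int = 8
    learning_rate: float = 1e-3
    batch_size: int = 8
    seed: int = 0
    base_channels: int = 8
    depth: int = 3

    def __post_init__(self) -> None:
        if self.n_train < 1 or self.n_val < 1:
            raise ValueError("n_train and n_val must be >= 1")


def split_auld(
    manifest: pd.DataFrame, cfg: SegTrainConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split the bootstrap corpus into train/val/test by *source image*.

    Sizes are exactly ``(n_train, n_val, remainder)`` in samples; all
    variants of one source image land in the same set so that a fake-label
    copy can never leak across splits. Requires the per-set sample counts to
    be divisible by the (uniform) variants-per-source count.
    """
    if len(manifest) < cfg.n_train + cfg.n_val + 1:
        raise ValueError(
            f"manifest has {len(manifest)} samples; need more than "
            f"{cfg.n_train + cfg.n_val}"
        )
    groups = manifest.groupby("source_index").size()
    sizes = groups.unique()
    if sizes.size != 1:
        raise ValueError("variant counts differ across source images")
    per_source = int(sizes[0])
    if cfg.n_train % per_source or cfg.n_val % per_source:
        raise ValueError(
            f"n_train/n_val must be divisible by the {per_source} variants per source"
        )
    sources = np.array(sorted(groups.index))
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 23]))
    rng.shuffle(sources)
    n_tr = cfg.n_train // per_source
    n_va = cfg.n_val // per_source
    train_src = set(sources[:n_tr])
    val_src = set(sources[n_tr : n_tr + n_va])
    test_src = set(sources[n_tr + n_va :])
    train = manifest[manifest.source_index.isin(train_src)]
    val = manifest[manifest.source_index.isin(val_src)]
    test = manifest[manifest.source_index.isin(test_src)]
    return train, val, test


def _stack(samples: list[MaskedMammogram]) -> tuple[np.ndarray, np.ndarray]:
    X = np.stack([s.image for s in samples]).astype(np.float32)[:, None]
    # normalize each image to [0, 1] for stable optimization
    mins = X.min(axis=(2, 3), keepdims=True)
    maxs = X.max(axis=(2, 3), keepdims=True)
    X = (X - mins) / np.maximum(maxs - mins, 1e-9)
    T = np.stack([s.mask for s in samples]).astype(np.float32)[:, None]
    return X, T


def train_unet(
    train: list[MaskedMammogram],
    val: list[MaskedMammogram],
    cfg: SegTrainConfig,
) -> tuple[UNet, list[dict]]:
    """Train the breast-area UNet; returns the best-validation checkpoint.

    The history has one entry per epoch with train loss, validation loss and
    validation Dice; the returned model carries the weights of the epoch with
    the lowest validation loss.
    """
    if not train or not val:
        raise ValueError("train and val sets must be non-empty")
    Xtr, Ttr = _stack(train)
    Xva, Tva = _stack(val)
    model = UNet(base=cfg.base_channels, depth=cfg.depth, seed=cfg.seed)
    opt = Adam(cfg.learning_rate)
    history: list[dict] = []
    best = {"val_loss": np.inf, "state": model.state_dict()}
    for epoch in range(cfg.epochs):
        train_losses = run_epochs(
            model, opt, bce_dice_loss, Xtr, Ttr,
            epochs=1, batch_size=cfg.batch_size,
            base_seed=cfg.seed, epoch_offset=epoch,
        )
        val_loss, val_dice = _validate(model, Xva, Tva, cfg.batch_size)
        history.append(
            {
                "epoch": epoch,
                "train_loss": train_losses[0],
                "val_loss": val_loss,
                "val_dice": val_dice,
            }
        )
        if val_loss < best["val_loss"]:
            best = {"val_loss": val_loss, "state": model.state_dict()}
    model.load_state_dict(best["state"])
    return model, history


def _validate(model, X, T, batch_size):
    logits = predict_batched(model, X, batch_size)
    loss, _ = bce_dice_loss(logits, T)
    pred = sigmoid(logits) > 0.5
    truth = T > 0.5
    inter = (pred & truth).sum()
    denom = pred.sum() + truth.sum()
    dice = 1.0 if denom == 0 else 2.0 * inter / denom
    return float(loss), float(dice)


def predict_mask(model: UNet, image: np.ndarray) -> np.ndarray:
    """Segment one image: threshold at 0.5, keep the largest component.

    Input intensities are min-max scaled the same way training images were.
    An all-background prediction returns an empty mask (callers fall back to
    the uncleaned image).
    """
    image = np.asarray(image, dtype=np.float32)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    lo, hi = image.min(), image.max()
    x = (image - lo) / max(hi - lo, 1e-9)
    logits = model(x[None, None])
    prob = sigmoid(logits)[0, 0]
    mask = prob > 0.5
    if not mask.any():
        return mask
    comps = cc_label(mask, connectivity=2)
    largest = np.argmax(np.bincount(comps.ravel())[1:]) + 1
    return ndimage.binary_fill_holes(comps == largest)


def dice_iou(pred: np.ndarray, truth: np.ndarray) -> SegMetrics:
    """Dice and IoU between two binary masks.

    ``dice = 2|A∩B| / (|A|+|B|)``, ``iou = |A∩B| / |A∪B|``; two empty masks
    count as perfect agreement (both metrics 1).
    """
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {truth.shape}")
    inter = int((pred & truth).sum())
    a, b = int(pred.sum()), int(truth.sum())
    union = a + b - inter
    if a + b == 0:
        return SegMetrics(dice=1.0, iou=1.0)
    return SegMetrics(dice=2.0 * inter / (a + b), iou=inter / union if union else 1.0)


def clean_and_crop(
    image: np.ndarray,
    mask: np.ndarray,
    margin: int = 0,
    out_size: tuple[int, int] = (256, 256),
) -> np.ndarray:
    """Apply a breast mask and crop away the background.

    Pixels outside the mask are zeroed, the image is cropped to the mask
    bounding box plus ``margin`` (clamped to the image bounds), and resized to
    ``out_size`` — the classifier input resolution.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError(f"image {image.shape} and mask {mask.shape} shapes differ")
    if not mask.any():
        raise ValueError("empty mask: fall back to the uncleaned image")
    cleaned = np.where(mask, image, 0.0)
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    r0 = max(0, rows[0] - margin)
    r1 = min(image.shape[0], rows[-1] + 1 + margin)
    c0 = max(0, cols[0] - margin)
    c1 = min(image.shape[1], cols[-1] + 1 + margin)
    cropped = cleaned[r0:r1, c0:c1]
    return _resize(cropped, tuple(out_size), order=1)
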