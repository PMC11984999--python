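"""Bootstrapping a breast-segmentation training corpus without annotations.

Supervised breast-area detection needs masks, but none exist for raw
mammograms. The bootstrap stage therefore: (1) clusters pixel intensities
with K-means to get candidate breast masks, (2) filters candidates with
geometric plausibility criteria — an automated stand-in for manual visual
inspection, (3) augments each accepted image into ``n_variants`` copies, the
original plus copies carrying one randomly-sized, randomly-placed fake
printed label in the background. Training on the augmented corpus (the
fake-label variants all share the *original* mask) teaches the segmenter
that bright rectangles are not breast tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as cc_label, regionprops
from sklearn.cluster import KMeans

from .types import ImageRecord


@dataclass
class MaskedMammogram:
    """An image paired with a (possibly bootstrapped) breast mask."""

    image: np.ndarray
    mask: np.ndarray
    provenance: str = "kmeans"  # or "ground_truth"
    quality_score: float = 0.0
    label_box: Optional[tuple[int, int, int, int]] = None

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape} and mask {self.mask.shape} shapes differ"
            )


@dataclass
class AugmentationConfig:
    """Fake-label augmentation parameters.

    ``near_breast_frac`` of the fake labels are placed hugging the breast
    boundary (1-4 px clearance): these hard negatives are what teach the
    segmenter not to annex a label that happens to print next to the tissue.
    """

    n_variants: int = 5
    label_size_range: tuple[float, float] = (0.05, 0.20)
    label_intensity_quantile: float = 0.99
    background_only: bool = True
    near_breast_frac: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        lo, hi = self.label_size_range
        if not (0 < lo <= hi < 0.5):
            raise ValueError("label_size_range must lie within (0, 0.5)")


@dataclass
class QualityThresholds:
    """Geometric plausibility criteria standing in for visual mask inspection."""

    min_area: float = 0.08
    max_area: float = 0.75
    min_solidity: float = 0.85


def kmeans_mask(image: np.ndarray, k: int = 2, seed: int = 0) -> np.ndarray:
    """Candidate breast mask from intensity clustering.

    Pixels are clustered into ``k`` intensity groups; everything brighter
    than the darkest (background) cluster is foreground. The mask is the
    largest connected foreground component with holes filled — printed
    labels, being background-detached blobs, are discarded at this step
    whenever the breast is the larger component.
    """
    image = np.asarray(image, dtype=np.float64)
    values = image.reshape(-1, 1)
    if np.unique(values).size < 2:
        raise ValueError("constant image: intensity clustering cannot separate clusters")
    km = KMeans(n_clusters=k, n_init=1, random_state=seed).fit(values)
    order = np.argsort(km.cluster_centers_.ravel(), kind="stable")
    background = order[0]
    fg = (km.labels_ != background).reshape(image.shape)
    if not fg.any():
        return fg
    comps = cc_label(fg, connectivity=2)
    largest = np.argmax(np.bincount(comps.ravel())[1:]) + 1
    return ndimage.binary_fill_holes(comps == largest)


def quality_filter(
    candidate: MaskedMammogram, thresholds: QualityThresholds | None = None
) -> bool:
    """Accept a candidate mask if it is geometrically plausible.

    Criteria: foreground area fraction within ``[min_area, max_area]``, the
    mask touches exactly one vertical image border (a breast is attached to
    one side, a label to none, a flood-fill failure to both), and solidity at
    least ``min_solidity``. Sets ``candidate.quality_score`` to the product of
    per-criterion scores.
    """
    th = thresholds or QualityThresholds()
    mask = candidate.mask
    n = mask.size
    area = mask.sum() / n
    area_ok = th.min_area <= area <= th.max_area

    touches_left = bool(mask[:, 0].any())
    touches_right = bool(mask[:, -1].any())
    border_ok = touches_left != touches_right

    solidity = 0.0
    if mask.any():
        props = regionprops(mask.astype(np.uint8))
        solidity = float(props[0].solidity)
    solidity_ok = solidity >= th.min_solidity

    candidate.quality_score = (
        (1.0 if area_ok else 0.0) * (1.0 if border_ok else 0.0) * (solidity if solidity_ok else 0.0)
    )
    return area_ok and border_ok and solidity_ok


def augment_with_fake_labels(
    sample: MaskedMammogram, cfg: AugmentationConfig | None = None
) -> list[MaskedMammogram]:
    """The n-variant augmentation: the original plus fake-label copies.

    Each of variants 2..n carries exactly one bright rectangle placed in the
    background, disjoint from the breast mask; every variant keeps the
    original mask, so the label pixels are labelled non-breast.
    """
    cfg = cfg or AugmentationConfig()
    if not sample.mask.any():
        raise ValueError("cannot augment a sample with an empty mask")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 17]))
    out = [
        MaskedMammogram(
            image=sample.image.copy(),
            mask=sample.mask.copy(),
            provenance=sample.provenance,
            quality_score=sample.quality_score,
        )
    ]
    rows, cols = sample.image.shape
    intensity = float(
        np.quantile(sample.image[sample.mask], cfg.label_intensity_quantile)
    )
    dilated = ndimage.binary_dilation(sample.mask, iterations=1)
    dist_to_breast = ndimage.distance_transform_edt(~dilated)
    for _ in range(cfg.n_variants - 1):
        near = rng.random() < cfg.near_breast_frac
        box = _sample_label_box(
            rng, dilated, cfg.label_size_range,
            dist=dist_to_breast if near else None,
        )
        if box is None and near:  # fall back to unconstrained placement
            box = _sample_label_box(rng, dilated, cfg.label_size_range)
        if box is None:
            raise ValueError("no background room left for a fake label")
        r0, c0, r1, c1 = box
        img = sample.image.copy()
        img[r0:r1, c0:c1] = intensity
        out.append(
            MaskedMammogram(
                image=img,
                mask=sample.mask.copy(),
                provenance=sample.provenance,
                quality_score=sample.quality_score,
                label_box=box,
            )
        )
    return out


def _sample_label_box(
    rng, forbidden: np.ndarray, size_range, dist: np.ndarray | None = None,
    max_tries: int = 200,
):
    """Rectangle in the allowed region; with ``dist`` given, only boxes whose
    closest edge lies within 4 px of the breast are accepted (hard negatives)."""
    rows, cols = forbidden.shape
    side = min(rows, cols)
    for _ in range(max_tries):
        h = max(2, int(rng.uniform(*size_range) * side))
        w = max(2, int(rng.uniform(*size_range) * side))
        if h >= rows or w >= cols:
            continue
        r0 = int(rng.integers(0, rows - h))
        c0 = int(rng.integers(0, cols - w))
        window = slice(r0, r0 + h), slice(c0, c0 + w)
        if forbidden[window].any():
            continue
        if dist is not None and dist[window].min() > 4:
            continue
        return (r0, c0, r0 + h, c0 + w)
    return None


@dataclass
class AuldResult:
    """The augmented bootstrap corpus and its manifest."""

    samples: list[MaskedMammogram]
    manifest: pd.DataFrame
    rejections: dict[int, str] = field(default_factory=dict)


def build_auld(
    images: list[np.ndarray] | list[ImageRecord],
    k: int = 2,
    cfg: AugmentationConfig | None = None,
    thresholds: QualityThresholds | None = None,
) -> AuldResult:
    """Full bootstrap: cluster -> filter -> augment, for a list of images.

    The manifest has one row per output sample (source index, variant index,
    quality score, fake-label box). Deterministic for a fixed ``cfg.seed``.
    Raises if no image survives the quality filter, reporting the rejection
    reason per image.
    """
    cfg = cfg or AugmentationConfig()
    th = thresholds or QualityThresholds()
    if len(images) == 0:
        raise ValueError("build_auld needs at least one input image")
    samples: list[MaskedMammogram] = []
    rows = []
    rejections: dict[int, str] = {}
    for idx, item in enumerate(images):
        image = item.pixels if isinstance(item, ImageRecord) else np.asarray(item)
        try:
            mask = kmeans_mask(image, k=k, seed=cfg.seed)
        except ValueError as exc:
            rejections[idx] = str(exc)
            continue
        cand = MaskedMammogram(image=np.asarray(image, dtype=np.float64), mask=mask)
        if not quality_filter(cand, th):
            rejections[idx] = (
                f"quality filter rejected mask (area={mask.mean():.3f}, "
                f"score={cand.quality_score:.3f})"
            )
            continue
        per_image_cfg = AugmentationConfig(
            n_variants=cfg.n_variants,
            label_size_range=cfg.label_size_range,
            label_intensity_quantile=cfg.label_intensity_quantile,
            background_only=cfg.background_only,
            seed=int(np.random.default_rng(np.random.SeedSequence([cfg.seed, idx])).integers(2**31)),
        )
        variants = augment_with_fake_labels(cand, per_image_cfg)
        for vi, variant in enumerate(variants):
            samples.append(variant)
            rows.append(
                {
                    "source_index": idx,
                    "variant_index": vi,
                    "quality_score": cand.quality_score,
                    "label_box": variant.label_box,
                }
            )
    if not samples:
        detail = "; ".join(f"image {i}: {r}" for i, r in rejections.items())
        raise ValueError(f"no masks survived the quality filter ({detail})")
    return AuldResult(samples=samples, manifest=pd.DataFrame(rows), rejections=rejections)
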