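"""Metadata-driven mammogram harmonization.

The steps, in pipeline order: linear rescale (slope/intercept), pixel
inversion when any of the three presentation attributes says stored values
are inverted, percentile windowing, laterality alignment so the breast always
sits at the left border, and spacing-aware resizing that first restores an
isotropic pixel grid before scaling to the model input size. Each applied
step is appended to the record's provenance log.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage.transform import resize as _sk_resize

from .types import DicomMeta, ImageRecord

DEFAULT_TARGET = (512, 512)
DEFAULT_CLIP_PERCENTILES = (0.5, 99.5)


def apply_rescale(pixels: np.ndarray, slope: float, intercept: float) -> np.ndarray:
    """Map stored values to output units: ``out = slope * stored + intercept``."""
    if slope == 0:
        raise ValueError("rescale slope must be non-zero (degenerate transform)")
    return np.asarray(pixels, dtype=np.float64) * slope + intercept


def should_invert(meta: DicomMeta) -> bool:
    """Decide whether stored pixel values are presentation-inverted.

    True iff the intensity relationship sign is +1, the photometric
    interpretation is MONOCHROME1, or the presentation LUT shape is INVERSE.
    """
    if meta.photometric_interpretation not in ("MONOCHROME1", "MONOCHROME2"):
        raise ValueError(
            f"unknown photometric interpretation {meta.photometric_interpretation!r}"
        )
    return (
        meta.pixel_intensity_relationship_sign == 1
        or meta.photometric_interpretation == "MONOCHROME1"
        or meta.presentation_lut_shape == "INVERSE"
    )


def invert_pixels(pixels: np.ndarray) -> np.ndarray:
    """Invert by subtracting each pixel from the image maximum."""
    pixels = np.asarray(pixels)
    if pixels.size == 0:
        raise ValueError("cannot invert an empty array")
    return pixels.max() - pixels


def clip_percentiles(
    pixels: np.ndarray, percentiles: tuple[float, float] = DEFAULT_CLIP_PERCENTILES
) -> np.ndarray:
    """Window intensities to the given percentile range (hot-pixel removal).

    Bounds are order statistics (not interpolated), so windowing an already
    windowed image is a no-op and the whole harmonization chain stays
    idempotent.
    """
    lo = np.percentile(pixels, percentiles[0], method="lower")
    hi = np.percentile(pixels, percentiles[1], method="higher")
    return np.clip(pixels, lo, hi)


def align_laterality(pixels: np.ndarray, laterality: str) -> np.ndarray:
    """Flip columns for right-breast images so the breast sits at the left."""
    if laterality == "L":
        return np.asarray(pixels)
    if laterality == "R":
        return np.asarray(pixels)[:, ::-1]
    raise ValueError(f"laterality must be 'L' or 'R', got {laterality!r}")


def resize_with_spacing(
    pixels: np.ndarray,
    spacing: tuple[float, float],
    target_size: tuple[int, int],
    order: int = 1,
) -> np.ndarray:
    """Resize preserving physical aspect ratio.

    Anisotropic images are first resampled onto an isotropic grid at the
    coarser of the two spacings (physical extents are preserved, no
    upsampling), then scaled to ``target_size``. ``order=0`` gives
    nearest-neighbour interpolation for masks.
    """
    if any(s <= 0 for s in spacing):
        raise ValueError(f"pixel spacing must be positive, got {spacing}")
    if min(target_size) < 8:
        raise ValueError(f"target_size must be at least 8x8, got {target_size}")
    pixels = np.asarray(pixels)
    row_mm, col_mm = spacing
    if row_mm != col_mm:
        iso = max(row_mm, col_mm)
        inter_shape = (
            max(1, int(round(pixels.shape[0] * row_mm / iso))),
            max(1, int(round(pixels.shape[1] * col_mm / iso))),
        )
        pixels = _resize(pixels, inter_shape, order)
    return _resize(pixels, tuple(target_size), order)


def _resize(pixels: np.ndarray, shape: tuple[int, int], order: int) -> np.ndarray:
    if pixels.shape == tuple(shape):
        return pixels
    if order == 0:
        out = _sk_resize(
            pixels.astype(np.float64), shape, order=0, anti_aliasing=False,
            preserve_range=True,
        )
        return out > 0.5 if pixels.dtype == bool else out
    downscaling = shape[0] < pixels.shape[0] or shape[1] < pixels.shape[1]
    return _sk_resize(
        pixels.astype(np.float64), shape, order=order,
        anti_aliasing=downscaling, preserve_range=True,
    )


def preprocess(
    record: ImageRecord,
    target_size: tuple[int, int] = DEFAULT_TARGET,
    clip: tuple[float, float] | None = DEFAULT_CLIP_PERCENTILES,
) -> ImageRecord:
    """Run the full harmonization chain on one record.

    Order: rescale -> inversion decision/application -> percentile windowing
    -> laterality alignment -> spacing-aware resize. The ground-truth mask,
    when present, is carried through the same geometric transforms with
    nearest-neighbour interpolation, and the metadata is rewritten to its
    harmonized form so a second pass is a no-op.
    """
    m = record.meta
    log: list[dict] = list(record.provenance)

    px = apply_rescale(record.pixels, m.rescale_slope, m.rescale_intercept)
    log.append({"step": "rescale", "slope": m.rescale_slope, "intercept": m.rescale_intercept})

    inverted = should_invert(m)
    if inverted:
        px = invert_pixels(px)
    log.append({"step": "invert", "applied": bool(inverted)})

    if clip is not None:
        px = clip_percentiles(px, clip)
        log.append({"step": "clip", "percentiles": list(clip)})

    px = align_laterality(px, m.laterality)
    flipped = m.laterality == "R"
    log.append({"step": "align_laterality", "flipped": flipped})

    px = resize_with_spacing(px, m.pixel_spacing, target_size, order=1)
    log.append({"step": "resize", "spacing": list(m.pixel_spacing), "target": list(target_size)})

    mask = record.mask
    if mask is not None:
        mask = align_laterality(mask, m.laterality)
        mask = resize_with_spacing(mask, m.pixel_spacing, target_size, order=0)
        mask = np.asarray(mask, dtype=bool)

    return ImageRecord(
        pixels=px,
        meta=m.normalized(),
        patient_id=record.patient_id,
        hospital_id=record.hospital_id,
        birads=record.birads,
        artifacts=record.artifacts,
        mask=mask,
        provenance=log,
    )


def warn_missing_optional(meta_dict: dict) -> DicomMeta:
    """Build a DicomMeta from a possibly-partial attribute dict.

    Missing optional attributes default to the non-inverting, non-flipping
    values with a warning; missing laterality is an error because silent
    mis-orientation is bias-critical.
    """
    if "laterality" not in meta_dict:
        raise ValueError("laterality (0020, 0062) is mandatory for harmonization")
    defaults = DicomMeta(laterality=meta_dict["laterality"])
    values = {}
    for name in (
        "rescale_intercept", "rescale_slope", "presentation_lut_shape",
        "pixel_intensity_relationship_sign", "photometric_interpretation",
        "pixel_spacing",
    ):
        if name in meta_dict:
            values[name] = meta_dict[name]
        else:
            values[name] = getattr(defaults, name)
            warnings.warn(f"missing optional DICOM attribute {name}; using default")
    return DicomMeta(laterality=meta_dict["laterality"], **values)
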