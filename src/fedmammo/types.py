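"""Core domain types shared across the toolkit.

A mammogram travels through the pipeline as an :class:`ImageRecord`: the raw
(or progressively harmonized) pixel array together with the DICOM attributes
that drive harmonization decisions, patient/hospital bookkeeping, the BIRADS
assessment label, artifact annotations, and — for synthetic phantoms — the
ground-truth breast mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: DICOM (group, element) codes for the attributes the harmonization uses.
DICOM_CODES = {
    "rescale_intercept": "(0028, 1052)",
    "rescale_slope": "(0028, 1053)",
    "presentation_lut_shape": "(2050, 0020)",
    "pixel_intensity_relationship_sign": "(0028, 1041)",
    "photometric_interpretation": "(0028, 0004)",
    "pixel_spacing": "(0028, 0030)",
    "laterality": "(0020, 0062)",
}


@dataclass
class DicomMeta:
    """The attribute set governing metadata-driven pre-processing.

    Parameters mirror the standard DICOM attributes: the linear rescale
    (slope/intercept), the three presentation attributes that decide whether
    stored values must be inverted so that dense tissue is bright, the pixel
    spacing in millimetres per axis, and the image laterality (which breast).
    """

    rescale_intercept: float = 0.0
    rescale_slope: float = 1.0
    presentation_lut_shape: str = "IDENTITY"
    pixel_intensity_relationship_sign: int = -1
    photometric_interpretation: str = "MONOCHROME2"
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    laterality: str = "L"

    def __post_init__(self) -> None:
        if self.laterality not in ("L", "R"):
            raise ValueError(
                f"laterality {self.laterality!r} is not one of 'L', 'R' "
                f"(DICOM {DICOM_CODES['laterality']})"
            )
        if self.pixel_intensity_relationship_sign not in (-1, 1):
            raise ValueError(
                "pixel intensity relationship sign must be -1 or +1, got "
                f"{self.pixel_intensity_relationship_sign}"
            )
        if any(s <= 0 for s in self.pixel_spacing):
            raise ValueError(f"pixel spacing must be positive, got {self.pixel_spacing}")

    def normalized(self) -> "DicomMeta":
        """Metadata describing an already-harmonized image (no-op on re-run)."""
        return DicomMeta(
            rescale_intercept=0.0,
            rescale_slope=1.0,
            presentation_lut_shape="IDENTITY",
            pixel_intensity_relationship_sign=-1,
            photometric_interpretation="MONOCHROME2",
            pixel_spacing=self.pixel_spacing,
            laterality="L",
        )


@dataclass
class ArtifactFlags:
    """Which artifacts a phantom carries, with their recorded geometry.

    ``label_box`` is ``(row0, col0, row1, col1)`` half-open; clip centres are
    ``(row, col)`` pairs; the implant is ``(row, col, radius)``.
    """

    has_label: bool = False
    label_box: Optional[tuple[int, int, int, int]] = None
    has_clips: bool = False
    clip_centers: list[tuple[int, int]] = field(default_factory=list)
    has_implant: bool = False
    implant: Optional[tuple[int, int, int]] = None
    mis_scan: bool = False

    def any(self) -> bool:
        return self.has_label or self.has_clips or self.has_implant or self.mis_scan


@dataclass
class ImageRecord:
    """One mammogram with its metadata, identity and optional ground truth."""

    pixels: np.ndarray
    meta: DicomMeta
    patient_id: str = ""
    hospital_id: str = ""
    birads: Optional[int] = None
    artifacts: ArtifactFlags = field(default_factory=ArtifactFlags)
    mask: Optional[np.ndarray] = None
    provenance: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.pixels.shape:
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match pixels "
                    f"{self.pixels.shape}"
                )

    def with_pixels(self, pixels: np.ndarray, **changes) -> "ImageRecord":
        """Copy of this record with new pixels (and optionally other fields)."""
        return replace(self, pixels=pixels, **changes)
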