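"""Synthetic phantom mammogram cohorts.

Real multi-hospital mammography data cannot ship with a toolkit, so this
module generates phantoms that reproduce the *properties* the harmonization
pipeline must cope with: a breast-shaped foreground attached to one vertical
border, hospital-specific raw intensity ranges and photometric conventions
(MONOCHROME1 scanners store inverted presentations), printed laterality/view
labels in the background, surgical-clip spots, implant disks, truncated
mis-scans, and an ordinal lesion signal tied to the BIRADS class so that
classifier training has something real to recover.

Every phantom carries its exact ground-truth breast mask, which is what makes
the segmentation and cleaning stages testable end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .types import ArtifactFlags, DicomMeta, ImageRecord

#: Smallest image side that can host the breast blob plus artifacts.
MIN_IMAGE_SIDE = 32


@dataclass
class HospitalProfile:
    """Per-hospital heterogeneity parameters for the generator.

    ``intensity_range`` is the raw stored-pixel range (e.g. a 12-bit scanner
    might use (0, 4095)); ``photometric`` selects whether the hospital stores
    direct (MONOCHROME2) or inverted (MONOCHROME1) presentations; the ``*_prob``
    fields are per-image artifact probabilities; ``spacing_mm`` is the pixel
    spacing written into the DICOM metadata.
    """

    hospital_id: str
    intensity_range: tuple[float, float] = (0.0, 4095.0)
    photometric: str = "MONOCHROME2"
    label_prob: float = 0.0
    clip_prob: float = 0.0
    implant_prob: float = 0.0
    mis_scan_prob: float = 0.0
    spacing_mm: tuple[float, float] = (0.703125, 0.703125)
    label_size_frac: tuple[float, float] = (0.08, 0.18)

    def __post_init__(self) -> None:
        lo, hi = self.intensity_range
        if not lo < hi:
            raise ValueError(f"intensity_range must satisfy low < high, got ({lo}, {hi})")
        if self.photometric not in ("MONOCHROME1", "MONOCHROME2"):
            raise ValueError(f"unknown photometric {self.photometric!r}")
        for name in ("label_prob", "clip_prob", "implant_prob", "mis_scan_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing_mm must be positive, got {self.spacing_mm}")


@dataclass
class PhantomSpec:
    """Geometry and class parameters for one phantom.

    The lesion parameters are tied deterministically to the BIRADS class:
    ``birads - 1`` lesions whose brightness grows with the class, so class
    membership is a learnable image property rather than a random label.
    """

    image_size: tuple[int, int] = (256, 256)
    laterality: str = "L"
    birads: int = 1
    lesion_radius_frac: tuple[float, float] = (0.03, 0.05)
    lesion_brightness: float | None = None  # default: 0.20 + 0.06 * birads
    seed: int = 0

    def __post_init__(self) -> None:
        if self.laterality not in ("L", "R"):
            raise ValueError(f"laterality must be 'L' or 'R', got {self.laterality!r}")
        if not 1 <= self.birads <= 5:
            raise ValueError(f"birads must be in 1..5, got {self.birads}")

    @property
    def lesion_count(self) -> int:
        return self.birads - 1

    @property
    def effective_lesion_brightness(self) -> float:
        if self.lesion_brightness is not None:
            return self.lesion_brightness
        return 0.20 + 0.06 * self.birads


def _smooth_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Zero-mean smooth random field, std ~= 1."""
    noise = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = noise.std()
    return noise / sd if sd > 0 else noise


def _disk(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def generate_phantom(spec: PhantomSpec, profile: HospitalProfile) -> ImageRecord:
    """Render one phantom mammogram with its ground-truth breast mask.

    The breast is a half-ellipse attached to the left border (mirrored for
    laterality ``R``) with multiplicative smooth texture; lesions, clips,
    implants and the printed label are inserted per the phantom parameters and
    the hospital profile, and
    the result is quantized into the hospital's raw intensity range (with
    inverted presentation for MONOCHROME1).
    """
    rows, cols = spec.image_size
    if min(rows, cols) < MIN_IMAGE_SIDE:
        raise ValueError(
            f"image_size {spec.image_size} too small to host the breast blob "
            f"(minimum side {MIN_IMAGE_SIDE})"
        )
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))

    # Breast: half-ellipse attached to column 0, jittered semi-axes/centre.
    cy = rows / 2 + rng.uniform(-0.05, 0.05) * rows
    a = rng.uniform(0.50, 0.62) * cols  # horizontal semi-axis
    b = rng.uniform(0.32, 0.42) * rows  # vertical semi-axis
    rr, cc = np.ogrid[:rows, :cols]
    mask = (cc / a) ** 2 + ((rr - cy) / b) ** 2 <= 1.0

    flags = ArtifactFlags()
    if rng.random() < profile.mis_scan_prob:
        # Truncated scan: the lower part of the breast was cut off.
        cut = int(cy + 0.1 * b)
        mask[cut:, :] = False
        flags.mis_scan = True

    img = np.full((rows, cols), 0.05, dtype=np.float64)
    img += 0.015 * _smooth_noise(rng, (rows, cols), sigma=max(rows, cols) / 32)
    tissue = 0.55 + 0.10 * _smooth_noise(rng, (rows, cols), sigma=max(rows, cols) / 24)
    img[mask] = tissue[mask]

    # Lesions: birads-1 bright round foci inside the breast.
    interior = ndimage.binary_erosion(mask, iterations=max(2, rows // 40))
    int_rows, int_cols = np.nonzero(interior)
    for _ in range(spec.lesion_count):
        if int_rows.size == 0:
            break
        i = rng.integers(int_rows.size)
        r = rng.uniform(*spec.lesion_radius_frac) * min(rows, cols)
        lesion = _disk((rows, cols), (int_rows[i], int_cols[i]), r) & mask
        img[lesion] += spec.effective_lesion_brightness

    if rng.random() < profile.implant_prob:
        if int_rows.size:
            i = rng.integers(int_rows.size)
            r = 0.12 * min(rows, cols)
            disk = _disk((rows, cols), (int_rows[i], int_cols[i]), r) & mask
            img[disk] = 0.95
            flags.has_implant = True
            flags.implant = (int(int_rows[i]), int(int_cols[i]), int(round(r)))

    if rng.random() < profile.clip_prob:
        n_clips = int(rng.integers(2, 6))
        centers = []
        for _ in range(n_clips):
            if int_rows.size == 0:
                break
            i = rng.integers(int_rows.size)
            clip = _disk((rows, cols), (int_rows[i], int_cols[i]), max(1.5, rows / 90)) & mask
            img[clip] = 0.98
            centers.append((int(int_rows[i]), int(int_cols[i])))
        if centers:
            flags.has_clips = True
            flags.clip_centers = centers

    if rng.random() < profile.label_prob:
        box = _place_label(rng, mask, profile.label_size_frac)
        if box is not None:
            r0, c0, r1, c1 = box
            glyph = _label_glyph(rng, (r1 - r0, c1 - c0))
            img[r0:r1, c0:c1] = glyph
            flags.has_label = True
            flags.label_box = box

    img = np.clip(img, 0.0, 1.0)

    if spec.laterality == "R":
        img = img[:, ::-1]
        mask = mask[:, ::-1]
        flags = _flip_flags(flags, cols)

    # Quantize into the hospital's raw range; MONOCHROME1 stores inverted.
    display = img
    if profile.photometric == "MONOCHROME1":
        display = 1.0 - img
    lo, hi = profile.intensity_range
    stored = np.rint(lo + display * (hi - lo)).astype(np.uint16)

    meta = DicomMeta(
        photometric_interpretation=profile.photometric,
        pixel_spacing=profile.spacing_mm,
        laterality=spec.laterality,
    )
    return ImageRecord(
        pixels=stored,
        meta=meta,
        hospital_id=profile.hospital_id,
        birads=spec.birads,
        artifacts=flags,
        mask=mask,
    )


def _place_label(
    rng: np.random.Generator,
    mask: np.ndarray,
    size_frac: tuple[float, float] = (0.08, 0.18),
    max_tries: int = 200,
):
    """Background-only rectangle, rejection-sampled away from the breast."""
    rows, cols = mask.shape
    # keep one pixel of clearance around the breast
    dilated = ndimage.binary_dilation(mask, iterations=1)
    for _ in range(max_tries):
        side = rng.uniform(*size_frac) * min(rows, cols)
        h = max(3, int(side))
        w = max(3, int(side * rng.uniform(1.0, 2.0)))
        if h >= rows or w >= cols:
            continue
        r0 = int(rng.integers(0, rows - h))
        c0 = int(rng.integers(0, cols - w))
        if not dilated[r0 : r0 + h, c0 : c0 + w].any():
            return (r0, c0, r0 + h, c0 + w)
    return None


def _label_glyph(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """High-contrast glyph-like texture: bright field with dark strokes."""
    h, w = shape
    coarse = rng.random((max(2, h // 3), max(2, w // 3))) > 0.35
    glyph = np.where(
        np.kron(coarse, np.ones((3, 3)))[:h, :w] if coarse.size else np.ones(shape),
        0.95,
        0.25,
    )
    if glyph.shape != shape:  # kron may undershoot for tiny boxes
        out = np.full(shape, 0.95)
        out[: glyph.shape[0], : glyph.shape[1]] = glyph
        glyph = out
    return glyph


def _flip_flags(flags: ArtifactFlags, cols: int) -> ArtifactFlags:
    out = ArtifactFlags(
        has_label=flags.has_label,
        has_clips=flags.has_clips,
        has_implant=flags.has_implant,
        mis_scan=flags.mis_scan,
    )
    if flags.label_box is not None:
        r0, c0, r1, c1 = flags.label_box
        out.label_box = (r0, cols - c1, r1, cols - c0)
    out.clip_centers = [(r, cols - 1 - c) for r, c in flags.clip_centers]
    if flags.implant is not None:
        r, c, rad = flags.implant
        out.implant = (r, cols - 1 - c, rad)
    return out


@dataclass
class Cohort:
    """A generated cohort: image records plus their manifest."""

    records: list[ImageRecord]
    manifest: pd.DataFrame


def generate_cohort(
    n_patients: int,
    images_per_patient: int,
    profiles: list[HospitalProfile],
    birads_distribution=(0.3, 0.25, 0.2, 0.15, 0.1),
    seed: int = 0,
    image_size: tuple[int, int] = (128, 128),
) -> Cohort:
    """Generate a patient-structured multi-hospital cohort.

    Every patient belongs to one hospital and carries one BIRADS class shared
    by all of their images; the manifest has one row per image with the
    patient/hospital/label/artifact bookkeeping the cohort-management stage
    consumes.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if images_per_patient < 1:
        raise ValueError("images_per_patient must be >= 1")
    if not profiles:
        raise ValueError("profiles list must not be empty")
    p = np.asarray(birads_distribution, dtype=float)
    if p.shape != (5,) or not math.isclose(p.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("birads_distribution must be 5 probabilities summing to 1")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    records: list[ImageRecord] = []
    rows = []
    for pi in range(n_patients):
        patient_id = f"P{pi:05d}"
        profile = profiles[int(rng.integers(len(profiles)))]
        birads = int(rng.choice(np.arange(1, 6), p=p))
        for ii in range(images_per_patient):
            spec = PhantomSpec(
                image_size=image_size,
                laterality="L" if rng.random() < 0.5 else "R",
                birads=birads,
                seed=int(rng.integers(2**31)),
            )
            rec = generate_phantom(spec, profile)
            rec.patient_id = patient_id
            records.append(rec)
            rows.append(
                {
                    "patient_id": patient_id,
                    "hospital_id": profile.hospital_id,
                    "birads": birads,
                    "implant_flag": rec.artifacts.has_implant,
                    "mis_scan_flag": rec.artifacts.mis_scan,
                    "path": "",
                }
            )
    return Cohort(records=records, manifest=pd.DataFrame(rows))
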