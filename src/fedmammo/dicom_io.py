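"""DICOM reading and writing for the harmonization pipeline.

Only the attribute set the pre-processing actually consumes is required:
rescale slope/intercept, the three presentation attributes deciding pixel
inversion, pixel spacing and image laterality. Files missing a mandatory
attribute fail loudly with the offending (group, element) code, because a
silently-defaulted laterality or photometric interpretation would bias every
downstream model.
"""

from __future__ import annotations

import os

import numpy as np
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

from .types import DICOM_CODES, ArtifactFlags, DicomMeta, ImageRecord

_MANDATORY = {
    "RescaleIntercept": DICOM_CODES["rescale_intercept"],
    "RescaleSlope": DICOM_CODES["rescale_slope"],
    "PresentationLUTShape": DICOM_CODES["presentation_lut_shape"],
    "PixelIntensityRelationshipSign": DICOM_CODES["pixel_intensity_relationship_sign"],
    "PhotometricInterpretation": DICOM_CODES["photometric_interpretation"],
    "PixelSpacing": DICOM_CODES["pixel_spacing"],
    "ImageLaterality": DICOM_CODES["laterality"],
}


class MissingAttributeError(KeyError):
    """A mandatory DICOM attribute is absent from the file."""


def _decimal_string(value: float) -> str:
    """Render a number the way DICOM decimal strings are usually printed."""
    return str(int(value)) if float(value) == int(value) else repr(float(value))


def write_dicom(record: ImageRecord, path: str | os.PathLike) -> None:
    """Write a record as a standard Secondary Capture DICOM file.

    Pixels are stored as unsigned 16-bit; the harmonization attribute set is
    emitted verbatim so that ``read_dicom`` round-trips losslessly.
    """
    pixels = np.asarray(record.pixels)
    if not np.issubdtype(pixels.dtype, np.integer):
        raise ValueError("DICOM writer requires integer pixel data")
    pixels = pixels.astype(np.uint16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "MG"
    ds.PatientID = record.patient_id or "UNKNOWN"
    ds.InstitutionName = record.hospital_id or ""

    m = record.meta
    ds.RescaleIntercept = _decimal_string(m.rescale_intercept)
    ds.RescaleSlope = _decimal_string(m.rescale_slope)
    ds.PresentationLUTShape = m.presentation_lut_shape
    ds.PixelIntensityRelationshipSign = int(m.pixel_intensity_relationship_sign)
    ds.PhotometricInterpretation = m.photometric_interpretation
    ds.PixelSpacing = [_decimal_string(s) for s in m.pixel_spacing]
    ds.ImageLaterality = m.laterality

    ds.Rows, ds.Columns = pixels.shape
    ds.SamplesPerPixel = 1
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = pixels.tobytes()

    if record.birads is not None:
        ds.ImageComments = f"birads={record.birads}"
    ds.save_as(str(path), enforce_file_format=True)


def read_dicom(path: str | os.PathLike) -> ImageRecord:
    """Read a DICOM mammogram, enforcing the harmonization attribute set.

    Raises :class:`MissingAttributeError` naming the DICOM code of the first
    absent mandatory attribute.
    """
    ds = pydicom.dcmread(str(path))
    for keyword, code in _MANDATORY.items():
        if keyword not in ds:
            raise MissingAttributeError(
                f"DICOM file {path} lacks mandatory attribute {code} ({keyword})"
            )

    meta = DicomMeta(
        rescale_intercept=float(ds.RescaleIntercept),
        rescale_slope=float(ds.RescaleSlope),
        presentation_lut_shape=str(ds.PresentationLUTShape),
        pixel_intensity_relationship_sign=int(ds.PixelIntensityRelationshipSign),
        photometric_interpretation=str(ds.PhotometricInterpretation),
        pixel_spacing=(float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1])),
        laterality=str(ds.ImageLaterality),
    )
    birads = None
    comments = getattr(ds, "ImageComments", "")
    if isinstance(comments, str) and comments.startswith("birads="):
        birads = int(comments.split("=", 1)[1])
    return ImageRecord(
        pixels=ds.pixel_array,
        meta=meta,
        patient_id=str(getattr(ds, "PatientID", "")),
        hospital_id=str(getattr(ds, "InstitutionName", "")),
        birads=birads,
        artifacts=ArtifactFlags(),
    )
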