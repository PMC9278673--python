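"""DICOM RT-Image serialization of rendered EPID images.

Pixels are stored as 16-bit unsigned integers with a rescale slope chosen
from the image maximum, so a write/read round trip reproduces the pixel
matrix exactly at the stored precision.
"""

from __future__ import annotations

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .simulate import EPIDImage

__all__ = ["DicomReadError", "write_rtimage", "read_rtimage"]

RT_IMAGE_STORAGE = "1.2.840.10008.5.1.4.1.1.481.1"
_MAX_STORED = 60000


class DicomReadError(ValueError):
    """A mandatory RT-Image attribute is missing; the message names the tag."""


def write_rtimage(image: EPIDImage, path) -> None:
    """Write an :class:`EPIDImage` as a DICOM RT-Image (modality RTIMAGE)."""
    peak = float(image.pixels.max())
    slope = peak / _MAX_STORED if peak > 0 else 1.0
    stored = np.round(image.pixels / slope).astype(np.uint16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = RT_IMAGE_STORAGE
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = RT_IMAGE_STORAGE
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTIMAGE"
    ds.PatientName = "QA^PicketFence"
    ds.PatientID = "PFQA"
    ds.RTImageLabel = image.meta.get("mlc", "PF")
    ds.ImagePlanePixelSpacing = [image.pitch, image.pitch]
    ds.RTImageSID = image.recorded_sdd
    ds.RadiationMachineSAD = image.sad
    # upper-left pixel center in the IEC X/Y receptor frame (at the panel)
    ds.RTImagePosition = [
        -(image.n_cols - 1) / 2.0 * image.pitch,
        (image.n_rows - 1) / 2.0 * image.pitch,
    ]
    ds.BeamLimitingDeviceAngle = image.collimator_angle
    ds.MetersetExposure = image.mu
    ds.Rows, ds.Columns = stored.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = slope
    ds.RescaleIntercept = 0.0
    ds.PixelData = stored.tobytes()
    ds.save_as(path, enforce_file_format=True)


_REQUIRED = (
    "Rows",
    "Columns",
    "ImagePlanePixelSpacing",
    "RTImageSID",
    "RadiationMachineSAD",
    "PixelData",
)


def read_rtimage(path) -> EPIDImage:
    """Read a DICOM RT-Image back into an :class:`EPIDImage`."""
    ds = pydicom.dcmread(path)
    missing = [tag for tag in _REQUIRED if tag not in ds]
    if missing:
        raise DicomReadError(f"missing mandatory RT-Image attribute(s): {missing}")
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    pixels = ds.pixel_array.astype(float) * slope + intercept
    return EPIDImage(
        pixels=pixels,
        pitch=float(ds.ImagePlanePixelSpacing[0]),
        recorded_sdd=float(ds.RTImageSID),
        sad=float(ds.RadiationMachineSAD),
        mu=float(getattr(ds, "MetersetExposure", 100.0)),
        collimator_angle=float(getattr(ds, "BeamLimitingDeviceAngle", 0.0)),
        meta={"mlc": str(getattr(ds, "RTImageLabel", ""))},
    )
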