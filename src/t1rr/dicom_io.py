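"""Reading and writing flip-angle DICOM series.

A scanner export (or the simulator) produces one series per flip angle;
series are identified by SeriesInstanceUID and the FlipAngle tag, slices
by InstanceNumber.  Signal intensities are stored as unsigned 16-bit
integers with a RescaleSlope chosen so the full dynamic range is used.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, MRImageStorage, generate_uid

from .mapping import FlipAngleImage
from .signal_model import AcquisitionParams

__all__ = ["write_flip_angle_series", "read_flip_angle_series"]


def write_flip_angle_series(img: FlipAngleImage, directory,
                            series_description: str | None = None,
                            study_uid: str | None = None,
                            series_number: int = 1,
                            instance_number: int = 1,
                            config_digest: str | None = None) -> Path:
    """Write one image as a single-slice MR DICOM series; returns the file path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    pixels = np.asarray(img.pixels, dtype=float)
    if np.any(pixels < 0):
        raise ValueError("signal intensities must be non-negative")
    peak = float(pixels.max())
    # DS values are capped at 16 chars; fix the slope at 8 significant digits
    slope = float(f"{peak / 60000.0:.8g}") if peak > 0 else 1.0
    stored = np.round(pixels / slope).astype(np.uint16)

    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = MRImageStorage
    file_meta.MediaStorageSOPInstanceUID = generate_uid()
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = file_meta
    ds.SOPClassUID = MRImageStorage
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "MR"
    ds.PatientName = img.series_meta.get("patient_name", "PHANTOM")
    ds.PatientID = img.series_meta.get("patient_id", "T1RR")
    ds.StudyInstanceUID = study_uid or img.series_meta.get("study_uid") or generate_uid()
    ds.SeriesInstanceUID = img.series_meta.get("series_uid") or generate_uid()
    ds.SeriesNumber = series_number
    ds.InstanceNumber = instance_number
    desc = series_description or img.series_meta.get("description") \
        or f"FLASH FA{img.flip_angle:g}"
    ds.SeriesDescription = desc
    if config_digest:
        ds.ImageComments = f"config_digest={config_digest}"

    ds.FlipAngle = img.flip_angle
    ds.RepetitionTime = img.params.tr
    ds.PixelSpacing = [str(s) for s in img.params.pixel_spacing]
    ds.Rows, ds.Columns = img.params.matrix
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = f"{slope:.8g}"
    ds.RescaleIntercept = 0.0
    ds.PixelData = stored.tobytes()

    path = directory / f"fa{img.flip_angle:g}_{instance_number:04d}.dcm"
    ds.save_as(path, enforce_file_format=True)
    return path


def read_flip_angle_series(directory, slice_index: int = 0) -> list[FlipAngleImage]:
    """Read all flip-angle series found under ``directory`` (recursively).

    Files are grouped by (SeriesInstanceUID, FlipAngle); within a group,
    slices are ordered by InstanceNumber and ``slice_index`` selects one.
    Returns one FlipAngleImage per series, sorted by flip angle.
    """
    directory = Path(directory)
    files = sorted(directory.rglob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no DICOM files under {directory}")

    groups: dict[tuple[str, float], list] = {}
    for f in files:
        ds = pydicom.dcmread(f)
        if "FlipAngle" not in ds:
            raise ValueError(f"{f} has no FlipAngle tag")
        key = (str(ds.SeriesInstanceUID), float(ds.FlipAngle))
        groups.setdefault(key, []).append(ds)

    images = []
    for (uid, fa), dss in groups.items():
        dss.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
        if not 0 <= slice_index < len(dss):
            raise IndexError(
                f"slice_index {slice_index} out of range for series {uid} "
                f"({len(dss)} slices)")
        ds = dss[slice_index]
        stored = np.frombuffer(ds.PixelData, dtype=np.uint16).reshape(ds.Rows, ds.Columns)
        pixels = stored * float(getattr(ds, "RescaleSlope", 1.0)) \
            + float(getattr(ds, "RescaleIntercept", 0.0))
        spacing = tuple(float(s) for s in ds.PixelSpacing)
        params = AcquisitionParams(tr=float(ds.RepetitionTime), flip_angles=(fa,),
                                   pixel_spacing=spacing,
                                   matrix=(int(ds.Rows), int(ds.Columns)))
        desc = str(getattr(ds, "SeriesDescription", ""))
        phase = None
        if "pre" in desc.lower():
            phase = "pre"
        elif "post" in desc.lower():
            phase = "post"
        images.append(FlipAngleImage(
            pixels, fa, params,
            {"series_uid": uid, "description": desc, "phase": phase}))
    images.sort(key=lambda im: im.flip_angle)
    return images
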