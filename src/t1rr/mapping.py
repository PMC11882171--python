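"""Pixel-wise T1 and T1-reduction-rate (RR) map generation.

Pipeline: two flip-angle images (same TR, same geometry) are optionally
smoothed, inverted pixel-by-pixel with the closed-form dual-angle fit to a
T1 map, and a pre/post-contrast T1 map pair is combined into the RR map

    RR% = 100 * (T1_pre - T1_post) / T1_pre,

the fraction by which the hepatobiliary contrast agent has shortened T1.
Smoothing conventions, the validity mask, and the DICOM/PNG export
quantization are documented on the individual functions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .signal_model import AcquisitionParams, T1_BOUNDS_MS, fit_t1_dual_angle

__all__ = [
    "GeometryMismatchError",
    "FlipAngleImage",
    "T1Map",
    "RRMap",
    "smooth_image",
    "compute_t1_map",
    "compute_rr_map",
    "export_map",
    "load_parametric_map",
]


class GeometryMismatchError(ValueError):
    """Two images/maps that must share geometry differ in a named attribute."""


@dataclass
class FlipAngleImage:
    """A single signal-intensity image acquired (or simulated) at one flip angle.

    ``series_meta`` carries acquisition identifiers (series UID, pre/post
    label, description); it is informational and never enters computation.
    """

    pixels: np.ndarray
    flip_angle: float
    params: AcquisitionParams
    series_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != self.params.matrix:
            raise ValueError(
                f"pixels shape {self.pixels.shape} != params.matrix {self.params.matrix}")
        if self.flip_angle not in self.params.flip_angles:
            raise ValueError(
                f"flip_angle {self.flip_angle} not among params.flip_angles "
                f"{self.params.flip_angles}")


@dataclass
class T1Map:
    """Pixel-wise T1 (ms) with equilibrium-magnetization map and validity mask."""

    t1: np.ndarray
    m0: np.ndarray
    valid: np.ndarray
    params: AcquisitionParams
    phase_label: str | None = None

    def __post_init__(self) -> None:
        if not (self.t1.shape == self.m0.shape == self.valid.shape):
            raise ValueError("t1, m0 and valid must share a shape")

    @property
    def data(self) -> np.ndarray:
        return self.t1


@dataclass
class RRMap:
    """Pixel-wise T1 reduction rate in percent, with validity mask."""

    rr: np.ndarray
    valid: np.ndarray
    params: AcquisitionParams | None = None

    def __post_init__(self) -> None:
        if self.rr.shape != self.valid.shape:
            raise ValueError("rr and valid must share a shape")

    @property
    def data(self) -> np.ndarray:
        return self.rr


def _kernel(mode: str, size: int) -> np.ndarray:
    if size < 1:
        raise ValueError("kernel size must be >= 1")
    if mode == "box":
        w = np.ones((size, size))
    elif mode == "gaussian":
        # sigma = size/4 px on a size x size support; samples at symmetric
        # (half-integer for even size) offsets around the window center
        sigma = size / 4.0
        off = np.arange(size) - (size - 1) / 2.0
        g = np.exp(-(off ** 2) / (2.0 * sigma ** 2))
        w = np.outer(g, g)
    else:
        raise ValueError(f"unknown smoothing mode {mode!r}")
    return w / w.sum()


def smooth_image(img: FlipAngleImage, mode: str = "gaussian",
                 kernel: int = 4) -> FlipAngleImage:
    """Spatially smooth a flip-angle image with a normalized kernel.

    ``gaussian``: sigma = kernel/4 px on a kernel x kernel support;
    ``box``: uniform kernel x kernel average.  Kernel weights sum to one,
    so constant images are fixed points.  Boundaries use edge replication.
    Even-sized kernels have no central sample; the output pixel is aligned
    with the top-left element of the central 2x2 block (a fixed, documented
    half-pixel convention shared by every map in a run, so it cancels in
    pre/post comparisons).
    """
    w = _kernel(mode, kernel)
    if kernel > min(img.pixels.shape):
        raise ValueError(
            f"kernel {kernel} exceeds image extent {img.pixels.shape}")
    origin = -1 if kernel % 2 == 0 else 0
    out = ndimage.correlate(img.pixels, w, mode="nearest", origin=(origin, origin))
    return FlipAngleImage(out, img.flip_angle, img.params, dict(img.series_meta))


def _check_geometry(a: AcquisitionParams, b: AcquisitionParams) -> None:
    attr = a.geometry_mismatch(b)
    if attr is not None:
        raise GeometryMismatchError(
            f"images differ in {attr}: {getattr(a, attr)} vs {getattr(b, attr)}")


def compute_t1_map(img_low: FlipAngleImage, img_high: FlipAngleImage,
                   smooth: bool = True, smooth_mode: str = "gaussian",
                   kernel: int = 4, phase_label: str | None = None,
                   t1_bounds: tuple[float, float] = T1_BOUNDS_MS) -> T1Map:
    """Invert a dual-flip-angle image pair to a pixel-wise T1 map.

    Smoothing (when enabled) is applied to the signal-intensity images
    before inversion, not to the T1 map.  Pixels whose inversion is
    undefined or falls outside ``t1_bounds`` are masked invalid.
    """
    _check_geometry(img_low.params, img_high.params)
    if img_low.flip_angle == img_high.flip_angle:
        raise ValueError("the two images must be acquired at distinct flip angles")
    a, b = img_low, img_high
    if smooth:
        a = smooth_image(a, mode=smooth_mode, kernel=kernel)
        b = smooth_image(b, mode=smooth_mode, kernel=kernel)
    fit = fit_t1_dual_angle(a.pixels, b.pixels, a.flip_angle, b.flip_angle,
                            a.params.tr, t1_bounds=t1_bounds)
    params = AcquisitionParams(
        tr=img_low.params.tr,
        flip_angles=(img_low.flip_angle, img_high.flip_angle),
        pixel_spacing=img_low.params.pixel_spacing,
        matrix=img_low.params.matrix)
    if phase_label is None:
        phase_label = img_low.series_meta.get("phase")
    return T1Map(fit.t1, fit.m0, fit.valid, params, phase_label)


def compute_rr_map(pre: T1Map, post: T1Map) -> RRMap:
    """T1 reduction rate map: RR% = 100 (T1_pre - T1_post) / T1_pre.

    Valid where both input maps are valid and T1_pre > 0.
    """
    _check_geometry(pre.params, post.params)
    valid = pre.valid & post.valid & (pre.t1 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rr = np.where(valid, 100.0 * (pre.t1 - post.t1) / pre.t1, np.nan)
    return RRMap(rr, valid, params=pre.params)


# --- export ---------------------------------------------------------------
# Stored-integer encodings: value = stored * RescaleSlope + RescaleIntercept.
# T1 maps: unsigned 16-bit, slope 0.1 -> 0.05 ms quantization, padding 65535.
# RR maps: signed 16-bit, slope 0.01 -> 0.005 % quantization, padding -32768.

_ENCODINGS = {
    "t1": dict(slope=0.1, signed=False, padding=65535, window=(0.0, 2000.0),
               units="ms", description="T1 map (ms)"),
    "rr": dict(slope=0.01, signed=True, padding=-32768, window=(0.0, 100.0),
               units="%", description="T1RR map (%)"),
}


def _secondary_capture_dataset(stored: np.ndarray, enc: dict, meta: dict):
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    file_meta.MediaStorageSOPInstanceUID = generate_uid()
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = Dataset()
    ds.file_meta = file_meta
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.PatientName = meta.get("patient_name", "PHANTOM")
    ds.PatientID = meta.get("patient_id", "T1RR")
    ds.StudyInstanceUID = meta.get("study_uid") or generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.SeriesDescription = enc["description"]
    ds.ImageComments = json.dumps(meta.get("comments", {}))
    ds.Rows, ds.Columns = stored.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 1 if enc["signed"] else 0
    ds.RescaleSlope = enc["slope"]
    ds.RescaleIntercept = 0
    ds.RescaleType = enc["units"]
    ds.PixelPaddingValue = enc["padding"]
    if "pixel_spacing" in meta:
        ds.PixelSpacing = [str(s) for s in meta["pixel_spacing"]]
    ds.PixelData = stored.tobytes()
    return ds


def export_map(m: T1Map | RRMap, path, config_digest: str | None = None) -> list[Path]:
    """Write a parametric map as DICOM (quantized, with rescale) plus a PNG.

    ``path`` is the output base name; ``<path>.dcm`` and ``<path>.png`` are
    written.  The DICOM stores integers that decode through
    RescaleSlope/Intercept to ms (T1) or percent (RR); invalid pixels are
    stored as the declared PixelPaddingValue.  The PNG is an 8-bit
    colorimetric rendering (viridis) with a fixed display window
    (T1: 0-2000 ms, RR: 0-100 %); invalid pixels render black.
    """
    kind = "t1" if isinstance(m, T1Map) else "rr"
    enc = _ENCODINGS[kind]
    values = m.data
    dtype = np.int16 if enc["signed"] else np.uint16
    stored = np.full(values.shape, enc["padding"], dtype=dtype)
    ok = m.valid & np.isfinite(values)
    stored[ok] = np.round(values[ok] / enc["slope"]).astype(dtype)

    base = Path(path)
    if base.suffix in {".dcm", ".png"}:
        base = base.with_suffix("")
    base.parent.mkdir(parents=True, exist_ok=True)

    comments = {"map": kind}
    if config_digest:
        comments["config_digest"] = config_digest
    meta = {"comments": comments}
    if getattr(m, "params", None) is not None:
        meta["pixel_spacing"] = m.params.pixel_spacing
    ds = _secondary_capture_dataset(stored, enc, meta)
    dcm_path = base.with_suffix(".dcm")
    ds.save_as(dcm_path, enforce_file_format=True)

    png_path = base.with_suffix(".png")
    _write_png(values, ok, enc, png_path, comments)
    return [dcm_path, png_path]


def _write_png(values, ok, enc, png_path, comments) -> None:
    import matplotlib
    matplotlib.use("Agg", force=False)
    from matplotlib import image as mimage
    from matplotlib import colormaps

    shown = np.where(ok, values, np.nan)
    cmap = colormaps["viridis"].copy()
    cmap.set_bad("black")
    lo, hi = enc["window"]
    mimage.imsave(png_path, shown, cmap=cmap, vmin=lo, vmax=hi,
                  metadata={"Description": json.dumps(comments)})


def load_parametric_map(path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Read back an exported DICOM map: (values, valid mask, metadata)."""
    import pydicom

    ds = pydicom.dcmread(path)
    stored = np.frombuffer(ds.PixelData, dtype=np.int16 if ds.PixelRepresentation else np.uint16)
    stored = stored.reshape(ds.Rows, ds.Columns)
    valid = stored != ds.PixelPaddingValue
    values = np.where(valid, stored * float(ds.RescaleSlope) + float(ds.RescaleIntercept), np.nan)
    try:
        meta = json.loads(getattr(ds, "ImageComments", "") or "{}")
    except json.JSONDecodeError:
        meta = {}
    meta.setdefault("units", getattr(ds, "RescaleType", None))
    return values, valid, meta
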