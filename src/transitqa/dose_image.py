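"""2D dose-plane data model and I/O.

A :class:`DoseImage` is the unit of exchange between the simulator, the gamma
engine and the pipeline: a rectangular grid of absorbed dose with physical
pixel pitch and the physical coordinate of the first pixel center.

Coordinate convention (fixed across the package): row-major grid, physical
coordinates are pixel centers, ``y`` increases with row index and ``x`` with
column index, all distances in millimetres.

Two on-disk formats are supported: a minimal single-plane DICOM RT Dose
(DoseUnits GY, dose-grid scaling applied on read) and a diffable plain-text
grid with a three-line header (``spacing``, ``origin``, ``unit``).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "DoseImage",
    "DoseImageError",
    "FormatError",
    "read_dose_plane",
    "write_dose_plane",
    "resample_to",
]

_RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"


class DoseImageError(ValueError):
    """Invalid dose image or incompatible pair of images."""


class FormatError(DoseImageError):
    """File does not conform to the expected dose-plane format."""


@dataclass
class DoseImage:
    """A 2D absorbed-dose distribution with physical geometry.

    Parameters
    ----------
    values
        ``(n_rows, n_cols)`` array of dose, finite and non-negative.
    spacing
        ``(row_mm, col_mm)`` pixel pitch at the image plane.
    origin
        ``(y_mm, x_mm)`` physical coordinate of the first pixel center.
    unit_label
        Free-text dose unit (``"Gy"`` or arbitrary consistent units).
    mask
        Optional validity mask (True = valid); produced by resampling when
        target points fall outside the source extent.
    """

    values: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    origin: tuple[float, float] = (0.0, 0.0)
    unit_label: str = "Gy"
    mask: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DoseImageError("dose grid must be 2D")
        if self.values.shape[0] < 2 or self.values.shape[1] < 2:
            raise DoseImageError("dose grid must be at least 2x2")
        if not np.all(np.isfinite(self.values)):
            raise DoseImageError("dose values must be finite")
        if np.any(self.values < 0):
            raise DoseImageError("dose values must be non-negative")
        self.spacing = (float(self.spacing[0]), float(self.spacing[1]))
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise DoseImageError("spacing components must be positive")
        self.origin = (float(self.origin[0]), float(self.origin[1]))
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise DoseImageError("mask shape must match dose grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def y_coords(self) -> np.ndarray:
        """Physical y (mm) of each row center."""
        return self.origin[0] + np.arange(self.shape[0]) * self.spacing[0]

    def x_coords(self) -> np.ndarray:
        """Physical x (mm) of each column center."""
        return self.origin[1] + np.arange(self.shape[1]) * self.spacing[1]

    def extent(self) -> tuple[float, float, float, float]:
        """(y_min, y_max, x_min, x_max) of pixel centers, mm."""
        y, x = self.y_coords(), self.x_coords()
        return y[0], y[-1], x[0], x[-1]

    def copy(self) -> "DoseImage":
        return replace(
            self,
            values=self.values.copy(),
            mask=None if self.mask is None else self.mask.copy(),
        )


# ---------------------------------------------------------------------------
# plain-text grid format
# ---------------------------------------------------------------------------

def _write_text(img: DoseImage, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"spacing {img.spacing[0]!r} {img.spacing[1]!r}\n")
        fh.write(f"origin {img.origin[0]!r} {img.origin[1]!r}\n")
        fh.write(f"unit {img.unit_label}\n")
        np.savetxt(fh, img.values, fmt="%.10g")


def _read_text(path: str) -> DoseImage:
    with open(path) as fh:
        header = {}
        for _ in range(3):
            line = fh.readline()
            if not line:
                raise FormatError(f"{path}: truncated header")
            key, _, rest = line.partition(" ")
            header[key.strip()] = rest.strip()
        if "spacing" not in header or "origin" not in header:
            raise FormatError(f"{path}: missing spacing/origin header lines")
        try:
            spacing = tuple(float(v) for v in header["spacing"].split())
            origin = tuple(float(v) for v in header["origin"].split())
        except ValueError as exc:
            raise FormatError(f"{path}: bad header values") from exc
        values = np.loadtxt(fh, ndmin=2)
    return DoseImage(values, spacing, origin, header.get("unit", "Gy"))


# ---------------------------------------------------------------------------
# minimal single-plane DICOM RT Dose
# ---------------------------------------------------------------------------

def _write_dicom(img: DoseImage, path: str) -> None:
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = _RTDOSE_SOP_CLASS
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(path, {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = _RTDOSE_SOP_CLASS
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "RTDOSE"
    ds.PatientName = "transitqa"
    ds.PatientID = "transitqa"
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.Rows, ds.Columns = img.shape
    ds.PixelSpacing = [img.spacing[0], img.spacing[1]]
    # DICOM ImagePositionPatient is (x, y, z); package origin is (y, x).
    ds.ImagePositionPatient = [img.origin[1], img.origin[0], 0.0]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]

    vmax = float(img.values.max())
    # 32-bit quantization: relative error < 1e-9 of max, well inside contract
    scaling = vmax / (2**32 - 1) if vmax > 0 else 1.0
    ds.DoseGridScaling = scaling
    pixels = np.round(img.values / scaling).astype(np.uint32)
    ds.PixelData = pixels.tobytes()
    pydicom.dcmwrite(path, ds, little_endian=True, implicit_vr=False)


def _read_dicom(path: str, frame: int | None = None) -> DoseImage:
    import pydicom

    ds = pydicom.dcmread(path)
    if "DoseGridScaling" not in ds:
        raise FormatError(f"{path}: missing DoseGridScaling")
    if "PixelSpacing" not in ds:
        raise FormatError(f"{path}: missing PixelSpacing")
    arr = ds.pixel_array
    if arr.ndim == 3:
        if frame is None:
            raise DoseImageError(
                f"{path}: multi-frame RT Dose requires an explicit frame index"
            )
        arr = arr[frame]
    values = arr.astype(float) * float(ds.DoseGridScaling)
    spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    ipp = getattr(ds, "ImagePositionPatient", [0.0, 0.0, 0.0])
    origin = (float(ipp[1]), float(ipp[0]))
    unit = str(getattr(ds, "DoseUnits", "GY")).capitalize()
    return DoseImage(values, spacing, origin, unit)


# ---------------------------------------------------------------------------
# public I/O and resampling
# ---------------------------------------------------------------------------

def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    return "dicom-rtdose" if os.fspath(path).lower().endswith(".dcm") else "text-grid"


def read_dose_plane(path: str, format: str | None = None, frame: int | None = None) -> DoseImage:
    """Read a 2D dose plane from ``text-grid`` or single-plane ``dicom-rtdose``."""
    fmt = _infer_format(path, format)
    if fmt == "text-grid":
        return _read_text(path)
    if fmt == "dicom-rtdose":
        return _read_dicom(path, frame=frame)
    raise ValueError(f"unknown dose-plane format {fmt!r}")


def write_dose_plane(img: DoseImage, path: str, format: str | None = None) -> None:
    """Write a dose plane; round-trips with :func:`read_dose_plane` to <1e-6 relative."""
    fmt = _infer_format(path, format)
    if fmt == "text-grid":
        _write_text(img, path)
    elif fmt == "dicom-rtdose":
        _write_dicom(img, path)
    else:
        raise ValueError(f"unknown dose-plane format {fmt!r}")


def resample_to(img: DoseImage, target: DoseImage) -> DoseImage:
    """Bilinearly resample ``img`` onto ``target``'s grid (physical coordinates).

    Target points outside ``img``'s extent are set to zero and flagged invalid
    in the returned image's ``mask``. Raises :class:`DoseImageError` when the
    physical extents do not overlap at all.
    """
    ylo, yhi, xlo, xhi = img.extent()
    tylo, tyhi, txlo, txhi = target.extent()
    if tyhi < ylo or tylo > yhi or txhi < xlo or txlo > xhi:
        raise DoseImageError("image extents do not overlap")

    interp = RegularGridInterpolator(
        (img.y_coords(), img.x_coords()),
        img.values,
        method="linear",
        bounds_error=False,
        fill_value=0.0,
    )
    ty, tx = np.meshgrid(target.y_coords(), target.x_coords(), indexing="ij")
    pts = np.stack([ty.ravel(), tx.ravel()], axis=1)
    vals = interp(pts).reshape(target.shape)
    inside = (
        (ty >= ylo) & (ty <= yhi) & (tx >= xlo) & (tx <= xhi)
    )
    vals[~inside] = 0.0
    return DoseImage(vals, target.spacing, target.origin, img.unit_label, mask=inside)
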