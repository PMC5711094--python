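"""Readers and writers for the plane formats the pipeline touches.

Supported formats:

``csv-grid``
    Package-native plain-text grid. Two mandatory header lines carrying the
    pixel spacing and origin, an optional quantity line, then comma-separated
    rows of values::

        # spacing_mm: 0.25,0.25
        # origin_mm: -10.0,-10.0
        # quantity: dose
        0.1,0.2,...

    Values are written with ``repr``-level precision so a write/read
    round-trip is bit-exact.

``tiff-16bit``
    16-bit-per-channel (grayscale or 48-bit RGB) TIFF, as produced by film
    scanners. Pixel spacing comes from the resolution tags; a missing or
    zero resolution is an error, never a silent default. RGB scans are
    returned as one plane per channel.

``dicom-rt-dose``
    Single-plane DICOM RT Dose (read-only; requires the optional
    ``pydicom`` dependency).
"""

from __future__ import annotations

import os
from typing import Literal

import numpy as np

from .grid import DosePlane

__all__ = ["read_plane", "write_plane", "FormatError"]

PlaneFormat = Literal["csv-grid", "dicom-rt-dose", "tiff-16bit"]


class FormatError(ValueError):
    """A file does not parse under the named standard."""


# ---------------------------------------------------------------------------
# csv-grid


def _read_csv_grid(path: str) -> DosePlane:
    with open(path) as fh:
        lines = fh.read().splitlines()
    header: dict[str, str] = {}
    body_start = 0
    for i, line in enumerate(lines):
        if not line.startswith("#"):
            body_start = i
            break
        key, _, value = line.lstrip("# ").partition(":")
        header[key.strip()] = value.strip()
    else:
        raise FormatError(f"{path}: no data rows")
    if "spacing_mm" not in header:
        raise FormatError(f"{path}: missing 'spacing_mm' header")
    if "origin_mm" not in header:
        raise FormatError(f"{path}: missing 'origin_mm' header")
    try:
        spacing = tuple(float(v) for v in header["spacing_mm"].split(","))
        origin = tuple(float(v) for v in header["origin_mm"].split(","))
        values = np.array(
            [[float(v) for v in line.split(",")] for line in lines[body_start:] if line],
            dtype=float,
        )
    except ValueError as exc:
        raise FormatError(f"{path}: malformed csv-grid: {exc}") from exc
    if len(spacing) != 2 or len(origin) != 2:
        raise FormatError(f"{path}: spacing/origin must have two components")
    quantity = header.get("quantity", "dose")
    return DosePlane(values, spacing, origin, quantity)


def _write_csv_grid(plane: DosePlane, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# spacing_mm: {plane.spacing[0]!r},{plane.spacing[1]!r}\n")
        fh.write(f"# origin_mm: {plane.origin[0]!r},{plane.origin[1]!r}\n")
        fh.write(f"# quantity: {plane.quantity}\n")
        for row in plane.values:
            fh.write(",".join(repr(float(v)) for v in row) + "\n")


# ---------------------------------------------------------------------------
# tiff


def _read_tiff(path: str) -> DosePlane | dict[str, DosePlane]:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        tags = page.tags
        xres = tags.get("XResolution")
        yres = tags.get("YResolution")
        unit = tags.get("ResolutionUnit")
    if xres is None or yres is None:
        raise FormatError(f"{path}: TIFF has no resolution tags; spacing unknown")

    def _to_mm_per_px(res) -> float:
        num, den = res.value
        if num == 0:
            raise FormatError(f"{path}: zero resolution tag")
        dots_per_unit = num / den
        unit_mm = 25.4  # inch
        if unit is not None and unit.value == 3:  # centimetre
            unit_mm = 10.0
        return unit_mm / dots_per_unit

    spacing = (_to_mm_per_px(yres), _to_mm_per_px(xres))
    data = np.asarray(data)
    if data.ndim == 2:
        return DosePlane(data.astype(float), spacing, (0.0, 0.0), "reading")
    if data.ndim == 3 and data.shape[2] == 3:
        return {
            channel: DosePlane(data[:, :, c].astype(float), spacing, (0.0, 0.0), "reading")
            for c, channel in enumerate("RGB")
        }
    raise FormatError(f"{path}: unsupported TIFF layout with shape {data.shape}")


def write_rgb_tiff(path: str, rgb: np.ndarray, dpi: float) -> None:
    """Write a 48-bit RGB TIFF (16 bits per channel) with resolution tags."""
    import tifffile

    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected (H, W, 3) array, got shape {rgb.shape}")
    if rgb.dtype != np.uint16:
        rgb = np.clip(np.round(rgb), 0, 2**16 - 1).astype(np.uint16)
    tifffile.imwrite(path, rgb, resolution=(dpi, dpi), resolutionunit="INCH")


# ---------------------------------------------------------------------------
# dicom


def _read_dicom_rt_dose(path: str) -> DosePlane:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError(
            "reading dicom-rt-dose requires the optional 'pydicom' dependency "
            "(pip install linacqa[dicom])"
        ) from exc

    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise FormatError(f"{path}: not an RT Dose object (Modality={getattr(ds, 'Modality', None)})")
    if "PixelSpacing" not in ds:
        raise FormatError(f"{path}: RT Dose missing PixelSpacing")
    arr = ds.pixel_array
    if arr.ndim == 3:  # multi-frame: take the single plane only
        if arr.shape[0] != 1:
            raise FormatError(f"{path}: multi-frame RT Dose not supported ({arr.shape[0]} frames)")
        arr = arr[0]
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    spacing = (float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1]))
    ipp = getattr(ds, "ImagePositionPatient", [0.0, 0.0, 0.0])
    origin = (float(ipp[1]), float(ipp[0]))
    return DosePlane(arr.astype(float) * scaling, spacing, origin, "dose")


# ---------------------------------------------------------------------------
# public API


def read_plane(path: str | os.PathLike, format: PlaneFormat) -> DosePlane | dict[str, DosePlane]:
    """Read a plane from ``path``.

    Returns a single :class:`~linacqa.grid.DosePlane`, except for RGB TIFF
    scans which return a dict ``{"R": plane, "G": plane, "B": plane}`` with
    one 16-bit plane per colour channel.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "csv-grid":
        return _read_csv_grid(path)
    if format == "tiff-16bit":
        return _read_tiff(path)
    if format == "dicom-rt-dose":
        return _read_dicom_rt_dose(path)
    raise FormatError(f"unsupported format {format!r}")


def write_plane(plane: DosePlane, path: str | os.PathLike, format: PlaneFormat = "csv-grid") -> None:
    """Write a plane. Only ``csv-grid`` output is supported."""
    if format != "csv-grid":
        raise FormatError(f"writing format {format!r} is not supported")
    _write_csv_grid(plane, os.fspath(path))
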