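"""Readers and writers for the standard formats around the projectors.

CT input: single-series DICOM directories (slices ordered by position along
the slice normal, rescale tags applied to reach HU) or 3D NIfTI files
(reoriented to the package's ``(z, y, x)`` convention).  DRR output: 16-bit
grayscale PNG for display-domain images, or 2D NIfTI for raw values.  Label
and rating tables are plain CSV with a header.
"""

from __future__ import annotations

from pathlib import Path
from typing import Tuple

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom
from PIL import Image

from .core import (
    AmbiguousSeriesError,
    CTVolume,
    DataError,
    DimensionalityError,
    DomainError,
    DRRImage,
    MetadataError,
    validate_volume,
)

__all__ = [
    "read_dicom_series",
    "read_nifti",
    "write_nifti",
    "write_drr",
    "read_label_csv",
    "read_rating_csv",
]


def read_dicom_series(directory) -> CTVolume:
    """Read one CT series from a directory of DICOM slice files.

    Slices are sorted by the projection of ImagePositionPatient onto the slice
    normal (robust against renumbered instances); RescaleSlope/Intercept are
    applied so the volume is in HU.  Raises :class:`AmbiguousSeriesError` when
    the directory holds more than one SeriesInstanceUID and
    :class:`MetadataError` when rescale or geometry tags are missing.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    slices = []
    for path in sorted(directory.iterdir()):
        if not path.is_file():
            continue
        try:
            ds = pydicom.dcmread(path)
        except Exception:
            continue  # skip non-DICOM files
        slices.append(ds)
    if not slices:
        raise DataError(f"no DICOM slices found in {directory}")

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in slices}
    if len(uids) != 1:
        raise AmbiguousSeriesError(f"directory holds {len(uids)} series, expected one")

    first = slices[0]
    for tag in ("RescaleSlope", "RescaleIntercept", "ImagePositionPatient",
                "ImageOrientationPatient", "PixelSpacing"):
        if tag not in first:
            raise MetadataError(f"missing required DICOM tag {tag}")

    orientation = np.asarray(first.ImageOrientationPatient, dtype=float)
    normal = np.cross(orientation[:3], orientation[3:])
    positions = np.array([np.dot(ds.ImagePositionPatient, normal) for ds in slices])
    order = np.argsort(positions)
    slices = [slices[i] for i in order]
    positions = positions[order]

    if len(slices) > 1:
        gaps = np.diff(positions)
        slice_spacing = float(np.median(gaps))
        if slice_spacing <= 0 or not np.allclose(gaps, slice_spacing, rtol=1e-3, atol=1e-3):
            raise MetadataError("inconsistent slice spacing along the series normal")
    else:
        slice_spacing = float(getattr(first, "SliceThickness", 1.0))

    row_spacing, col_spacing = (float(v) for v in first.PixelSpacing)
    data = np.stack(
        [
            float(ds.RescaleSlope) * ds.pixel_array.astype(float) + float(ds.RescaleIntercept)
            for ds in slices
        ]
    )
    origin = (float(positions[0]), 0.0, 0.0)
    return validate_volume(
        CTVolume(data=data, spacing=(slice_spacing, row_spacing, col_spacing), origin=origin)
    )


def read_nifti(path) -> CTVolume:
    """Read a 3D NIfTI volume, reoriented to the ``(z, y, x)`` axis order.

    NIfTI stores data ``(x, y, z)``-fastest; the array is transposed and the
    header zooms reversed accordingly.  Raises :class:`DimensionalityError`
    for non-3D files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    if img.ndim != 3:
        raise DimensionalityError(f"expected a 3D NIfTI, got {img.ndim}D")
    data = np.asarray(img.dataobj, dtype=float).transpose(2, 1, 0)
    zooms = img.header.get_zooms()[:3]
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return validate_volume(CTVolume(data=data, spacing=spacing))


def write_nifti(volume: CTVolume, path) -> None:
    """Write a volume as 3D NIfTI (inverse of :func:`read_nifti`)."""
    dz, dy, dx = volume.spacing
    affine = np.diag([dx, dy, dz, 1.0])
    img = nib.Nifti1Image(volume.data.transpose(2, 1, 0), affine)
    img.header.set_zooms((dx, dy, dz))
    nib.save(img, str(path))


def write_drr(image: DRRImage, path, format: str = "png16") -> None:
    """Write a DRR to disk.

    ``png16`` requires a display-domain image and scales [0, 1] linearly to
    the full uint16 range; ``nifti2d`` stores the raw float values of any
    domain together with the pixel spacing.
    """
    path = Path(path)
    if format == "png16":
        if image.domain != "display":
            raise DomainError(
                "png16 export requires a display-domain image; run intensity_to_display first"
            )
        data = np.asarray(image.data, dtype=float)
        if data.min() < 0.0 or data.max() > 1.0:
            raise DataError("display-domain values must lie in [0, 1]")
        scaled = np.round(data * 65535.0).astype(np.uint16)
        Image.fromarray(scaled).save(path)
    elif format == "nifti2d":
        dv, du = image.pixel_spacing
        img = nib.Nifti1Image(np.asarray(image.data, dtype=np.float64).T, np.diag([du, dv, 1.0, 1.0]))
        img.header.set_zooms((du, dv))
        nib.save(img, str(path))
    else:
        raise DataError(f"unknown DRR output format {format!r}")


def read_drr_nifti(path) -> DRRImage:
    """Read back a 2D NIfTI written by :func:`write_drr` (raw values)."""
    img = nib.load(str(path))
    if img.ndim != 2:
        raise DimensionalityError(f"expected a 2D NIfTI, got {img.ndim}D")
    zooms = img.header.get_zooms()[:2]
    return DRRImage(
        data=np.asarray(img.dataobj, dtype=float).T,
        pixel_spacing=(float(zooms[1]), float(zooms[0])),
        domain="line_integral",
    )


def read_label_csv(path) -> pd.DataFrame:
    """Read a case/label table: columns ``case_id`` and ``label`` (binary).

    Raises :class:`KeyError` on duplicate case ids and :class:`DataError`
    on labels outside {0, 1}.
    """
    frame = pd.read_csv(path)
    if not {"case_id", "label"}.issubset(frame.columns):
        raise DataError("label CSV needs 'case_id' and 'label' columns")
    if frame["case_id"].duplicated().any():
        dupes = frame.loc[frame["case_id"].duplicated(), "case_id"].tolist()
        raise KeyError(f"duplicate case ids: {dupes}")
    if not frame["label"].isin([0, 1]).all():
        raise DataError("labels must be 0 or 1")
    frame["label"] = frame["label"].astype(int)
    return frame


def read_rating_csv(path) -> pd.DataFrame:
    """Read a cases × raters table of 6-point Likert ratings.

    Every non-missing rating must be an integer in 1..6; missing cells stay
    missing (NaN), never silently 0.  The first column is the case id (index).
    """
    frame = pd.read_csv(path, index_col=0)
    if frame.index.duplicated().any():
        raise KeyError(f"duplicate case ids: {frame.index[frame.index.duplicated()].tolist()}")
    values = frame.to_numpy(dtype=float)
    present = ~np.isnan(values)
    ok = (values[present] >= 1) & (values[present] <= 6) & (values[present] % 1 == 0)
    if not np.all(ok):
        bad = sorted(set(values[present][~ok].tolist()))
        raise DataError(f"ratings must be integers in 1..6; found {bad}")
    return frame
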