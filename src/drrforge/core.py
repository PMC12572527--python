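"""Domain types and coordinate conventions shared by every drrforge module.

Conventions
-----------
Axis order of every CT volume is ``(z, y, x)``:

* ``z`` — cranio-caudal (axial slice index, head at index 0 by convention),
* ``y`` — antero-posterior (the posteroanterior beam integrates along this axis),
* ``x`` — left-right.

Voxel coordinates are 0-based and refer to voxel *centers*; the world position
of voxel ``(i, j, k)`` is ``origin + index * spacing`` (mm).  The volume's
bounding box extends half a voxel beyond the outermost centers.

Hounsfield units are floored at ``HU_FLOOR`` (−1024), the scanner convention
for air, which also guarantees non-negative attenuation coefficients
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Optional, Tuple

import numpy as np

HU_FLOOR: float = -1024.0
HU_AIR: float = -1000.0
HU_WATER: float = 0.0

Domain = Literal["line_integral", "intensity", "display"]
Technique = Literal["beer_lambert", "softmip", "wedge", "point_source", "mip", "mean"]

TECHNIQUES: tuple[str, ...] = ("beer_lambert", "softmip", "wedge", "point_source", "mip", "mean")

# Material labels used by attenuation.material_decompose
MATERIAL_AIR = 0
MATERIAL_SOFT_TISSUE = 1
MATERIAL_BONE = 2


class DrrForgeError(Exception):
    """Base class for all drrforge errors."""


class DimensionalityError(DrrForgeError, ValueError):
    """An array does not have the expected number of dimensions."""


class DataError(DrrForgeError, ValueError):
    """Voxel or pixel data violates a contract (NaN/Inf, bad spacing, ...)."""


class DomainError(DrrForgeError, ValueError):
    """A DRR image is in the wrong domain for the requested operation."""


class GeometryError(DrrForgeError, ValueError):
    """Invalid projection geometry (zero direction, source inside volume, ...)."""


class DegenerateWeightsError(DrrForgeError, ValueError):
    """Every weight along a ray is zero; the weighted mean is undefined."""


class MetadataError(DrrForgeError, ValueError):
    """Required file metadata is missing or inconsistent."""


class AmbiguousSeriesError(MetadataError):
    """A DICOM directory contains more than one series."""


class PhantomSpecError(DrrForgeError, ValueError):
    """A phantom specification is geometrically inconsistent."""


class DegenerateLabelsError(DrrForgeError, ValueError):
    """A label vector contains only one class; ROC analysis is undefined."""


@dataclass(frozen=True)
class CTVolume:
    """A 3D CT volume in Hounsfield units with ``(z, y, x)`` axis order.

    Parameters
    ----------
    data
        3D float array of HU values, axis order ``(z, y, x)``.
    spacing
        Voxel spacing ``(dz, dy, dx)`` in mm, all strictly positive.
    origin
        World position (mm) of the center of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_labels: Tuple[str, str, str] = ("z", "y", "x")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical edge lengths (mm) of the volume bounding box, per axis."""
        return np.asarray(self.shape, dtype=float) * np.asarray(self.spacing, dtype=float)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """World-space bounding box ``(lo, hi)`` including the half-voxel margin."""
        origin = np.asarray(self.origin, dtype=float)
        spacing = np.asarray(self.spacing, dtype=float)
        shape = np.asarray(self.shape, dtype=float)
        lo = origin - 0.5 * spacing
        hi = origin + (shape - 0.5) * spacing
        return lo, hi

    def center(self) -> np.ndarray:
        """World-space center of the bounding box (mm)."""
        lo, hi = self.bounds()
        return 0.5 * (lo + hi)


@dataclass(frozen=True)
class DRRImage:
    """A 2D digitally reconstructed radiograph.

    ``domain`` tags the physical meaning of the pixel values:

    * ``line_integral`` — non-negative attenuation-like values (a Beer–Lambert
      line integral, or a weighted HU mean shifted to a non-negative scale);
    * ``intensity`` — transmitted intensity in ``[0, i0]``;
    * ``display`` — presentation values in ``[0, 1]``.

    A parallel PA projection of a ``(Z, Y, X)`` volume has shape ``(Z, X)``.
    """

    data: np.ndarray
    pixel_spacing: Tuple[float, float] = (1.0, 1.0)
    domain: Domain = "intensity"
    technique: str = "beer_lambert"
    i0: float = 1.0

    def __post_init__(self) -> None:
        if np.asarray(self.data).ndim != 2:
            raise DimensionalityError(
                f"DRRImage data must be 2D, got {np.asarray(self.data).ndim}D"
            )

    @property
    def shape(self) -> Tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray, *, domain: Optional[str] = None) -> "DRRImage":
        return replace(self, data=data, domain=domain or self.domain)


@dataclass(frozen=True)
class ProjectionGeometry:
    """Acquisition geometry for a projector.

    ``parallel`` mode integrates along one axis of the voxel grid (default
    ``y``, i.e. a posteroanterior view) and ignores the source/detector
    fields.  ``point_source`` mode traces diverging rays from a source point
    to a flat detector perpendicular to ``y``; ``source_detector_distance``
    (SDD) and ``source_object_distance`` (SOD) set the magnification
    ``SDD / SOD``.
    """

    mode: Literal["parallel", "point_source"] = "parallel"
    axis: int = 1  # y: posteroanterior
    source_detector_distance: float = 1800.0
    source_object_distance: float = 1500.0
    detector_size: Optional[Tuple[int, int]] = None  # (nv, nu) = (rows~z, cols~x)
    detector_pitch: Optional[Tuple[float, float]] = None  # (dv, du) mm/pixel
    source_position: Optional[Tuple[float, float, float]] = None  # (z, y, x) mm
    step_length: Optional[float] = None  # ray sampling step, mm

    def __post_init__(self) -> None:
        if self.mode == "point_source":
            if self.source_detector_distance <= 0:
                raise GeometryError("source_detector_distance must be > 0")
            if self.source_object_distance <= 0:
                raise GeometryError("source_object_distance must be > 0")

    @property
    def magnification(self) -> float:
        return self.source_detector_distance / self.source_object_distance


@dataclass(frozen=True)
class WeightingFunction:
    """A map from normalized sorted position ``x ∈ [0, 1]`` to weight ``≥ 0``.

    Houses the SoftMip and wedge profiles as well as the degenerate
    MIP (top-position indicator) and mean (constant) weightings.
    """

    name: str
    fn: Callable[[np.ndarray], np.ndarray]
    parameters: dict = field(default_factory=dict)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if np.any(x < 0.0) or np.any(x > 1.0):
            raise DataError("normalized sorted positions must lie in [0, 1]")
        w = np.asarray(self.fn(x), dtype=float)
        if np.any(w < 0.0):
            raise DataError(f"weighting function {self.name!r} produced negative weights")
        return w


@dataclass(frozen=True)
class MaterialMap:
    """Per-voxel material labels aligned with a :class:`CTVolume`.

    ``labels`` holds ``MATERIAL_AIR`` / ``MATERIAL_SOFT_TISSUE`` /
    ``MATERIAL_BONE``; ``mu`` is the per-voxel linear attenuation (mm⁻¹)
    assigned from the per-material coefficients.
    """

    labels: np.ndarray
    mu: np.ndarray
    coefficients: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.labels.shape != self.mu.shape:
            raise DataError("labels and mu must share a shape")


def validate_volume(volume: CTVolume) -> CTVolume:
    """Validate and normalize a loaded CT volume.

    Returns a volume whose data is float, 3D, free of NaN/Inf, and floored at
    −1024 HU.  Raises :class:`DimensionalityError` for non-3D input and
    :class:`DataError` for non-finite voxels or non-positive spacing.
    """
    data = np.asarray(volume.data)
    if data.ndim != 3:
        raise DimensionalityError(f"CT volume must be 3D, got {data.ndim}D")
    if not np.all(np.isfinite(data)):
        raise DataError("CT volume contains NaN or Inf voxels")
    spacing = np.asarray(volume.spacing, dtype=float)
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise DataError(f"voxel spacing must be three positive numbers, got {volume.spacing}")
    data = data.astype(float, copy=False)
    if data.min() < HU_FLOOR:
        data = np.maximum(data, HU_FLOOR)
    return replace(volume, data=data, spacing=tuple(spacing.tolist()))
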