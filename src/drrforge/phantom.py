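"""Seedable synthetic chest-CT phantom.

The phantom emulates a thorax at HU scale with geometric primitives: an
elliptic-cylinder body of soft tissue (0 HU) in an air background (−1000 HU),
two lung ellipsoids (−850 HU), a posterior spine cylinder (700 HU), elliptical
rib arcs (500 HU), optional spherical nodules written last (default +50 HU,
the soft-tissue density of a real pulmonary nodule), and additive white
Gaussian texture noise (default σ = 20 HU) mimicking ultra-low-dose CT
noisiness.

The default grid is 128³ at 1.5 mm isotropic spacing — a thin-slice
reconstruction of a compact 19 cm field of view, chosen so an 8 mm nodule
spans more than five voxels and remains resolvable, while keeping every test
desk-scale.  All anatomy defaults are expressed as fractions of the field of
view, so the same proportions hold at any grid size.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import CTVolume, PhantomSpecError, validate_volume

__all__ = ["PhantomSpec", "Lesion", "CohortCase", "generate_chest_phantom", "generate_cohort"]

Point = Tuple[float, float, float]


@dataclass(frozen=True)
class Lesion:
    """A spherical nodule: center (z, y, x) in mm, radius in mm, HU value."""

    center: Point
    radius: float = 4.0
    hu: float = 50.0


@dataclass(frozen=True)
class PhantomSpec:
    """Full geometric description of one phantom instance.

    Lengths are mm in world coordinates (origin at the center of voxel
    ``(0,0,0)``).  Fields left ``None`` are resolved to anatomy-proportioned
    defaults from the grid extent by :meth:`resolved`.
    """

    shape: Tuple[int, int, int] = (128, 128, 128)
    spacing: Tuple[float, float, float] = (1.5, 1.5, 1.5)
    body_half_axes: Optional[Tuple[float, float]] = None  # (by, bx) mm
    lung_half_axes: Optional[Tuple[float, float, float]] = None  # (az, ay, ax) mm
    lung_centers: Optional[Tuple[Point, Point]] = None
    spine_radius: Optional[float] = None
    spine_hu: float = 700.0
    rib_count: int = 8
    rib_radius: float = 2.5  # tube half-thickness, mm
    rib_hu: float = 500.0
    body_hu: float = 0.0
    lung_hu: float = -850.0
    air_hu: float = -1000.0
    lesions: Tuple[Lesion, ...] = ()
    noise_sigma: float = 20.0
    seed: int = 0

    @property
    def extent(self) -> np.ndarray:
        return np.asarray(self.shape, dtype=float) * np.asarray(self.spacing, dtype=float)

    @property
    def grid_center(self) -> np.ndarray:
        return (np.asarray(self.shape, dtype=float) - 1.0) / 2.0 * np.asarray(
            self.spacing, dtype=float
        )

    def resolved(self) -> "PhantomSpec":
        """Fill unset anatomy fields with defaults proportional to the grid."""
        lz, ly, lx = self.extent
        cz, cy, cx = self.grid_center
        body = self.body_half_axes or (0.29 * ly, 0.42 * lx)
        lungs_ha = self.lung_half_axes or (0.36 * lz, 0.20 * ly, 0.15 * lx)
        lung_centers = self.lung_centers or (
            (cz, cy - 0.02 * ly, cx - 0.22 * lx),
            (cz, cy - 0.02 * ly, cx + 0.22 * lx),
        )
        spine_radius = self.spine_radius or 0.06 * lx
        return replace(
            self,
            body_half_axes=body,
            lung_half_axes=lungs_ha,
            lung_centers=lung_centers,
            spine_radius=spine_radius,
        )


@dataclass(frozen=True)
class CohortCase:
    """One synthetic case: its phantom spec and binary lesion label."""

    case_id: str
    spec: PhantomSpec
    label: int

    def volume(self) -> CTVolume:
        return generate_chest_phantom(self.spec)


def _check_lesions(spec: PhantomSpec) -> None:
    az, ay, ax = spec.lung_half_axes  # type: ignore[misc]
    for lesion in spec.lesions:
        if lesion.radius <= 0:
            raise PhantomSpecError("lesion radius must be positive")
        inside_any = False
        for lc in spec.lung_centers:  # type: ignore[union-attr]
            margins = np.array([az, ay, ax]) - lesion.radius
            if np.any(margins <= 0):
                continue
            d = (np.asarray(lesion.center) - np.asarray(lc)) / margins
            if np.sum(d**2) <= 1.0:
                inside_any = True
                break
        if not inside_any:
            raise PhantomSpecError(
                f"lesion at {lesion.center} (r={lesion.radius} mm) does not fit inside a lung"
            )


def generate_chest_phantom(spec: PhantomSpec) -> CTVolume:
    """Render a phantom spec to a CT volume (validated, HU-floored).

    Structures are painted in order air → body → lungs → spine → ribs →
    lesions, then seeded Gaussian texture noise is added.  Identical specs
    (including seed) produce bit-identical volumes.
    """
    spec = spec.resolved()
    _check_lesions(spec)

    nz, ny, nx = spec.shape
    dz, dy, dx = spec.spacing
    z = (np.arange(nz) * dz)[:, None, None]
    y = (np.arange(ny) * dy)[None, :, None]
    x = (np.arange(nx) * dx)[None, None, :]
    cz, cy, cx = spec.grid_center

    hu = np.full(spec.shape, spec.air_hu, dtype=float)

    by, bx = spec.body_half_axes  # type: ignore[misc]
    body = ((y - cy) / by) ** 2 + ((x - cx) / bx) ** 2 <= 1.0
    hu[np.broadcast_to(body, spec.shape)] = spec.body_hu

    az, ay, ax = spec.lung_half_axes  # type: ignore[misc]
    for lc in spec.lung_centers:  # type: ignore[union-attr]
        lung = (
            ((z - lc[0]) / az) ** 2 + ((y - lc[1]) / ay) ** 2 + ((x - lc[2]) / ax) ** 2
        ) <= 1.0
        hu[lung] = spec.lung_hu

    # posterior spine cylinder
    sy, sx = cy + 0.6 * by, cx
    spine = ((y - sy) ** 2 + (x - sx) ** 2) <= spec.spine_radius**2  # type: ignore[operator]
    hu[np.broadcast_to(spine, spec.shape)] = spec.spine_hu

    # elliptical rib arcs: thin ring shells at evenly spaced axial levels,
    # open at the anterior midline (sternum gap)
    if spec.rib_count > 0:
        ra, rb = 0.86 * bx, 0.86 * by
        q = np.sqrt(((x - cx) / ra) ** 2 + ((y - cy) / rb) ** 2)
        t = spec.rib_radius / (0.5 * (ra + rb))
        ring = np.abs(q - 1.0) <= t
        theta = np.arctan2((y - cy) / rb, (x - cx) / ra)
        gap = np.abs(theta + np.pi / 2.0) > 0.45  # anterior (−y) opening
        ring2d = np.broadcast_to(ring & gap, spec.shape)
        levels = np.linspace(cz - 0.38 * spec.extent[0], cz + 0.38 * spec.extent[0], spec.rib_count)
        for zk in levels:
            band = np.abs(z - zk) <= max(spec.rib_radius, dz / 2.0)
            hu[np.broadcast_to(band, spec.shape) & ring2d] = spec.rib_hu

    for lesion in spec.lesions:
        lz_, ly_, lx_ = lesion.center
        ball = ((z - lz_) ** 2 + (y - ly_) ** 2 + (x - lx_) ** 2) <= lesion.radius**2
        hu[ball] = lesion.hu

    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sigma, size=spec.shape)

    return validate_volume(CTVolume(data=hu, spacing=spec.spacing))


def generate_cohort(
    n_cases: int,
    lesion_prevalence: float,
    seed: int = 0,
    *,
    shape: Tuple[int, int, int] = (128, 128, 128),
    spacing: Tuple[float, float, float] = (1.5, 1.5, 1.5),
    lesion_radius: float = 4.0,
    lesion_hu: float = 50.0,
    anatomy_jitter: float = 0.06,
) -> List[CohortCase]:
    """Generate a fully seed-deterministic cohort of phantom cases.

    Each case gets independently jittered anatomy (body and lung half-axes
    scaled by ``1 ± anatomy_jitter``) and, with probability
    ``lesion_prevalence``, a single spherical nodule at a random position
    inside one lung.  The label is 1 iff the case carries a lesion.  Volumes
    are realized lazily through :meth:`CohortCase.volume`.
    """
    if not 0.0 <= lesion_prevalence <= 1.0:
        raise PhantomSpecError("lesion_prevalence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    base = PhantomSpec(shape=shape, spacing=spacing).resolved()
    cases: List[CohortCase] = []
    for i in range(n_cases):
        body = tuple(
            a * rng.uniform(1 - anatomy_jitter, 1 + anatomy_jitter) for a in base.body_half_axes
        )
        lungs_ha = tuple(
            a * rng.uniform(1 - anatomy_jitter, 1 + anatomy_jitter) for a in base.lung_half_axes
        )
        has_lesion = bool(rng.random() < lesion_prevalence)
        lesions: Tuple[Lesion, ...] = ()
        if has_lesion:
            side = int(rng.integers(0, 2))
            lc = np.asarray(base.lung_centers[side])
            # random point well inside the lung ellipsoid
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            r = 0.55 * rng.uniform() ** (1 / 3)
            offset = u * r * (np.asarray(lungs_ha) - lesion_radius).clip(min=0.0)
            lesions = (Lesion(center=tuple(lc + offset), radius=lesion_radius, hu=lesion_hu),)
        case_seed = int(rng.integers(0, 2**31 - 1))
        spec = replace(
            base,
            body_half_axes=body,  # type: ignore[arg-type]
            lung_half_axes=lungs_ha,  # type: ignore[arg-type]
            lesions=lesions,
            seed=case_seed,
        )
        cases.append(CohortCase(case_id=f"case_{i:04d}", spec=spec, label=int(has_lesion)))
    return cases
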