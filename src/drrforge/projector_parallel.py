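"""Parallel-beam posteroanterior projectors.

Three families share the parallel geometry (one output pixel per ``(z, x)``
column, integration along ``y``):

* :func:`beer_lambert_project` — physical line integral of the linear
  attenuation coefficient, transmitted intensity ``I = I0·exp(−∫μ dy)``;
* :func:`sorted_weighted_project` — rank-weighted column average: the samples
  of each ray are sorted ascending and combined with weights that depend only
  on the normalized sorted position, which covers SoftMip
  (:func:`softmip_weight`), the visually tuned wedge ramp
  (:func:`wedge_weight`), and the degenerate MIP / mean cases.

Sampling along ``y`` uses the voxel grid directly — every voxel of a column
contributes exactly once, with path length ``dy``.

The SoftMip profile is piecewise linear in the normalized sorted position
``x ∈ [0, 1]``: ``0.5·x`` below the breakpoint and a steeper line reaching 1
at the top position.  With the default breakpoint 0.5 the upper branch is
``1.5·x − 0.5`` and the profile is continuous (both branches give 0.25 at the
breakpoint).  Low-ranked (dark) samples are down-weighted, the maximum gets
full weight — interpolating between a mean projection and a MIP, which is what
makes the profile attractive for noisy ultra-low-dose CT data.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .attenuation import AttenuationModel, hu_to_mu
from .core import (
    CTVolume,
    DataError,
    DegenerateWeightsError,
    DRRImage,
    WeightingFunction,
)

__all__ = [
    "softmip_weight",
    "wedge_weight",
    "softmip_weighting",
    "wedge_weighting",
    "mip_weighting",
    "mean_weighting",
    "sorted_positions",
    "sorted_weighted_project",
    "beer_lambert_project",
]


def _check_unit_interval(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0.0) or np.any(x > 1.0):
        raise DataError("sorted position must lie in [0, 1]")
    return x


def softmip_weight(x, breakpoint: float = 0.5) -> np.ndarray:
    """SoftMip weight at normalized sorted position ``x``.

    ``f(x) = 0.5·x`` for ``x ≤ breakpoint``; above the breakpoint the weight
    rises linearly to ``f(1) = 1``.  For the default breakpoint 0.5 this is
    ``1.5·x − 0.5``.  Continuous, non-decreasing, with range [0, 1].
    """
    x = _check_unit_interval(x)
    b = float(breakpoint)
    if not 0.0 < b < 1.0:
        raise DataError("breakpoint must lie strictly inside (0, 1)")
    lower = 0.5 * x
    upper = 0.5 * b + (1.0 - 0.5 * b) * (x - b) / (1.0 - b)
    return np.where(x <= b, lower, upper)


def wedge_weight(x, onset: float = 0.0, plateau: float = 1.0) -> np.ndarray:
    """Wedge weight: a linear ramp from ``onset`` to ``plateau``.

    The published slab technique tuned its profile visually and never printed
    it; the default ``f(x) = x`` is a documented stand-in.  Positions below
    ``onset`` get weight 0, positions above ``plateau`` weight 1.
    """
    x = _check_unit_interval(x)
    if not 0.0 <= onset < plateau <= 1.0:
        raise DataError("wedge requires 0 <= onset < plateau <= 1")
    return np.clip((x - onset) / (plateau - onset), 0.0, 1.0)


def softmip_weighting(breakpoint: float = 0.5) -> WeightingFunction:
    return WeightingFunction(
        "softmip", lambda x: softmip_weight(x, breakpoint), {"breakpoint": breakpoint}
    )


def wedge_weighting(onset: float = 0.0, plateau: float = 1.0) -> WeightingFunction:
    return WeightingFunction(
        "wedge",
        lambda x: wedge_weight(x, onset, plateau),
        {"onset": onset, "plateau": plateau},
    )


def mip_weighting() -> WeightingFunction:
    """Indicator of the top sorted position: recovers the per-column maximum."""
    return WeightingFunction("mip", lambda x: (np.asarray(x, dtype=float) == 1.0).astype(float))


def mean_weighting() -> WeightingFunction:
    """Constant weight: recovers the per-column mean."""
    return WeightingFunction("mean", lambda x: np.ones_like(np.asarray(x, dtype=float)))


def sorted_positions(n: int) -> np.ndarray:
    """Normalized sorted positions ``x_i = i/(n−1)``; a single sample gets 1."""
    if n < 1:
        raise DataError("a ray needs at least one sample")
    if n == 1:
        return np.ones(1)
    return np.arange(n, dtype=float) / (n - 1)


def sorted_weighted_project(
    volume: CTVolume,
    weight_fn: WeightingFunction,
    *,
    shift: float = 0.0,
    technique: Optional[str] = None,
) -> DRRImage:
    """Rank-weighted parallel PA projection.

    Per output pixel ``(z, x)`` the ``y``-column values are sorted ascending,
    weighted by ``weight_fn`` evaluated at the normalized sorted positions,
    and combined as ``Σ wᵢ vᵢ / Σ wᵢ`` — a convex combination, invariant to
    any permutation of the column.  ``shift`` is added to the voxel values
    before projection (the technique dispatcher uses +1024 so HU columns
    project to non-negative values); because the weights are normalized this
    is a pure offset of the output.

    Raises :class:`DegenerateWeightsError` when every weight is zero.
    """
    data = np.asarray(volume.data, dtype=float)
    n = data.shape[1]
    weights = weight_fn(sorted_positions(n))
    total = weights.sum()
    if total <= 0.0:
        raise DegenerateWeightsError(
            f"weighting {weight_fn.name!r} assigns zero weight to every sample of a {n}-long ray"
        )
    col_sorted = np.sort(data + shift, axis=1)
    out = np.tensordot(col_sorted, weights, axes=([1], [0])) / total
    dz, _, dx = volume.spacing
    return DRRImage(
        data=out,
        pixel_spacing=(dz, dx),
        domain="line_integral",
        technique=technique or weight_fn.name,
    )


def beer_lambert_project(
    volume: CTVolume,
    model: Optional[AttenuationModel] = None,
    i0: float = 1.0,
    *,
    domain: str = "intensity",
) -> DRRImage:
    """Parallel Beer–Lambert PA projection.

    Per pixel the line integral ``L(z, x) = Σ_y μ(HU) · dy`` is accumulated
    over the column; the intensity domain returns ``I = i0·exp(−L)``, the
    ``line_integral`` domain returns ``L`` itself.
    """
    model = model or AttenuationModel()
    if domain not in ("intensity", "line_integral"):
        raise DataError(f"unsupported output domain {domain!r}")
    mu = hu_to_mu(volume.data, model)
    dz, dy, dx = volume.spacing
    line_integral = mu.sum(axis=1) * dy
    if domain == "line_integral":
        out = line_integral
    else:
        out = i0 * np.exp(-line_integral)
    return DRRImage(
        data=out,
        pixel_spacing=(dz, dx),
        domain=domain,  # type: ignore[arg-type]
        technique="beer_lambert",
        i0=i0,
    )
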