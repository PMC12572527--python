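"""One-call DRR generation: technique dispatch over the projector modules."""

from __future__ import annotations

from typing import Optional

import numpy as np

from .attenuation import AttenuationModel
from .core import CTVolume, DataError, DRRImage, ProjectionGeometry, TECHNIQUES, validate_volume
from .projector_parallel import (
    beer_lambert_project,
    mean_weighting,
    mip_weighting,
    softmip_weighting,
    sorted_weighted_project,
    wedge_weighting,
)
from .projector_pointsource import apply_noise, point_source_project

__all__ = ["generate_drr", "NoiseParams"]

# HU offset applied before rank-weighted projection so outputs are non-negative
# attenuation proxies (air floors at 0 on the shifted scale).
HU_SHIFT = 1024.0


class NoiseParams(dict):
    """Noise settings for the point-source technique (see ``apply_noise``)."""

    @classmethod
    def default(cls) -> "NoiseParams":
        return cls(photons_per_pixel=1e5, scatter_fraction=0.1, scatter_sigma=10.0)


def generate_drr(
    volume: CTVolume,
    technique: str,
    *,
    model: Optional[AttenuationModel] = None,
    geometry: Optional[ProjectionGeometry] = None,
    i0: float = 1.0,
    noise: Optional[dict] = None,
    noise_seed: Optional[int] = None,
    softmip_breakpoint: float = 0.5,
    wedge_onset: float = 0.0,
    wedge_plateau: float = 1.0,
) -> DRRImage:
    """Generate a DRR with the named technique.

    ``beer_lambert`` and ``point_source`` return intensity-domain images;
    the rank-weighted techniques (``softmip``, ``wedge``, ``mip``, ``mean``)
    return non-negative attenuation-proxy values (HU shifted by +1024) in the
    ``line_integral`` domain.  ``noise`` applies photon/scatter simulation to
    the point-source output only.
    """
    if technique not in TECHNIQUES:
        raise DataError(f"unknown technique {technique!r}; expected one of {TECHNIQUES}")
    volume = validate_volume(volume)

    if technique == "beer_lambert":
        return beer_lambert_project(volume, model, i0)
    if technique == "point_source":
        drr = point_source_project(volume, geometry, model, i0)
        if noise is not None:
            drr = apply_noise(drr, seed=noise_seed, **noise)
        return drr

    weighting = {
        "softmip": lambda: softmip_weighting(softmip_breakpoint),
        "wedge": lambda: wedge_weighting(wedge_onset, wedge_plateau),
        "mip": mip_weighting,
        "mean": mean_weighting,
    }[technique]()
    return sorted_weighted_project(volume, weighting, shift=HU_SHIFT, technique=technique)
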