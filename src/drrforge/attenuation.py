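"""Hounsfield-unit to linear-attenuation conversion and material decomposition.

The model is monoenergetic: a single effective-energy water coefficient
``mu_water`` (default 0.02 mm⁻¹, roughly water at ~60–70 keV) and the standard
CT relation

    μ(HU) = mu_water · (1 + HU / 1000),   clamped at 0,

so that air (−1000 HU) attenuates nothing and water (0 HU) attenuates at
``mu_water``.  The point-source projector additionally decomposes voxels into
air / soft tissue / bone by HU thresholds and scales the bone class by
``bone_factor``, mimicking the class-specific attenuation of
material-decomposition DRR pipelines without a full spectral model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    MATERIAL_AIR,
    MATERIAL_BONE,
    MATERIAL_SOFT_TISSUE,
    CTVolume,
    DataError,
    MaterialMap,
)


@dataclass(frozen=True)
class AttenuationModel:
    """Monoenergetic attenuation model.

    Parameters
    ----------
    mu_water
        Linear attenuation of water at the effective energy, mm⁻¹.
    bone_factor
        Multiplier applied to the water-relative coefficient within the bone
        class during material decomposition.
    air_below, bone_above
        HU thresholds of the three-class decomposition: voxels below
        ``air_below`` are air, above ``bone_above`` are bone, the rest soft
        tissue.
    """

    mu_water: float = 0.02
    bone_factor: float = 2.0
    air_below: float = -500.0
    bone_above: float = 300.0

    def __post_init__(self) -> None:
        if self.mu_water < 0:
            raise DataError("mu_water must be non-negative")
        if self.bone_factor < 0:
            raise DataError("bone_factor must be non-negative")
        if not self.air_below < self.bone_above:
            raise DataError("air_below threshold must lie below bone_above")


def hu_to_mu(hu, model: AttenuationModel | None = None) -> np.ndarray:
    """Convert HU to linear attenuation (mm⁻¹): ``mu_water·(1 + HU/1000)``, ≥ 0.

    Total on finite inputs; HU at or below −1000 maps to exactly 0.
    Accepts scalars or arrays.
    """
    model = model or AttenuationModel()
    hu = np.asarray(hu, dtype=float)
    mu = model.mu_water * (1.0 + hu / 1000.0)
    return np.maximum(mu, 0.0)


def material_decompose(volume: CTVolume, model: AttenuationModel | None = None) -> MaterialMap:
    """Label every voxel air / soft tissue / bone and assign attenuation.

    Air voxels get μ = 0; soft-tissue voxels get the standard HU scaling
    ``mu_water·(1 + HU/1000)``; bone voxels get the same scaling multiplied by
    ``bone_factor``.  Every voxel receives exactly one label.
    """
    model = model or AttenuationModel()
    hu = np.asarray(volume.data, dtype=float)

    labels = np.full(hu.shape, MATERIAL_SOFT_TISSUE, dtype=np.int8)
    labels[hu < model.air_below] = MATERIAL_AIR
    labels[hu > model.bone_above] = MATERIAL_BONE

    base = np.maximum(model.mu_water * (1.0 + hu / 1000.0), 0.0)
    mu = np.where(labels == MATERIAL_BONE, model.bone_factor * base, base)
    mu = np.where(labels == MATERIAL_AIR, 0.0, mu)

    coefficients = {
        MATERIAL_AIR: 0.0,
        MATERIAL_SOFT_TISSUE: model.mu_water,
        MATERIAL_BONE: model.bone_factor * model.mu_water,
    }
    return MaterialMap(labels=labels, mu=mu, coefficients=coefficients)
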