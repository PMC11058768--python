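"""The downgrading cascade: biomass carbon → digestible annual forage.

Standing aboveground biomass carbon is reduced, step by step, to the
digestible biomass a megaherbivore could actually crop in one year:

1. carbon → total biomass (× 2.03);
2. restriction to the preferred plant functional types, weighted by their
   fractional cover and digestibility (forb 0.8, graminoid 0.5, deciduous
   shrub 0.6, the shrub term further halved to reflect proboscidean
   preference and to avoid shrub-biomass bias);
3. a sustainable forage/utilisation rate (10% by default);
4. an NPP conversion (× 0.4) restricting standing biomass to what was grown
   within the year.

Every step is a scalar multiplication, so the cascade is order-free; the
stage tags exist for reporting, not for mathematics.  The output unit is
Mg km⁻² yr⁻¹ of digestible annually generated biomass (AgDB-annual).

Uncertainty enters through the biomass layer only: lower/upper confidence
limits are mean ∓ 1.96 × SE (a 95% prediction-interval multiplier), with the
lower limit clipped at zero since negative biomass is physically
meaningless.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np

from .grid import GridLayer, LandscapeStack, PREFERRED_PFTS

__all__ = [
    "DowngradeConfig",
    "AgDBLayer",
    "carbon_to_total",
    "confidence_bounds",
    "pixel_downgrade_factor",
    "downgrade_factor_layer",
    "compute_agdb_annual",
    "downgrade_stages",
]

logger = logging.getLogger(__name__)

#: Conversion to the internal canonical biomass unit, Mg km⁻²
#: (1 Mg ha⁻¹ = 100 Mg km⁻²; 1 g m⁻² = 1 Mg km⁻²).
_UNIT_TO_MG_KM2 = {
    "Mg C ha-1": 100.0,
    "Mg ha-1": 100.0,
    "g C m-2": 1.0,
    "g m-2": 1.0,
    "Mg C km-2": 1.0,
    "Mg km-2": 1.0,
}

BiomassVariant = Literal["mean", "lcl", "ucl"]

STAGES = ("total_biomass", "digestible", "foraged", "annual")


def _default_digestibility() -> dict[str, float]:
    return {"forb": 0.8, "graminoid": 0.5, "deciduous_shrub": 0.6}


@dataclass
class DowngradeConfig:
    """All multiplicative factors of the cascade, with unit declarations."""

    carbon_to_biomass: float = 2.03
    digestibility: dict[str, float] = field(default_factory=_default_digestibility)
    shrub_preference_adj: float = 0.5
    forage_rate: float = 0.10
    forage_rate_low: float = 0.05
    forage_rate_high: float = 0.25
    npp_factor: float = 0.4
    agbc_units: str = "Mg C ha-1"
    pi_multiplier: float = 1.96

    def __post_init__(self) -> None:
        if self.carbon_to_biomass <= 0:
            raise ValueError("carbon_to_biomass must be positive")
        if set(self.digestibility) != set(PREFERRED_PFTS):
            raise ValueError(
                f"digestibility keys must be exactly {set(PREFERRED_PFTS)}"
            )
        for k, v in self.digestibility.items():
            if not 0 <= v <= 1:
                raise ValueError(f"digestibility[{k!r}] must be in [0, 1]")
        for name in ("shrub_preference_adj", "forage_rate", "npp_factor"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.agbc_units not in _UNIT_TO_MG_KM2:
            raise ValueError(f"unknown biomass unit {self.agbc_units!r}; "
                             f"known: {sorted(_UNIT_TO_MG_KM2)}")
        if self.pi_multiplier <= 0:
            raise ValueError("pi_multiplier must be positive")

    @property
    def unit_scale_to_mg_km2(self) -> float:
        return _UNIT_TO_MG_KM2[self.agbc_units]

    def to_dict(self) -> dict:
        return {
            "carbon_to_biomass": self.carbon_to_biomass,
            "digestibility": dict(self.digestibility),
            "shrub_preference_adj": self.shrub_preference_adj,
            "forage_rate": self.forage_rate,
            "forage_rate_low": self.forage_rate_low,
            "forage_rate_high": self.forage_rate_high,
            "npp_factor": self.npp_factor,
            "agbc_units": self.agbc_units,
            "pi_multiplier": self.pi_multiplier,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DowngradeConfig":
        return cls(**dict(d))


@dataclass
class AgDBLayer:
    """A downgrading-stage raster (Mg km⁻², per year at the annual stage)."""

    layer: GridLayer
    stage: str

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}")
        valid = ~self.layer.nodata_mask
        if np.any(self.layer.values[valid] < 0):
            raise ValueError("AgDB values must be non-negative")

    @property
    def values(self) -> np.ndarray:
        return self.layer.values


def carbon_to_total(agbc: GridLayer, factor: float = 2.03) -> GridLayer:
    """Convert biomass carbon to total biomass by the carbon:biomass factor."""
    if factor <= 0:
        raise ValueError("carbon-to-biomass factor must be positive")
    units = agbc.units.replace(" C ", " ") if " C " in agbc.units else agbc.units
    return agbc.copy_with(agbc.values * factor, units=units)


def confidence_bounds(mean: GridLayer, se: GridLayer,
                      pi_multiplier: float = 1.96) -> tuple[GridLayer, GridLayer]:
    """Lower/upper biomass confidence limits: mean ∓ multiplier × SE.

    The lower limit is clipped at zero — negative biomass is outside the
    range of possibility.
    """
    if mean.shape != se.shape:
        raise ValueError("mean and SE layers are not co-registered")
    lcl = mean.copy_with(np.maximum(0.0, mean.values - pi_multiplier * se.values))
    ucl = mean.copy_with(mean.values + pi_multiplier * se.values)
    return lcl, ucl


def pixel_downgrade_factor(cover_at_pixel: Mapping[str, float],
                           config: DowngradeConfig) -> float:
    """Dimensionless forage-availability factor for one pixel.

    Sum over the preferred plant functional types of cover × digestibility,
    with the deciduous-shrub term further multiplied by the shrub-preference
    adjustment.  Non-preferred types (evergreen shrub, other) contribute
    nothing; unknown keys are ignored with a warning.
    """
    factor = 0.0
    for pft, frac in cover_at_pixel.items():
        if not 0 <= frac <= 1 + 1e-6:
            raise ValueError(f"cover fraction for {pft!r} out of [0, 1]")
        if pft in config.digestibility:
            adj = config.shrub_preference_adj if pft == "deciduous_shrub" else 1.0
            factor += frac * config.digestibility[pft] * adj
        elif pft not in ("evergreen_shrub", "other", "water"):
            logger.warning("ignoring unknown plant functional type %r", pft)
    return factor


def downgrade_factor_layer(stack: LandscapeStack,
                           config: DowngradeConfig) -> GridLayer:
    """Per-pixel downgrade factor as a raster (vectorised form)."""
    for pft in PREFERRED_PFTS:
        if pft not in stack.cover:
            raise ValueError(f"stack is missing cover layer for preferred "
                             f"plant functional type {pft!r}")
    factor = np.zeros(stack.shape)
    for pft in PREFERRED_PFTS:
        adj = config.shrub_preference_adj if pft == "deciduous_shrub" else 1.0
        factor += stack.cover[pft].values.astype(float) * config.digestibility[pft] * adj
    return stack.agbc_mean.copy_with(factor, units="dimensionless")


def _combined_nodata(stack: LandscapeStack) -> np.ndarray:
    mask = stack.agbc_mean.nodata_mask | stack.agbc_se.nodata_mask
    for lyr in stack.cover.values():
        mask = mask | lyr.nodata_mask
    return mask


def _biomass_variant(stack: LandscapeStack, config: DowngradeConfig,
                     variant: BiomassVariant) -> GridLayer:
    if variant == "mean":
        return stack.agbc_mean
    lcl, ucl = confidence_bounds(stack.agbc_mean, stack.agbc_se,
                                 config.pi_multiplier)
    return {"lcl": lcl, "ucl": ucl}[variant]


def compute_agdb_annual(stack: LandscapeStack, config: DowngradeConfig,
                        biomass_variant: BiomassVariant = "mean",
                        forage_rate_override: float | None = None) -> AgDBLayer:
    """Digestible annually generated biomass (Mg km⁻² yr⁻¹) per pixel.

    Per valid pixel: biomass carbon (unit-converted to Mg C km⁻²)
    × carbon:biomass × downgrade factor × forage rate × NPP factor.
    Water pixels are a true zero (zero-forage habitat); nodata in any input
    layer propagates to nodata in the output.
    """
    rate = config.forage_rate if forage_rate_override is None else forage_rate_override
    if not 0 < rate <= 1:
        raise ValueError("forage rate must be in (0, 1]")
    agbc = _biomass_variant(stack, config, biomass_variant)
    factor = downgrade_factor_layer(stack, config)
    values = (
        agbc.values.astype(float)
        * config.unit_scale_to_mg_km2
        * config.carbon_to_biomass
        * factor.values
        * rate
        * config.npp_factor
    )
    values = np.where(stack.water_mask, 0.0, values)
    mask = _combined_nodata(stack)
    values = np.where(mask, 0.0, values)
    layer = GridLayer(values, units="Mg km-2 yr-1", nodata_mask=mask,
                      pixel_size_m=stack.pixel_size_m)
    return AgDBLayer(layer, stage="annual")


def downgrade_stages(stack: LandscapeStack, config: DowngradeConfig,
                     biomass_variant: BiomassVariant = "mean",
                     forage_rate_override: float | None = None
                     ) -> dict[str, AgDBLayer]:
    """All intermediate stage rasters, for reporting.

    Stage means shrink monotonically: total_biomass ≥ digestible ≥ foraged
    ≥ annual.  The final 'annual' stage equals :func:`compute_agdb_annual`
    up to floating-point associativity.
    """
    rate = config.forage_rate if forage_rate_override is None else forage_rate_override
    agbc = _biomass_variant(stack, config, biomass_variant)
    mask = _combined_nodata(stack)

    def _mk(values: np.ndarray, stage: str) -> AgDBLayer:
        v = np.where(stack.water_mask | mask, 0.0, values)
        units = "Mg km-2 yr-1" if stage == "annual" else "Mg km-2"
        return AgDBLayer(GridLayer(v, units=units, nodata_mask=mask.copy(),
                                   pixel_size_m=stack.pixel_size_m), stage)

    total = agbc.values.astype(float) * config.unit_scale_to_mg_km2 \
        * config.carbon_to_biomass
    digestible = total * downgrade_factor_layer(stack, config).values
    foraged = digestible * rate
    annual = foraged * config.npp_factor
    return {
        "total_biomass": _mk(total, "total_biomass"),
        "digestible": _mk(digestible, "digestible"),
        "foraged": _mk(foraged, "foraged"),
        "annual": _mk(annual, "annual"),
    }
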