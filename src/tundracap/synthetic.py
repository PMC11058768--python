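"""Synthetic Arctic landscape generator.

Emulates the statistical structure of the North Slope input rasters the
analysis assumes — a 300 m aboveground biomass carbon map with per-pixel
standard errors, fractional top cover per plant functional type, an integer
ecological-landscape raster, and surface water — without any real data:

* ecoregions form latitudinal bands (coastal plain in the north, then
  foothills, mountains, and boreal lowlands in the south);
* mean biomass roughly doubles from the northern band to the southern band;
* deciduous-shrub cover rises southward, approaching half of cover in the
  boreal band;
* water pixels carry zero biomass and zero vegetated cover.

Pixel-level texture is multiplicative lognormal noise smoothed with a
Gaussian kernel: lognormal keeps biomass positive and right-skewed like real
biomass maps, and smoothing gives short-range spatial autocorrelation.  No
claim of fidelity beyond these first-order properties is made.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .grid import GridLayer, LandscapeStack, PFT_NAMES, write_stack

__all__ = ["SyntheticConfig", "generate_stack", "write_stack"]

#: Band names used when the default four-band layout is requested
#: (row 0 = north).
_BAND_NAMES_4 = ("coastal_plain", "foothills", "mountains", "boreal")

#: Label reserved for water in the zone raster.
WATER_ZONE = 0

#: Mean cover fractions by PFT at the northern and southern band.  Deciduous
#: shrub comes from ``shrub_gradient``; the remaining types interpolate
#: between these endpoints.  Chosen so graminoid-dominated lowland tundra in
#: the north gives way to shrub tundra in the south and cover sums stay < 1.
_COVER_NORTH = {"forb": 0.08, "graminoid": 0.30, "evergreen_shrub": 0.12, "other": 0.10}
_COVER_SOUTH = {"forb": 0.05, "graminoid": 0.20, "evergreen_shrub": 0.05, "other": 0.05}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic landscape.

    ``mean_agbc_north`` (Mg C ha⁻¹) sets the biomass level of the coldest
    band; the southern band mean is ``south_north_biomass_ratio`` times it,
    with intermediate bands geometrically interpolated.  The default level is
    a calibration constant chosen so that default-pipeline densities land in
    a plausible 0–0.4 individuals km⁻² range, not a claim of fidelity to any
    real map.
    """

    n_rows: int = 100
    n_cols: int = 100
    n_bands: int = 4
    south_north_biomass_ratio: float = 2.0
    mean_agbc_north: float = 1.2
    se_fraction: float = 0.15
    shrub_gradient: tuple[float, float] = (0.45, 0.10)  # (south, north)
    water_fraction: float = 0.05
    noise_sigma: float = 0.3
    smoothing_px: float = 2.0
    pixel_size_m: float = 300.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError("grid dimensions must be positive")
        if self.n_bands <= 0 or self.n_bands > self.n_rows:
            raise ValueError("n_bands must be in [1, n_rows]")
        if self.south_north_biomass_ratio <= 0:
            raise ValueError("south_north_biomass_ratio must be positive")
        if self.mean_agbc_north <= 0:
            raise ValueError("mean_agbc_north must be positive")
        if not 0 <= self.se_fraction < 1:
            raise ValueError("se_fraction must be in [0, 1)")
        if not 0 <= self.water_fraction <= 1:
            raise ValueError("water_fraction must be in [0, 1]")
        south, north = self.shrub_gradient
        if not (0 <= north <= south <= 1):
            raise ValueError("shrub_gradient must satisfy 0 <= north <= south <= 1")


def _band_index(n_rows: int, n_bands: int) -> np.ndarray:
    """Band label per row, 0 = northernmost band (row 0)."""
    edges = np.linspace(0, n_rows, n_bands + 1)
    return np.clip(np.searchsorted(edges, np.arange(n_rows), side="right") - 1,
                   0, n_bands - 1)


def _smooth_unit_noise(rng: np.random.Generator, shape, sigma_log: float,
                       smooth_px: float) -> np.ndarray:
    """Smoothed multiplicative lognormal noise with unit mean."""
    if sigma_log == 0:
        return np.ones(shape)
    z = gaussian_filter(rng.standard_normal(shape), smooth_px, mode="nearest")
    z /= max(z.std(), 1e-12)
    return np.exp(sigma_log * z - 0.5 * sigma_log**2)


def generate_stack(config: SyntheticConfig) -> LandscapeStack:
    """Generate a co-registered synthetic landscape stack.

    Deterministic: the same config (including seed) produces a bit-identical
    stack.  Band-mean biomass increases geometrically from north to south so
    the south/north ratio of band means tracks
    ``south_north_biomass_ratio``; deciduous-shrub band-mean cover increases
    monotonically southward.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    nr, nc = config.n_rows, config.n_cols
    bands = _band_index(nr, config.n_bands)[:, None] * np.ones((1, nc), dtype=int)

    # north -> south geometric biomass gradient
    if config.n_bands == 1:
        band_means = np.array([config.mean_agbc_north])
    else:
        expo = np.arange(config.n_bands) / (config.n_bands - 1)
        band_means = config.mean_agbc_north * config.south_north_biomass_ratio**expo
    noise = _smooth_unit_noise(rng, (nr, nc), config.noise_sigma,
                               config.smoothing_px)

    # water from a thresholded smoothed field (quantile -> exact area fraction)
    wfield = gaussian_filter(rng.standard_normal((nr, nc)), config.smoothing_px,
                             mode="nearest")
    if config.water_fraction >= 1.0:
        water = np.ones((nr, nc), dtype=bool)
    elif config.water_fraction <= 0.0:
        water = np.zeros((nr, nc), dtype=bool)
    else:
        water = wfield <= np.quantile(wfield, config.water_fraction)

    # normalise the noise to unit mean within each band's land pixels:
    # smoothing leaves few effective samples per band, so without this the
    # realised band contrast would wander well away from the configured ratio
    # on small grids
    for b in range(config.n_bands):
        sel = (bands == b) & ~water
        if sel.any():
            noise[sel] /= noise[sel].mean()
    agbc = band_means[bands] * noise
    se = config.se_fraction * agbc

    # cover: band-level endpoints interpolated north -> south, light noise
    frac = bands / max(config.n_bands - 1, 1)
    south_shrub, north_shrub = config.shrub_gradient
    base = {"deciduous_shrub": north_shrub + (south_shrub - north_shrub) * frac}
    for pft in _COVER_NORTH:
        base[pft] = _COVER_NORTH[pft] + (_COVER_SOUTH[pft] - _COVER_NORTH[pft]) * frac
    cover_vals = {}
    for pft in PFT_NAMES:
        noise = 0.02 * gaussian_filter(rng.standard_normal((nr, nc)),
                                       config.smoothing_px, mode="nearest")
        cover_vals[pft] = np.clip(base[pft] + noise, 0.0, 1.0)
    total = sum(cover_vals.values())
    over = total > 1.0
    if np.any(over):
        scale = np.where(over, 1.0 / np.maximum(total, 1e-12), 1.0)
        for pft in cover_vals:
            cover_vals[pft] = cover_vals[pft] * scale

    # water carries no vegetation and no biomass
    agbc = np.where(water, 0.0, agbc)
    se = np.where(water, 0.0, se)
    for pft in cover_vals:
        cover_vals[pft] = np.where(water, 0.0, cover_vals[pft])

    zones = np.where(water, WATER_ZONE, bands + 1).astype(np.int32)
    if config.n_bands == 4:
        zone_names = {i + 1: _BAND_NAMES_4[i] for i in range(4)}
    else:
        zone_names = {i + 1: f"band_{i + 1}" for i in range(config.n_bands)}
    zone_names[WATER_ZONE] = "water"

    px = config.pixel_size_m
    f32 = lambda a: a.astype(np.float32)
    return LandscapeStack(
        agbc_mean=GridLayer(f32(agbc), "Mg C ha-1", pixel_size_m=px),
        agbc_se=GridLayer(f32(se), "Mg C ha-1", pixel_size_m=px),
        cover={p: GridLayer(f32(v), "fraction", pixel_size_m=px)
               for p, v in cover_vals.items()},
        zones=GridLayer(zones, "zone label", pixel_size_m=px),
        zone_names=zone_names,
        water_mask=water,
    )
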