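"""Carrying capacity: forage density → herbivore density → population.

Per-pixel density (individuals km⁻²) is annual digestible forage production
(Mg km⁻² yr⁻¹) divided by one animal's unrounded annual need (t yr⁻¹;
1 Mg = 1 t).  Density is therefore inversely proportional to body mass: the
high-mass bound gives the LOW density bound and vice versa, and the
density ratio between the two mass bounds equals the inverse mass ratio
exactly.

Zonal summaries aggregate by ecological-landscape label; the supported
population of a zone is the sum over its pixels of density × pixel area.
Counts stay real-valued internally — rounding to the nearest thousand is a
rendering convention only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .downgrade import AgDBLayer
from .grid import GridLayer

__all__ = ["DensityLayer", "density_from_agdb", "zonal_summary",
           "total_population", "PopulationTotals", "TOTAL_LABEL"]

logger = logging.getLogger(__name__)

TOTAL_LABEL = "ALL"


@dataclass
class DensityLayer:
    """Per-pixel supportable density (individuals km⁻²) at one body mass."""

    layer: GridLayer
    body_mass_kg: float

    def __post_init__(self) -> None:
        if self.body_mass_kg <= 0:
            raise ValueError("body mass must be positive")
        valid = ~self.layer.nodata_mask
        if np.any(self.layer.values[valid] < 0):
            raise ValueError("densities must be non-negative")

    @property
    def values(self) -> np.ndarray:
        return self.layer.values


class PopulationTotals(NamedTuple):
    count_low_mass: float
    count_high_mass: float
    mean_density_low_mass: float
    mean_density_high_mass: float


def density_from_agdb(agdb: AgDBLayer, annual_need_tonnes: float,
                      body_mass_kg: float | None = None) -> DensityLayer:
    """Supportable density = annual forage production / one animal's need."""
    if annual_need_tonnes <= 0:
        raise ValueError("annual need must be positive")
    if agdb.stage != "annual":
        raise ValueError("density requires the annual AgDB stage")
    layer = agdb.layer.copy_with(agdb.values / annual_need_tonnes,
                                 units="individuals km-2")
    # body mass is bookkeeping only; infer a nominal value if absent
    mass = body_mass_kg if body_mass_kg is not None else annual_need_tonnes * 1000.0
    return DensityLayer(layer, body_mass_kg=mass)


def zonal_summary(density_low: DensityLayer, density_high: DensityLayer,
                  agdb: AgDBLayer, zones: GridLayer,
                  pixel_area_km2: float | None = None,
                  zone_names: dict[int, str] | None = None) -> pd.DataFrame:
    """Per-zone table of area, mean forage density, densities and population.

    Columns are labelled by body mass explicitly: ``*_low_mass`` columns
    refer to the lighter animal (the HIGHER density).  The ``ALL`` row is the
    pooled computation over every valid pixel, not a mean of zone means.
    Empty zone labels are omitted with a warning.
    """
    if pixel_area_km2 is None:
        pixel_area_km2 = zones.pixel_area_km2
    if density_low.body_mass_kg > density_high.body_mass_kg:
        raise ValueError("density_low must be the low-body-mass layer")
    valid = ~agdb.layer.nodata_mask
    labels = zones.values
    names = zone_names or {}

    def _row(sel: np.ndarray, label, name: str) -> dict:
        n = int(sel.sum())
        dl, dh = density_low.values[sel], density_high.values[sel]
        return {
            "zone": label,
            "name": name,
            "area_km2": n * pixel_area_km2,
            "mean_agdb": float(agdb.values[sel].mean()) if n else 0.0,
            "mean_density_low_mass": float(dl.mean()) if n else 0.0,
            "mean_density_high_mass": float(dh.mean()) if n else 0.0,
            "supported_individuals_low_mass": float(dl.sum() * pixel_area_km2),
            "supported_individuals_high_mass": float(dh.sum() * pixel_area_km2),
        }

    rows = []
    for label in sorted(np.unique(labels[valid]).tolist()):
        sel = valid & (labels == label)
        rows.append(_row(sel, int(label), names.get(int(label), str(int(label)))))
    if zone_names:
        for label in zone_names:
            if label not in {r["zone"] for r in rows}:
                logger.warning("zone label %r has no valid pixels; omitted", label)
    if not rows:
        raise ValueError("no valid pixels to summarise")
    rows.append(_row(valid, TOTAL_LABEL, "all zones"))
    return pd.DataFrame(rows)


def total_population(summary: pd.DataFrame) -> PopulationTotals:
    """All-zones supported population and pooled mean densities.

    Returns counts at both body-mass bounds (low mass → larger count) and
    the pooled mean densities over all valid pixels.
    """
    if summary is None or len(summary) == 0:
        raise ValueError("empty zonal summary")
    row = summary[summary["zone"] == TOTAL_LABEL]
    if len(row) != 1:
        raise ValueError("summary lacks the all-zones total row")
    r = row.iloc[0]
    return PopulationTotals(
        count_low_mass=float(r["supported_individuals_low_mass"]),
        count_high_mass=float(r["supported_individuals_high_mass"]),
        mean_density_low_mass=float(r["mean_density_low_mass"]),
        mean_density_high_mass=float(r["mean_density_high_mass"]),
    )


def approx_thousands(count: float, granularity: int | None = None) -> str:
    """Render a population count the way headline figures are quoted (~N,000).

    Large counts round to the nearest thousand; small-area runs fall back to
    a finer granularity so the figure stays informative.
    """
    if granularity is None:
        granularity = 1000 if count >= 10000 else (100 if count >= 1000 else 1)
    return f"~{int(round(count / granularity) * granularity):,}"
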