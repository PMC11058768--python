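"""Raster containers and single-band TIFF I/O.

A :class:`GridLayer` is the common currency of the pipeline: one 2-D field of
a single physical quantity with a unit label, a nodata mask, and a square
pixel size in metres.  A :class:`LandscapeStack` bundles the co-registered
layers the analysis needs: aboveground biomass carbon (mean and standard
error), fractional top cover per plant functional type, integer ecological
landscape zones, and a water mask.

Layers are persisted as single-band TIFF files (float32 for continuous
quantities, int32 for zone labels) with the unit label, nodata value and
pixel size recorded as JSON in the image-description tag.  The grid is
abstract-georeferenced: row 0 is the northern edge, the pixel unit is metres,
and no real-world CRS is asserted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "PFT_NAMES",
    "PREFERRED_PFTS",
    "GridLayer",
    "LandscapeStack",
    "write_stack",
    "read_stack",
]

#: All plant functional types carried as cover layers.
PFT_NAMES = ("forb", "graminoid", "deciduous_shrub", "evergreen_shrub", "other")

#: The herbivore-preferred subset that contributes digestible forage.
PREFERRED_PFTS = ("forb", "graminoid", "deciduous_shrub")

_COVER_TOL = 1e-6
_FLOAT_NODATA = -9999.0
_INT_NODATA = -1


@dataclass
class GridLayer:
    """One 2-D raster of a single physical quantity.

    Parameters
    ----------
    values
        2-D array; finite wherever ``nodata_mask`` is False.
    units
        Non-empty unit label, e.g. ``"Mg C ha-1"``, ``"fraction"``,
        ``"Mg km-2 yr-1"``.
    nodata_mask
        Boolean array, True where the pixel carries no data.
    pixel_size_m
        Side length of the square pixel in metres (default 300).
    """

    values: np.ndarray
    units: str
    nodata_mask: np.ndarray | None = None
    pixel_size_m: float = 300.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("GridLayer values must be 2-D")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.nodata_mask.shape != self.values.shape:
            raise ValueError("nodata_mask shape does not match values")
        if not self.units:
            raise ValueError("units label must be non-empty")
        if not self.pixel_size_m > 0:
            raise ValueError("pixel_size_m must be positive")
        valid = self.values[~self.nodata_mask]
        if valid.size and not np.all(np.isfinite(valid.astype(float))):
            raise ValueError("values must be finite where nodata_mask is False")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def pixel_area_km2(self) -> float:
        return (self.pixel_size_m / 1000.0) ** 2

    def copy_with(self, values: np.ndarray, units: str | None = None) -> "GridLayer":
        """A new layer sharing this one's mask and geometry."""
        return GridLayer(
            values=values,
            units=units if units is not None else self.units,
            nodata_mask=self.nodata_mask.copy(),
            pixel_size_m=self.pixel_size_m,
        )


def _check_coregistered(layers: Mapping[str, GridLayer]) -> None:
    shapes = {lyr.shape for lyr in layers.values()}
    sizes = {lyr.pixel_size_m for lyr in layers.values()}
    if len(shapes) > 1 or len(sizes) > 1:
        raise ValueError(
            f"layers are not co-registered: shapes={shapes}, pixel sizes={sizes}"
        )


@dataclass
class LandscapeStack:
    """Co-registered bundle of the inputs to the downgrading cascade."""

    agbc_mean: GridLayer
    agbc_se: GridLayer
    cover: dict[str, GridLayer]
    zones: GridLayer
    zone_names: dict[int, str]
    water_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.water_mask is None:
            self.water_mask = np.zeros(self.agbc_mean.shape, dtype=bool)
        self.water_mask = np.asarray(self.water_mask, dtype=bool)
        all_layers = {"agbc_mean": self.agbc_mean, "agbc_se": self.agbc_se,
                      "zones": self.zones, **{f"cover:{k}": v for k, v in self.cover.items()}}
        _check_coregistered(all_layers)
        if self.water_mask.shape != self.agbc_mean.shape:
            raise ValueError("water_mask shape mismatch")
        self.validate()

    def validate(self) -> None:
        """Enforce the stack invariants; raise ``ValueError`` on violation."""
        valid = ~self.agbc_mean.nodata_mask
        if np.any(self.agbc_mean.values[valid] < 0):
            raise ValueError("agbc_mean must be non-negative")
        if np.any(self.agbc_se.values[~self.agbc_se.nodata_mask] < 0):
            raise ValueError("agbc_se must be non-negative")
        total = np.zeros(self.agbc_mean.shape)
        for name, lyr in self.cover.items():
            v = lyr.values
            ok = ~lyr.nodata_mask
            if np.any(v[ok] < 0) or np.any(v[ok] > 1):
                raise ValueError(f"cover fraction out of [0, 1] for {name!r}")
            total[ok] += v[ok]
        if np.any(total > 1 + _COVER_TOL):
            raise ValueError("cover fractions sum to more than 1 at some pixel")
        for name in self.cover:
            if np.any(self.cover[name].values[self.water_mask] != 0):
                raise ValueError(f"water pixels must have zero {name!r} cover")

    @property
    def shape(self) -> tuple[int, int]:
        return self.agbc_mean.shape

    @property
    def pixel_size_m(self) -> float:
        return self.agbc_mean.pixel_size_m

    @property
    def pixel_area_km2(self) -> float:
        return self.agbc_mean.pixel_area_km2


# ---------------------------------------------------------------------------
# TIFF persistence
# ---------------------------------------------------------------------------

def _write_layer(path: Path, layer: GridLayer, dtype: str) -> None:
    nodata = _INT_NODATA if dtype == "int32" else _FLOAT_NODATA
    data = layer.values.astype(dtype)
    data[layer.nodata_mask] = nodata
    meta = {
        "units": layer.units,
        "nodata": nodata,
        "pixel_size_m": layer.pixel_size_m,
        "row0": "north",
    }
    tifffile.imwrite(path, data, description=json.dumps(meta, sort_keys=True))


def _read_layer(path: Path) -> GridLayer:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = json.loads(tif.pages[0].description)
    mask = data == meta["nodata"]
    return GridLayer(
        values=data,
        units=meta["units"],
        nodata_mask=mask,
        pixel_size_m=float(meta["pixel_size_m"]),
    )


def write_stack(stack: LandscapeStack, directory: str | Path) -> dict[str, Path]:
    """Write every layer of *stack* as a single-band TIFF under *directory*.

    Continuous layers are written as float32, the zone raster as int32 and the
    water mask as uint8; zone labels map to names in ``zone_names.csv``.
    Returns the mapping from layer name to file path.  Reading the directory
    back with :func:`read_stack` reproduces all values bit-exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    for name, layer, dtype in [
        ("agbc_mean", stack.agbc_mean, "float32"),
        ("agbc_se", stack.agbc_se, "float32"),
        ("zones", stack.zones, "int32"),
    ]:
        paths[name] = directory / f"{name}.tif"
        _write_layer(paths[name], layer, dtype)
    for pft, layer in stack.cover.items():
        paths[f"cover_{pft}"] = directory / f"cover_{pft}.tif"
        _write_layer(paths[f"cover_{pft}"], layer, "float32")

    water = GridLayer(stack.water_mask.astype(np.uint8), units="boolean",
                      pixel_size_m=stack.pixel_size_m)
    paths["water_mask"] = directory / "water_mask.tif"
    tifffile.imwrite(
        paths["water_mask"], water.values,
        description=json.dumps({"units": "boolean", "nodata": 255,
                                "pixel_size_m": stack.pixel_size_m,
                                "row0": "north"}, sort_keys=True),
    )

    names = pd.DataFrame(
        sorted(stack.zone_names.items()), columns=["label", "name"]
    )
    paths["zone_names"] = directory / "zone_names.csv"
    names.to_csv(paths["zone_names"], index=False)
    return paths


def read_stack(directory: str | Path) -> LandscapeStack:
    """Read a stack previously written by :func:`write_stack`."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"no such stack directory: {directory}")
    cover = {}
    for pft in PFT_NAMES:
        p = directory / f"cover_{pft}.tif"
        if p.exists():
            cover[pft] = _read_layer(p)
    with tifffile.TiffFile(directory / "water_mask.tif") as tif:
        water = tif.asarray().astype(bool)
    names = pd.read_csv(directory / "zone_names.csv")
    zone_names = dict(zip(names["label"].astype(int), names["name"].astype(str)))
    return LandscapeStack(
        agbc_mean=_read_layer(directory / "agbc_mean.tif"),
        agbc_se=_read_layer(directory / "agbc_se.tif"),
        cover=cover,
        zones=_read_layer(directory / "zones.tif"),
        zone_names=zone_names,
        water_mask=water,
    )
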