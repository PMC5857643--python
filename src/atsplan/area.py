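"""Cultivation-area model.

Areal biomass productivity is modelled as a linear function of absolute
latitude, anchored at the equator and at 40 degrees; the cultivation area a
cell needs is its required biomass divided by the local productivity.  Grid
cells are treated as spherical trapezoids (zones bounded by two parallels
and two meridians) for land-fraction diagnostics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ProductivityModel",
    "GridSpec",
    "areal_productivity",
    "required_area",
    "cell_geodesic_area",
    "add_area_columns",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0
HA_PER_KM2 = 100.0


@dataclass(frozen=True)
class ProductivityModel:
    """Linear relation between |latitude| and areal yield.

    Defaults anchor 91 t ha^-1 yr^-1 (ash-free dry weight) at the equator
    and 55 t ha^-1 yr^-1 at 40 degrees, the performance envelope of
    production-scale algal turf scrubber floways.  Hemisphere symmetry is
    built in: only |latitude| matters.
    """

    p0: float = 91.0
    p40: float = 55.0

    @property
    def slope(self) -> float:
        """Yield change per degree of absolute latitude (t ha^-1 yr^-1 deg^-1)."""
        return (self.p40 - self.p0) / 40.0

    def at(self, latitude):
        return areal_productivity(self, latitude)


def areal_productivity(model: ProductivityModel, latitude):
    """Areal yield (t ha^-1 yr^-1) at a latitude in degrees.

    Raises ``ValueError`` if |latitude| exceeds 90 or the linear model goes
    nonpositive anywhere in the requested latitudes (the model is then
    invalid there, not merely small).
    """
    lat = np.asarray(latitude, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    prod = model.p0 + model.slope * np.abs(lat)
    if np.any(prod <= 0.0):
        raise ValueError("productivity model nonpositive at a requested latitude")
    if lat.ndim == 0:
        return float(prod)
    return prod


def required_area(biomass_t, latitude, model: ProductivityModel | None = None):
    """Cultivation area (ha) producing ``biomass_t`` (t yr^-1) at a latitude."""
    if model is None:
        model = ProductivityModel()
    biomass = np.asarray(biomass_t, dtype=float)
    if np.any(biomass < 0):
        raise ValueError("biomass must be nonnegative")
    area = biomass / areal_productivity(model, latitude)
    if biomass.ndim == 0 and np.ndim(latitude) == 0:
        return float(area)
    return area


@dataclass(frozen=True)
class GridSpec:
    """Regular geographic grid of square (in degrees) cells.

    ``cell_arcmin`` is the cell edge in arc-minutes and must divide 360
    degrees evenly.  ``lat_min``/``lon_min`` locate the grid's south-west
    corner (cell edges, not centers).
    """

    cell_arcmin: float = 60.0
    lat_min: float = -90.0
    lon_min: float = -180.0
    n_lat: int = 180
    n_lon: int = 360
    radius_km: float = EARTH_RADIUS_KM

    def __post_init__(self) -> None:
        if self.cell_arcmin <= 0:
            raise ValueError("cell size must be positive")
        n_per_circle = 360.0 * 60.0 / self.cell_arcmin
        if abs(n_per_circle - round(n_per_circle)) > 1e-9:
            raise ValueError("cell size must divide 360 degrees evenly")
        if self.n_lat < 1 or self.n_lon < 1:
            raise ValueError("grid must contain at least one cell")
        if self.lat_min < -90 or self.lat_min + self.n_lat * self.cell_deg > 90 + 1e-9:
            raise ValueError("grid extends beyond the poles")

    @property
    def cell_deg(self) -> float:
        return self.cell_arcmin / 60.0

    def lat_centers(self) -> np.ndarray:
        return self.lat_min + self.cell_deg * (np.arange(self.n_lat) + 0.5)

    def lon_centers(self) -> np.ndarray:
        lon = self.lon_min + self.cell_deg * (np.arange(self.n_lon) + 0.5)
        return (lon + 180.0) % 360.0 - 180.0


def cell_geodesic_area(grid: GridSpec, lat_center) -> np.ndarray | float:
    """Area (ha) of a grid cell centred at ``lat_center`` degrees.

    Uses the spherical-zone closed form
    ``A = R^2 * dlambda * (sin(phi_n) - sin(phi_s))``; exact for a cell
    bounded by parallels and meridians on a sphere, so a full tiling sums
    to the sphere's area.
    """
    lat = np.asarray(lat_center, dtype=float)
    half = grid.cell_deg / 2.0
    phi_n = np.radians(np.minimum(lat + half, 90.0))
    phi_s = np.radians(np.maximum(lat - half, -90.0))
    dlam = np.radians(grid.cell_deg)
    area_km2 = grid.radius_km**2 * dlam * (np.sin(phi_n) - np.sin(phi_s))
    area_ha = area_km2 * HA_PER_KM2
    if lat.ndim == 0:
        return float(area_ha)
    return area_ha


def add_area_columns(
    requirements: pd.DataFrame,
    model: ProductivityModel | None = None,
    grid: GridSpec | None = None,
    area_fraction_warn: float = 1.0,
) -> pd.DataFrame:
    """Attach productivity and area columns to a per-cell requirement table.

    Adds ``productivity_t_ha_yr``, ``ats_area_ha``, ``cell_area_ha`` and
    ``area_fraction`` (cultivation area over geodesic cell area).  Logs a
    warning when any fraction exceeds ``area_fraction_warn`` — a cell that
    would need more floway than it has land is a sign the inputs or the
    grid resolution are off, not an error in the arithmetic.
    """
    if model is None:
        model = ProductivityModel()
    if grid is None:
        grid = GridSpec()
    out = requirements.copy()
    lat = out["lat"].to_numpy(dtype=float)
    out["productivity_t_ha_yr"] = areal_productivity(model, lat)
    out["ats_area_ha"] = out["biomass_t"].to_numpy(dtype=float) / out["productivity_t_ha_yr"]
    out["cell_area_ha"] = cell_geodesic_area(grid, lat)
    out["area_fraction"] = out["ats_area_ha"] / out["cell_area_ha"]
    worst = float(out["area_fraction"].max()) if len(out) else 0.0
    if worst > area_fraction_warn:
        n_over = int((out["area_fraction"] > area_fraction_warn).sum())
        logger.warning(
            "%d cells need more cultivation area than %.0f%% of their land "
            "(max fraction %.2f)", n_over, 100 * area_fraction_warn, worst,
        )
    return out
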