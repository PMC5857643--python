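"""Readers and writers for the pipeline's on-disk formats.

Nutrient rasters travel as NetCDF (classic format, via xarray's scipy
backend) with ``lat``/``lon`` coordinate axes in degrees and data values
in kg per grid cell per year; NaN is the nodata value.  Basin polygons
travel as GeoJSON FeatureCollections.  All tabular outputs are plain
UTF-8 CSV with a header row, '.' decimals and no thousands separators.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from shapely.geometry import mapping, shape

from .basins import Basin, BasinSet

__all__ = [
    "read_nutrient_raster",
    "write_nutrient_raster",
    "read_basins_geojson",
    "write_basins_geojson",
    "write_csv",
    "read_csv",
]

logger = logging.getLogger(__name__)

CELL_COLUMNS = ["lon", "lat", "excess_n_kg", "excess_p_kg"]

_LAT_NAMES = ("lat", "latitude", "y")
_LON_NAMES = ("lon", "longitude", "x")


def _find_coord(ds: xr.Dataset, candidates: tuple[str, ...]) -> str:
    for name in candidates:
        if name in ds.coords:
            return name
    raise ValueError(
        f"no geographic coordinate among {candidates}; if the raster is in a "
        "projected CRS, reproject it to geographic lat/lon first"
    )


def read_nutrient_raster(path: str | Path, n_var: str = "excess_n_kg",
                         p_var: str = "excess_p_kg") -> pd.DataFrame:
    """Read a NetCDF nutrient raster into a cell table.

    The file must carry geographic ``lat``/``lon`` (or ``latitude``/
    ``longitude``) coordinates giving cell centers in degrees.  Values are
    kg of excess nutrient per cell per year; nodata becomes NaN.  Either
    nutrient variable may be absent, in which case its column is all-NaN.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        raise ValueError(
            "GeoTIFF input is not supported by this build; convert the raster "
            "to NetCDF with geographic lat/lon coordinates"
        )
    ds = xr.open_dataset(path, engine="scipy")
    try:
        lat_name = _find_coord(ds, _LAT_NAMES)
        lon_name = _find_coord(ds, _LON_NAMES)
        lat = ds[lat_name].values.astype(float)
        lon = ds[lon_name].values.astype(float)
        if np.abs(lat).max() > 90.0:
            raise ValueError("latitude values outside [-90, 90]; not a geographic grid")
        lon2d, lat2d = np.meshgrid(lon, lat)
        out = pd.DataFrame({"lon": lon2d.ravel(), "lat": lat2d.ravel()})

        def grab(candidates: tuple[str, ...]) -> np.ndarray:
            for var in candidates:
                if var in ds.data_vars:
                    return ds[var].transpose(lat_name, lon_name).values.astype(float).ravel()
            return np.full(len(out), np.nan)

        out["excess_n_kg"] = grab((n_var, "n", "N"))
        out["excess_p_kg"] = grab((p_var, "p", "P"))
    finally:
        ds.close()
    if out[["excess_n_kg", "excess_p_kg"]].isna().all().all():
        logger.warning("raster %s contains no usable nutrient values", path)
    return out


def write_nutrient_raster(cells: pd.DataFrame, path: str | Path) -> Path:
    """Write a cell table to classic NetCDF; inverse of :func:`read_nutrient_raster`.

    The table must tile a regular lat/lon grid (every lon present at every
    lat), which all tables produced by this package do.
    """
    path = Path(path)
    lat = np.unique(cells["lat"].to_numpy())
    lon = np.unique(cells["lon"].to_numpy())
    if len(lat) * len(lon) != len(cells):
        raise ValueError("cell table does not tile a regular lat/lon grid")
    pivot_n = cells.pivot_table(index="lat", columns="lon", values="excess_n_kg", dropna=False)
    pivot_p = cells.pivot_table(index="lat", columns="lon", values="excess_p_kg", dropna=False)
    ds = xr.Dataset(
        {
            "excess_n_kg": (("lat", "lon"), pivot_n.to_numpy()),
            "excess_p_kg": (("lat", "lon"), pivot_p.to_numpy()),
        },
        coords={"lat": pivot_n.index.to_numpy(), "lon": pivot_n.columns.to_numpy()},
        attrs={"units": "kg per grid cell per year", "nodata": "NaN"},
    )
    ds.to_netcdf(path, engine="scipy")
    return path


def read_basins_geojson(path: str | Path) -> BasinSet:
    """Read basin polygons from a GeoJSON FeatureCollection.

    Each feature needs an ``id`` (feature id or ``properties.id``); a
    ``properties.name`` and ``properties.area_ha`` are used when present.
    """
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    basins = []
    for i, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties") or {}
        bid = str(feat.get("id", props.get("id", i)))
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            raise ValueError(f"basin {bid!r} has invalid geometry")
        basins.append(Basin(
            id=bid,
            name=str(props.get("name", bid)),
            geometry=geom,
            area_ha=props.get("area_ha"),
        ))
    return BasinSet(basins)


def write_basins_geojson(basins: BasinSet, path: str | Path) -> Path:
    path = Path(path)
    features = []
    for b in basins:
        props = {"id": b.id, "name": b.name}
        if b.area_ha is not None:
            props["area_ha"] = b.area_ha
        features.append({
            "type": "Feature",
            "id": b.id,
            "properties": props,
            "geometry": mapping(b.geometry),
        })
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
    return path


#: Fixed float formatting keeps CSV output byte-stable across runs.
CSV_FLOAT_FORMAT = "%.10g"


def write_csv(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    frame.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT, lineterminator="\n")
    return path


def read_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
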