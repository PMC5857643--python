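"""Basin aggregation, ranking and concentration statistics.

Per-cell cultivation areas are summed over hydrological basins (cell-center
point-in-polygon containment), basins are ranked by total area, and the
heavy-tail structure of a field is summarised by top-share concentration
statistics and mass-share bins (the largest cells carrying 10% of the
total, the next 40%, and the remaining 50%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

__all__ = [
    "Basin",
    "BasinSet",
    "assign_cells_to_basins",
    "summarize_basins",
    "concentration_stat",
    "mass_share_bins",
]

UNBASINED = "unbasined"

BIN_TOP10 = "top10"
BIN_NEXT40 = "next40"
BIN_BOTTOM50 = "bottom50"


@dataclass(frozen=True)
class Basin:
    """One drainage basin: identifier, display name, polygon footprint."""

    id: str
    name: str
    geometry: BaseGeometry
    area_ha: float | None = None

    def __post_init__(self) -> None:
        if not self.geometry.is_valid:
            raise ValueError(f"basin {self.id!r} has invalid geometry")
        if self.area_ha is not None and self.area_ha < 0:
            raise ValueError(f"basin {self.id!r} has negative area")


@dataclass
class BasinSet:
    """A collection of basins with unique ids."""

    basins: list[Basin] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [b.id for b in self.basins]
        if len(set(ids)) != len(ids):
            raise ValueError("basin ids are not unique")

    def __len__(self) -> int:
        return len(self.basins)

    def __iter__(self):
        return iter(self.basins)

    def by_id(self, basin_id: str) -> Basin:
        for b in self.basins:
            if b.id == basin_id:
                return b
        raise KeyError(basin_id)


def assign_cells_to_basins(cells: pd.DataFrame, basins: BasinSet) -> pd.Series:
    """Map each cell to the basin containing its center point.

    Cells on a shared boundary go to the basin with the lexicographically
    smallest id, so the assignment is a function of the geometry alone.
    Cells inside no basin are labelled ``"unbasined"``.
    """
    order = np.argsort([b.id for b in basins.basins], kind="stable")
    ordered = [basins.basins[i] for i in order]
    tree = STRtree([b.geometry for b in ordered])
    pts = [Point(xy) for xy in zip(cells["lon"].to_numpy(), cells["lat"].to_numpy())]
    labels = np.full(len(pts), UNBASINED, dtype=object)
    cell_idx, basin_idx = tree.query(pts, predicate="covered_by")
    # boundary cells can be covered by several basins; keep the smallest id
    for ci, bi in zip(cell_idx, basin_idx):
        bid = ordered[bi].id
        if labels[ci] == UNBASINED or bid < labels[ci]:
            labels[ci] = bid
    return pd.Series(labels, index=cells.index, name="basin")


def summarize_basins(
    basin_of_cell: pd.Series,
    ats_area_ha: pd.Series,
    basins: BasinSet | None = None,
    include_unbasined: bool = True,
    basin_area_ha: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Rank basins by summed cultivation area.

    Returns a frame sorted descending by ``ats_area_ha`` (ties broken by
    basin id) with columns ``rank``, ``basin``, ``name``, ``ats_area_ha``,
    ``share_pct`` (of the ranked total), ``cum_share_pct``, and — when
    basin footprint areas are known — ``pct_of_basin_area``, the floway
    area as a percentage of the basin's own land area.

    The ``"unbasined"`` pool is appended after the ranked basins (rank
    ``NaN``) so the summed column conserves the global total.
    """
    area = np.asarray(ats_area_ha, dtype=float)
    if np.any(area < 0):
        raise ValueError("cell areas must be nonnegative")
    df = pd.DataFrame({"basin": np.asarray(basin_of_cell, dtype=object), "ats_area_ha": area})
    sums = df.groupby("basin", sort=False)["ats_area_ha"].sum()
    unbasined_total = float(sums.pop(UNBASINED)) if UNBASINED in sums.index else 0.0

    if basins is not None:
        # basins with no cells still appear, with zero area
        sums = sums.reindex([b.id for b in basins], fill_value=0.0)

    out = sums.rename_axis("basin").reset_index()
    out = out.sort_values(["ats_area_ha", "basin"], ascending=[False, True], kind="stable")
    out = out.reset_index(drop=True)
    out.insert(0, "rank", np.arange(1, len(out) + 1))

    names = {}
    footprint = dict(basin_area_ha or {})
    if basins is not None:
        for b in basins:
            names[b.id] = b.name
            if b.area_ha is not None:
                footprint.setdefault(b.id, b.area_ha)
    out.insert(2, "name", out["basin"].map(names).fillna(out["basin"]))

    total = out["ats_area_ha"].sum()
    if total > 0:
        out["share_pct"] = 100.0 * out["ats_area_ha"] / total
    else:
        out["share_pct"] = 0.0
    out["cum_share_pct"] = out["share_pct"].cumsum()
    if footprint:
        out["pct_of_basin_area"] = 100.0 * out["ats_area_ha"] / out["basin"].map(footprint)

    if include_unbasined:
        pool = {
            "rank": np.nan,
            "basin": UNBASINED,
            "name": UNBASINED,
            "ats_area_ha": unbasined_total,
            "share_pct": np.nan,
            "cum_share_pct": np.nan,
        }
        out = pd.concat([out, pd.DataFrame([pool])], ignore_index=True)
    return out


def concentration_stat(values, target_share: float = 0.5) -> float:
    """Smallest fraction of items carrying ``target_share`` of the total.

    Items are sorted descending; the returned fraction k/n uses the fewest
    items whose sum reaches ``target_share`` of the grand total.  This is
    the inverse of a Lorenz-curve lookup: e.g. "half of the total excess
    is accounted for by 6.8% of the cells".
    """
    if not 0.0 < target_share < 1.0:
        raise ValueError("target_share must lie strictly between 0 and 1")
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if np.any(v < 0):
        raise ValueError("values must be nonnegative")
    total = v.sum()
    if v.size == 0 or total == 0:
        raise ValueError("concentration undefined for an all-zero field")
    v = np.sort(v)[::-1]
    k = int(np.searchsorted(np.cumsum(v), target_share * total)) + 1
    return k / v.size


def mass_share_bins(values) -> np.ndarray:
    """Label each item ``top10`` / ``next40`` / ``bottom50`` by mass share.

    Items sorted descending are accumulated; the items needed to reach 10%
    of the total mass are ``top10``, those needed to continue to 50% are
    ``next40``, the rest ``bottom50``.  An item straddling a boundary goes
    to the higher bin.  Non-finite values get an empty label.
    """
    v = np.asarray(values, dtype=float)
    flat = v.ravel()
    labels = np.full(flat.shape, "", dtype=object)
    ok = np.isfinite(flat)
    if np.any(flat[ok] < 0):
        raise ValueError("values must be nonnegative")
    total = flat[ok].sum()
    if total == 0:
        labels[ok] = BIN_BOTTOM50
        return labels.reshape(v.shape)
    idx = np.nonzero(ok)[0]
    order = idx[np.argsort(-flat[idx], kind="stable")]  # ties keep input order
    cum_before = np.concatenate([[0.0], np.cumsum(flat[order])[:-1]])
    binned = np.where(
        cum_before < 0.10 * total, BIN_TOP10,
        np.where(cum_before < 0.50 * total, BIN_NEXT40, BIN_BOTTOM50),
    )
    labels[order] = binned
    return labels.reshape(v.shape)
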