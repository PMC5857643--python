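"""End-to-end orchestration: cells in, ranked plan and economics out.

A run starts from either a pair of nutrient rasters plus basin polygons on
disk, or a seeded synthetic world, and produces a bundle of CSVs — per-cell
biomass requirements, per-cell cultivation areas, a basin ranking, a
concentration/binning summary and an economic build-out trajectory —
together with a JSON manifest recording every parameter needed to
reproduce the run bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .area import GridSpec, ProductivityModel, add_area_columns
from .basins import (
    UNBASINED,
    BasinSet,
    assign_cells_to_basins,
    concentration_stat,
    mass_share_bins,
    summarize_basins,
)
from .economics import EconScenario, calibrate_initial_spending, scenario_preset, simulate
from .io import read_basins_geojson, read_nutrient_raster, write_csv
from .nutrients import MassRatios, cell_requirements
from .synth import SynthConfig, fixture_small, generate_basins, generate_nutrient_grid

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything a run needs; exactly one input source must be active.

    ``source`` selects where cells come from: ``"synthetic"`` (uses
    ``synth``), ``"fixture"`` (the shipped 10x10 grid) or ``"files"``
    (``n_raster``/``p_raster``/``basins_path``).
    """

    source: str = "synthetic"
    n_raster: str | None = None
    p_raster: str | None = None
    basins_path: str | None = None
    synth: SynthConfig = field(default_factory=SynthConfig)
    p0: float = 91.0
    p40: float = 55.0
    sizing_policy: str = "complete"
    econ_case: str = "worst"
    econ_nutrient: str = "np"
    econ_pairing: str = "conservative"
    use_computed_requirement: bool = True
    outdir: str = "atsplan_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.source not in ("synthetic", "fixture", "files"):
            raise ValueError("source must be 'synthetic', 'fixture' or 'files'")
        if self.source == "files" and not (self.n_raster or self.p_raster):
            raise ValueError("source 'files' requires at least one nutrient raster path")


def _load_cells_and_basins(config: PipelineConfig) -> tuple[pd.DataFrame, BasinSet | None, GridSpec]:
    if config.source == "fixture":
        from .synth import FIXTURE_GRID

        cells, basins = fixture_small()
        return cells, basins, FIXTURE_GRID
    if config.source == "synthetic":
        synth = config.synth
        if config.seed != synth.seed:
            synth = SynthConfig(**{**asdict_synth(synth), "seed": config.seed})
        cells = generate_nutrient_grid(synth)
        basins = generate_basins(synth)
        return cells, basins, synth.grid
    # files
    if config.n_raster:
        cells = read_nutrient_raster(config.n_raster)
        if config.p_raster and config.p_raster != config.n_raster:
            p_cells = read_nutrient_raster(config.p_raster)
            cells["excess_p_kg"] = p_cells["excess_p_kg"].to_numpy()
    else:
        cells = read_nutrient_raster(config.p_raster)
    basins = read_basins_geojson(config.basins_path) if config.basins_path else None
    lat = np.unique(cells["lat"].to_numpy())
    step = float(np.min(np.diff(lat))) if len(lat) > 1 else 1.0
    grid = GridSpec(
        cell_arcmin=step * 60.0,
        lat_min=float(lat.min()) - step / 2.0,
        lon_min=float(cells["lon"].min()) - step / 2.0,
        n_lat=len(lat),
        n_lon=int(round(len(cells) / len(lat))),
    )
    return cells, basins, grid


def asdict_synth(synth: SynthConfig) -> dict:
    d = asdict(synth)
    d["grid"] = synth.grid
    return d


def _summary_table(areas: pd.DataFrame, ratios: MassRatios) -> pd.DataFrame:
    """Global totals, concentration statistics and mass-share bin masses."""
    n = areas["excess_n_kg"].to_numpy(dtype=float)
    p = areas["excess_p_kg"].to_numpy(dtype=float)
    pos_n = np.where(np.isfinite(n) & (n > 0), n, 0.0)
    pos_p = np.where(np.isfinite(p) & (p > 0), p, 0.0)
    rows = [
        ("total_excess_n_t", pos_n.sum() / 1e3),
        ("total_excess_p_t", pos_p.sum() / 1e3),
        ("n_cells", float(len(areas))),
        ("n_cells_with_data", float((np.isfinite(n) | np.isfinite(p)).sum())),
        ("n_cells_n_limited", float((areas["limitation"] == "N_limited").sum())),
        ("n_cells_p_limited", float((areas["limitation"] == "P_limited").sum())),
        ("total_biomass_t_yr", float(areas["biomass_t"].sum())),
        ("total_ats_area_ha", float(areas["ats_area_ha"].sum())),
    ]
    for label, vals in (("n", pos_n), ("p", pos_p)):
        if vals.sum() > 0:
            rows.append((f"half_mass_cell_fraction_{label}", concentration_stat(vals[vals > 0], 0.5)))
            bins = mass_share_bins(vals)
            for b in ("top10", "next40", "bottom50"):
                rows.append((f"bin_{b}_{label}_t", vals[bins == b].sum() / 1e3))
    rows.append(("r_pn", ratios.r_pn))
    return pd.DataFrame(rows, columns=["quantity", "value"])


def run_pipeline(config: PipelineConfig, composition=None) -> dict[str, Path]:
    """Execute the full planning pipeline and write the report bundle.

    Returns a mapping from artifact name to written path.  Stages:
    nutrient accounting -> area model -> basin ranking -> summary
    statistics -> economic build-out (requirement taken from the computed
    biomass total unless ``use_computed_requirement`` is off, in which
    case the published global requirement is used).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    logger.info("stage 1/5: loading cells (%s)", config.source)
    cells, basins, grid = _load_cells_and_basins(config)

    logger.info("stage 2/5: nutrient accounting over %d cells", len(cells))
    ratios = MassRatios.from_composition() if composition is None else MassRatios.from_composition(composition)
    req = cell_requirements(cells, ratios, policy=config.sizing_policy)
    paths["requirements"] = write_csv(req, outdir / "cell_requirements.csv")

    logger.info("stage 3/5: area model")
    model = ProductivityModel(p0=config.p0, p40=config.p40)
    areas = add_area_columns(req, model=model, grid=grid)

    logger.info("stage 4/5: basin ranking")
    if basins is not None:
        areas["basin"] = assign_cells_to_basins(areas, basins)
        footprint = areas.groupby("basin")["cell_area_ha"].sum().to_dict()
        footprint.pop(UNBASINED, None)
        ranking = summarize_basins(
            areas["basin"], areas["ats_area_ha"], basins=basins, basin_area_ha=footprint
        )
        paths["basin_ranking"] = write_csv(ranking, outdir / "basin_ranking.csv")
    paths["areas"] = write_csv(areas, outdir / "cell_areas.csv")

    summary = _summary_table(areas, ratios)
    paths["summary"] = write_csv(summary, outdir / "summary.csv")

    logger.info("stage 5/5: economic build-out")
    scenario = scenario_preset(
        case=config.econ_case, nutrient=config.econ_nutrient, pairing=config.econ_pairing
    )
    if config.use_computed_requirement:
        total_biomass = float(areas["biomass_t"].sum())
        total_area = float(areas["ats_area_ha"].sum())
        if total_biomass > 0 and total_area > 0:
            scenario = EconScenario(
                capex=scenario.capex,
                opex=scenario.opex,
                lifetime=scenario.lifetime,
                growth_rate=scenario.growth_rate,
                growth_years=scenario.growth_years,
                horizon=scenario.horizon,
                unit_productivity=total_biomass / total_area,
                biomass_requirement=total_biomass,
            )
    s0 = calibrate_initial_spending(scenario)
    trajectory = simulate(scenario, s0)
    paths["econ_trajectory"] = write_csv(trajectory, outdir / "econ_trajectory.csv")

    manifest = {
        "package": "atsplan",
        "version": __version__,
        "seed": config.seed,
        "source": config.source,
        "sizing_policy": config.sizing_policy,
        "productivity": {"p0": config.p0, "p40": config.p40},
        "grid": {
            "cell_arcmin": grid.cell_arcmin,
            "lat_min": grid.lat_min,
            "lon_min": grid.lon_min,
            "n_lat": grid.n_lat,
            "n_lon": grid.n_lon,
            "registration": "cell-center coordinates, lat positive north, lon in [-180, 180)",
        },
        "synth": None if config.source != "synthetic" else {
            k: v for k, v in asdict(config.synth).items() if k != "grid"
        },
        "inputs": {
            "n_raster": config.n_raster,
            "p_raster": config.p_raster,
            "basins": config.basins_path,
        },
        "econ": {
            "case": config.econ_case,
            "nutrient": config.econ_nutrient,
            "pairing": config.econ_pairing,
            "capex": scenario.capex,
            "opex": scenario.opex,
            "lifetime": scenario.lifetime,
            "unit_productivity": scenario.unit_productivity,
            "biomass_requirement": scenario.biomass_requirement,
            "calibrated_s0": s0,
        },
        "currency": "2018 USD",
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    manifest_path = outdir / "manifest.json"
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["manifest"] = manifest_path
    return paths
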