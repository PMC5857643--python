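"""Techno-economic build-out simulation.

Models a two-century programme of floway construction: annual gross
spending grows exponentially (10% yr^-1 by default) for 100 years, then
holds constant for another 100.  Each year's budget first pays operating
cost on the surviving floway area, and the remainder buys new area at the
capital cost per hectare.  Facilities built in the same year form a cohort
that retires together after the facility lifetime; synchronized retirement
and rebuilding produces the characteristic "ringing" oscillation in
operational area and biomass, a damped echo whose period is set by the
lifetime and the OpEx/CapEx ratio.

The initial spending rate is calibrated (bisection) so that once the
build-out is complete — from the end of spending growth onward — the
*minimum* annual biomass never falls below the recycling requirement,
ringing troughs included.

All monetary values are 2018 US dollars.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "EconScenario",
    "TABLE_PARAMS",
    "scenario_preset",
    "spending_schedule",
    "simulate",
    "calibrate_initial_spending",
    "steady_state_expense",
    "fuel_power",
    "percent_of",
]

logger = logging.getLogger(__name__)

#: Seconds in a Julian year.
SECONDS_PER_YEAR = 3.1557e7

#: Fuel value of the carbohydrate and protein content of ATS biomass,
#: MJ per kg ash-free dry weight.
DEFAULT_SPECIFIC_ENERGY_MJ_KG = 13.2

#: Global biomass requirement for complete N and P recycling (t yr^-1) and
#: the cultivation area producing it (ha); their ratio is the effective
#: areal productivity used by the aspatial economic model.
NP_BIOMASS_REQUIREMENT_T = 1.2e9
NP_AREA_REQUIREMENT_HA = 1.9e7
DEFAULT_UNIT_PRODUCTIVITY = NP_BIOMASS_REQUIREMENT_T / NP_AREA_REQUIREMENT_HA

#: Biomass requirement for recycling net anthropogenic carbon (t yr^-1).
C_BIOMASS_REQUIREMENT_T = 2.2e10

#: Cost and lifetime parameters: best/worst-case capital expenditure
#: ($ ha^-1), operating expenditure ($ ha^-1 yr^-1) and facility lifetime
#: (yr), plus the published scenario endpoints kept as metadata only.
TABLE_PARAMS = {
    "cap_lo": 2.50e5,
    "cap_hi": 1.00e6,
    "op_lo": 3.30e4,
    "op_hi": 7.00e4,
    "op_life_long": 40,
    "op_life_short": 20,
    # scenario endpoints as published; not used by the simulator
    "betterNP.exp": 2.30e12,
    "betterNP.bm": 3.10e9,
    "worseNP.exp": 6.10e12,
    "worseNP.bm": 3.10e9,
    "betterC.exp": 1.60e13,
    "betterC.bm": 2.20e10,
    "worseC.exp": 4.30e13,
    "worseC.bm": 2.20e10,
}


@dataclass(frozen=True)
class EconScenario:
    """Parameters of one build-out scenario.

    capex / opex are per hectare of floway; ``unit_productivity`` converts
    operational hectares to annual biomass; ``biomass_requirement`` is the
    post-completion minimum the calibration must sustain.
    """

    capex: float
    opex: float
    lifetime: int
    growth_rate: float = 0.10
    growth_years: int = 100
    horizon: int = 200
    unit_productivity: float = DEFAULT_UNIT_PRODUCTIVITY
    biomass_requirement: float = NP_BIOMASS_REQUIREMENT_T

    def __post_init__(self) -> None:
        if min(self.capex, self.opex, self.unit_productivity) <= 0:
            raise ValueError("capex, opex and unit productivity must be positive")
        if self.lifetime < 1 or int(self.lifetime) != self.lifetime:
            raise ValueError("lifetime must be a positive integer number of years")
        if self.horizon < self.growth_years:
            raise ValueError("horizon must reach at least the end of spending growth")
        if self.biomass_requirement < 0:
            raise ValueError("biomass requirement must be nonnegative")


def scenario_preset(
    case: str = "worst",
    nutrient: str = "np",
    pairing: str = "conservative",
    **overrides,
) -> EconScenario:
    """Build a best- or worst-case scenario from the published parameters.

    ``pairing`` selects how facility lifetimes attach to cost levels:
    ``"conservative"`` (default) pairs the worst case (high CapEx/OpEx) with
    the short 20-year lifetime and the best case with the long 40-year one;
    ``"proportional"`` assumes longevity scales with capital quality, pairing
    low CapEx with 20 years and high CapEx with 40.
    ``nutrient`` is ``"np"`` (N and P recycling) or ``"c"`` (net
    anthropogenic carbon, a ~18x larger biomass requirement).
    """
    if case not in ("best", "worst"):
        raise ValueError("case must be 'best' or 'worst'")
    if pairing not in ("conservative", "proportional"):
        raise ValueError("pairing must be 'conservative' or 'proportional'")
    if nutrient not in ("np", "c"):
        raise ValueError("nutrient must be 'np' or 'c'")
    capex = TABLE_PARAMS["cap_hi"] if case == "worst" else TABLE_PARAMS["cap_lo"]
    opex = TABLE_PARAMS["op_hi"] if case == "worst" else TABLE_PARAMS["op_lo"]
    if pairing == "conservative":
        lifetime = TABLE_PARAMS["op_life_short"] if case == "worst" else TABLE_PARAMS["op_life_long"]
    else:
        lifetime = TABLE_PARAMS["op_life_long"] if case == "worst" else TABLE_PARAMS["op_life_short"]
    requirement = NP_BIOMASS_REQUIREMENT_T if nutrient == "np" else C_BIOMASS_REQUIREMENT_T
    scenario = EconScenario(
        capex=capex, opex=opex, lifetime=int(lifetime), biomass_requirement=requirement
    )
    return replace(scenario, **overrides) if overrides else scenario


def spending_schedule(s0: float, scenario: EconScenario) -> np.ndarray:
    """Annual gross spending for years 1..horizon.

    S_t = S0 * (1 + g)^(t-1) during the growth phase — growth is applied
    99 times between year 1 and year 100 — then constant at the year-100
    level.
    """
    if s0 <= 0:
        raise ValueError("initial spending must be positive")
    t = np.arange(1, scenario.horizon + 1)
    exponent = np.minimum(t, scenario.growth_years) - 1
    return s0 * (1.0 + scenario.growth_rate) ** exponent


def simulate(scenario: EconScenario, s0: float) -> pd.DataFrame:
    """Run the cohort build-out simulation.

    Year-by-year, in order: cohorts whose age has reached the lifetime
    retire; operating cost is paid on the surviving area; all remaining
    budget buys new floway area, which operates (and produces biomass)
    from its build year.  If the operating obligation alone exceeds the
    year's budget, the newest cohorts are decommissioned until the
    survivors are affordable (logged as a warning).

    Returns a frame with one row per year: ``year``, ``spending``,
    ``opex_outlay``, ``capex_outlay``, ``new_area_ha``,
    ``operational_area_ha``, ``biomass_t``.
    """
    spend = spending_schedule(s0, scenario)
    build_area: list[float] = []  # cohort areas, indexed by build year - 1
    rows = np.zeros((scenario.horizon, 6))
    shortfall_years = 0
    for i in range(scenario.horizon):
        year = i + 1
        budget = spend[i]
        # survivors: cohorts with build_year > year - lifetime
        oldest_alive = max(0, year - scenario.lifetime)  # cohorts [oldest_alive:] survive
        surviving = build_area[oldest_alive:]
        obligation = scenario.opex * sum(surviving)
        if obligation > budget:
            shortfall_years += 1
            affordable = budget / scenario.opex
            kept = 0.0
            for j in range(len(surviving)):  # keep oldest first, drop newest
                if kept + surviving[j] <= affordable + 1e-12:
                    kept += surviving[j]
                else:
                    trimmed = max(0.0, affordable - kept)
                    # partially decommission the cohort that breaks the budget
                    build_area[oldest_alive + j] = trimmed
                    kept += trimmed
                    for k in range(j + 1, len(surviving)):
                        build_area[oldest_alive + k] = 0.0
                    break
            surviving = build_area[oldest_alive:]
            obligation = scenario.opex * sum(surviving)
        opex_outlay = obligation
        capex_outlay = budget - opex_outlay
        new_area = capex_outlay / scenario.capex
        build_area.append(new_area)
        operational = sum(build_area[oldest_alive:])
        rows[i] = (budget, opex_outlay, capex_outlay, new_area, operational,
                   operational * scenario.unit_productivity)
    if shortfall_years:
        logger.warning(
            "operating budget shortfall in %d of %d years; newest cohorts decommissioned",
            shortfall_years, scenario.horizon,
        )
    out = pd.DataFrame(
        rows,
        columns=["spending", "opex_outlay", "capex_outlay", "new_area_ha",
                 "operational_area_ha", "biomass_t"],
    )
    out.insert(0, "year", np.arange(1, scenario.horizon + 1))
    return out


def _post_completion_min_biomass(scenario: EconScenario, s0: float) -> float:
    traj = simulate(scenario, s0)
    window = traj.loc[traj["year"] >= scenario.growth_years, "biomass_t"]
    return float(window.min())


def calibrate_initial_spending(
    scenario: EconScenario,
    rtol: float = 1e-6,
    bracket: tuple[float, float] = (1.0, 1e15),
) -> float:
    """Minimal initial spending meeting the recycling requirement.

    Finds, by bisection to relative tolerance ``rtol``, the smallest S0
    such that the minimum annual biomass from the end of spending growth
    through the horizon is at least ``scenario.biomass_requirement``.  The
    requirement binds at the ringing troughs, so the calibrated programme
    overshoots at the peaks.
    """
    lo, hi = bracket
    if scenario.biomass_requirement == 0:
        return lo

    def ok(s0: float) -> bool:
        return _post_completion_min_biomass(scenario, s0) >= scenario.biomass_requirement

    # expand the bracket geometrically if needed
    expansions = 0
    while not ok(hi):
        hi *= 10.0
        expansions += 1
        if expansions > 20:
            raise ValueError("biomass requirement unachievable within any spending bracket")
    if ok(lo):
        return lo
    while hi / lo - 1.0 > rtol:
        mid = math.sqrt(lo * hi)
        if ok(mid):
            hi = mid
        else:
            lo = mid
    return hi


def steady_state_expense(area_ha: float, capex: float, opex: float, lifetime: float) -> float:
    """Annual gross expense sustaining a fixed operational area ($ yr^-1).

    Closed form ``area * (opex + capex / lifetime)``: operating cost on the
    whole area plus replacing 1/lifetime of it each year.  This is the
    plateau a completed build-out settles around.
    """
    if min(area_ha, capex, opex, lifetime) < 0:
        raise ValueError("inputs must be nonnegative")
    if lifetime <= 0:
        raise ValueError("lifetime must be positive")
    return area_ha * (opex + capex / lifetime)


def fuel_power(biomass_t_yr: float, specific_energy_mj_kg: float = DEFAULT_SPECIFIC_ENERGY_MJ_KG) -> float:
    """Continuous power (W) embodied in an annual biomass flow.

    ``biomass_t_yr`` tonnes per year at ``specific_energy_mj_kg`` (fuel
    value of the carbohydrate and protein content per kg ash-free dry
    weight), averaged over a Julian year.
    """
    if biomass_t_yr < 0 or specific_energy_mj_kg < 0:
        raise ValueError("inputs must be nonnegative")
    joules_per_year = biomass_t_yr * 1e3 * specific_energy_mj_kg * 1e6
    return joules_per_year / SECONDS_PER_YEAR


def percent_of(value: float, reference: float) -> float:
    """``value`` as a percentage of ``reference``."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return 100.0 * value / reference
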