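"""Cohort build-out simulator, calibration, and closed-form helpers."""

import numpy as np
import pytest

from atsplan.economics import (
    EconScenario,
    TABLE_PARAMS,
    calibrate_initial_spending,
    fuel_power,
    percent_of,
    scenario_preset,
    simulate,
    spending_schedule,
    steady_state_expense,
)


def toy_scenario(**overrides) -> EconScenario:
    base = dict(capex=100.0, opex=10.0, lifetime=5, growth_rate=0.1, growth_years=10,
                horizon=20, unit_productivity=1.0, biomass_requirement=100.0)
    base.update(overrides)
    return EconScenario(**base)


class TestSpendingSchedule:
    def test_99_growth_steps_between_year_1_and_100(self):
        sc = scenario_preset("worst")
        s = spending_schedule(1.0, sc)
        assert s[99] / s[0] == pytest.approx(1.1**99, rel=1e-12)
        assert s[99] / s[0] == pytest.approx(1.2527e4, rel=1e-3)

    def test_constant_after_growth_years(self):
        sc = scenario_preset("worst")
        s = spending_schedule(7.0, sc)
        assert np.all(s[99:] == s[99])

    def test_zero_growth_is_constant(self):
        sc = toy_scenario(growth_rate=0.0)
        assert np.all(spending_schedule(5.0, sc) == 5.0)

    def test_nonpositive_s0_rejected(self):
        with pytest.raises(ValueError):
            spending_schedule(0.0, toy_scenario())


class TestSimulate:
    def test_budget_conservation_every_year(self):
        traj = simulate(scenario_preset("worst"), 2e8)
        assert np.allclose(traj["opex_outlay"] + traj["capex_outlay"], traj["spending"])
        assert (traj[["opex_outlay", "capex_outlay", "new_area_ha",
                      "operational_area_ha", "biomass_t"]] >= 0).all().all()

    def test_no_retirement_converges_to_s_over_opex(self):
        sc = toy_scenario(lifetime=100, growth_rate=0.0, growth_years=1, horizon=60,
                          biomass_requirement=0.0)
        traj = simulate(sc, 1000.0)
        area = traj["operational_area_ha"].to_numpy()
        assert np.all(np.diff(area) > -1e-12)          # approaches from below
        assert np.all(area <= 1000.0 / sc.opex + 1e-9)
        assert area[-1] == pytest.approx(1000.0 / sc.opex, rel=1e-2)

    def test_single_cohort_operates_exactly_lifetime_years(self):
        # opex-free facilities: one cohort in year 1, nothing after
        sc = EconScenario(capex=100.0, opex=1e-12, lifetime=5, growth_rate=0.0,
                          growth_years=1, horizon=12, unit_productivity=1.0,
                          biomass_requirement=0.0)
        spend = spending_schedule(1000.0, sc)
        assert np.all(spend == 1000.0)
        # emulate a one-off grant by a scenario with a single nonzero year:
        # constant spending rebuilds, so instead check cohort lifetime directly
        traj = simulate(sc, 1000.0)
        # every year builds ~10 ha; after year 5 the year-(t-5) cohort retires,
        # so operational area plateaus at lifetime * build
        area = traj["operational_area_ha"].to_numpy()
        assert area[4] == pytest.approx(5 * 10.0, rel=1e-6)
        assert np.allclose(area[5:], area[4], rtol=1e-6)

    def test_area_conservation_against_cohort_replay(self):
        """Operational area equals an independent replay of cohort retirements."""
        sc = toy_scenario(horizon=40, growth_years=15)
        traj = simulate(sc, 50.0)
        new = traj["new_area_ha"].to_numpy()
        for t in range(1, sc.horizon + 1):
            alive = sum(new[b - 1] for b in range(1, t + 1) if b + sc.lifetime > t)
            assert traj.loc[t - 1, "operational_area_ha"] == pytest.approx(alive, rel=1e-12)

    def test_nondecreasing_biomass_without_retirement(self):
        sc = toy_scenario(lifetime=30, horizon=25, growth_rate=0.0, growth_years=1)
        traj = simulate(sc, 100.0)
        assert np.all(np.diff(traj["biomass_t"].to_numpy()) >= -1e-12)

    def test_budget_shortfall_decommissions_newest(self, caplog):
        # spending collapses after the growth phase would normally keep rising
        sc = EconScenario(capex=10.0, opex=10.0, lifetime=50, growth_rate=0.5,
                          growth_years=5, horizon=10, unit_productivity=1.0,
                          biomass_requirement=0.0)
        with caplog.at_level("WARNING", logger="atsplan.economics"):
            traj = simulate(sc, 1.0)
        # growth stops at year 5 but opex on accumulated area keeps growing
        assert np.allclose(traj["opex_outlay"] + traj["capex_outlay"], traj["spending"])
        assert (traj["operational_area_ha"] <= traj["spending"] / sc.opex + 1e-9).all()
        assert any("shortfall" in r.message for r in caplog.records)

    def test_ringing_period_matches_characteristic_root(self):
        """Post-completion biomass rings at the period of the dominant root of
        the cohort-replacement recurrence, not exactly at the lifetime."""
        sc = scenario_preset("worst")  # lifetime 20, opex/capex = 0.07
        s0 = calibrate_initial_spending(sc)
        traj = simulate(sc, s0)
        b = traj.loc[traj["year"] > sc.growth_years, "biomass_t"].to_numpy()
        x = b - b.mean()
        k = int(np.argmax(np.abs(np.fft.rfft(x))[1:])) + 1
        observed_period = len(b) / k
        # independent oracle: roots of z^(L-1) + a*(z^(L-2)+...+1), a = opex/capex
        a = sc.opex / sc.capex
        roots = np.roots(np.concatenate([[1.0], np.full(sc.lifetime - 1, a)]))
        dom = roots[np.argmax(np.abs(roots))]
        predicted = 2 * np.pi / abs(np.angle(dom))
        # match to the resolution of the 100-sample DFT grid
        grid = len(b) / np.arange(1, len(b) // 2 + 1)
        assert observed_period == grid[np.argmin(np.abs(grid - predicted))]


class TestCalibration:
    def test_zero_requirement_returns_lower_bound(self):
        sc = toy_scenario(biomass_requirement=0.0)
        assert calibrate_initial_spending(sc, bracket=(1.0, 1e6)) == 1.0

    def test_monotone_in_requirement(self):
        s_lo = calibrate_initial_spending(toy_scenario(biomass_requirement=50.0))
        s_hi = calibrate_initial_spending(toy_scenario(biomass_requirement=100.0))
        assert s_hi >= s_lo

    def test_matches_bruteforce_grid_search(self):
        """Bisection agrees with an exhaustive geometric scan over S0."""
        sc = toy_scenario()

        def min_biomass(s0):
            traj = simulate(sc, s0)
            return traj.loc[traj["year"] >= sc.growth_years, "biomass_t"].min()

        calibrated = calibrate_initial_spending(sc)
        grid = np.geomspace(calibrated / 10, calibrated * 10, 4001)
        feasible = [s for s in grid if min_biomass(s) >= sc.biomass_requirement]
        brute = min(feasible)
        # the scan's resolution is one geometric step, 100**(1/4000) ~ 0.12%
        assert calibrated == pytest.approx(brute, rel=2e-3)

    def test_calibration_is_tight(self):
        sc = toy_scenario()
        s0 = calibrate_initial_spending(sc)
        traj = simulate(sc, s0 * (1 - 1e-4))
        post = traj.loc[traj["year"] >= sc.growth_years, "biomass_t"]
        assert post.min() < sc.biomass_requirement

    def test_unachievable_requirement_raises(self):
        sc = toy_scenario(biomass_requirement=1e30)
        # opex obligations cap operational area at S/opex, so no finite S0 in a
        # bounded bracket satisfies an absurd requirement quickly -> error path
        with pytest.raises(ValueError):
            calibrate_initial_spending(sc, bracket=(1.0, 1e3))

    def test_worst_case_exceeds_best_case(self):
        s_best = calibrate_initial_spending(scenario_preset("best"))
        s_worst = calibrate_initial_spending(scenario_preset("worst"))
        assert s_worst > s_best
        best_plateau = spending_schedule(s_best, scenario_preset("best"))[-1]
        worst_plateau = spending_schedule(s_worst, scenario_preset("worst"))[-1]
        assert worst_plateau > best_plateau


class TestClosedForms:
    def test_steady_state_expense_worst_case(self):
        got = steady_state_expense(1.9e7, 1.0e6, 7.0e4, 20)
        assert got == pytest.approx(2.28e12)

    def test_zero_area(self):
        assert steady_state_expense(0.0, 1e6, 7e4, 20) == 0.0

    def test_infinite_lifetime_limit(self):
        assert steady_state_expense(100.0, 1e6, 7e4, 1e12) == pytest.approx(100.0 * 7e4, rel=1e-6)

    def test_fuel_power_unit_arithmetic(self):
        assert fuel_power(1.0, 31.557) == pytest.approx(1000.0)
        assert fuel_power(0.0) == 0.0

    def test_percent_of(self):
        assert percent_of(5.0, 5.0) == 100.0
        with pytest.raises(ValueError):
            percent_of(1.0, 0.0)


class TestPresets:
    def test_conservative_pairing_lifetimes(self):
        assert scenario_preset("worst", pairing="conservative").lifetime == 20
        assert scenario_preset("best", pairing="conservative").lifetime == 40

    def test_proportional_pairing_lifetimes(self):
        assert scenario_preset("worst", pairing="proportional").lifetime == 40
        assert scenario_preset("best", pairing="proportional").lifetime == 20

    def test_carbon_requirement_scale(self):
        np_req = scenario_preset("worst", nutrient="np").biomass_requirement
        c_req = scenario_preset("worst", nutrient="c").biomass_requirement
        assert c_req / np_req == pytest.approx(2.2e10 / 1.2e9)

    def test_published_endpoints_kept_as_metadata(self):
        assert TABLE_PARAMS["betterNP.bm"] == 3.10e9
        assert TABLE_PARAMS["cap_lo"] == 2.50e5

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            scenario_preset("middling")
        with pytest.raises(ValueError):
            EconScenario(capex=-1, opex=1, lifetime=1)
        with pytest.raises(ValueError):
            EconScenario(capex=1, opex=1, lifetime=0)
        with pytest.raises(ValueError):
            EconScenario(capex=1, opex=1, lifetime=5, growth_years=10, horizon=5)
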