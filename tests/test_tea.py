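"""Biorefinery sizing, CHP utility closure and the DCF/MPSP solver."""

import pytest

from sucpipe.tea import (BiorefineryScenario, DCFParams, ProcessBlock,
                         capital_cost, neutralization_demand, run_tea,
                         size_biorefinery, solve_mpsp, utility_balance)


def _scenario(**kw):
    base = dict(yield_=0.473, titer=63.1, productivity=0.657)
    base.update(kw)
    return BiorefineryScenario(**base)


class TestScenarioValidation:
    def test_yield_above_carbon_ceiling_rejected(self):
        with pytest.raises(ValueError, match="ceiling"):
            _scenario(yield_=1.4)

    def test_unknown_regime_rejected(self):
        with pytest.raises(ValueError, match="regime"):
            _scenario(regime="ph_7")


class TestSizing:
    def test_sugar_demand_is_capacity_over_yield(self, pilot_scenario):
        sized = size_biorefinery(pilot_scenario)
        annual_sugar = sized.per_kg["sugar"] * sized.annual_production
        assert annual_sugar == pytest.approx(26800e3 / 0.473, rel=1e-12)
        assert annual_sugar / 1000 == pytest.approx(56660, abs=10)  # t/y

    def test_doubling_titer_halves_broth_and_evaporation(self):
        lo = size_biorefinery(_scenario(titer=50.0))
        hi = size_biorefinery(_scenario(titer=100.0))
        assert hi.per_kg["broth_L"] == pytest.approx(lo.per_kg["broth_L"] / 2)
        # water per kg falls slightly faster than half (more concentrated broth)
        assert hi.per_kg["water_evaporated"] < lo.per_kg["water_evaporated"] / 2

    def test_neutral_regime_needs_more_base_than_low_ph(self):
        low = neutralization_demand(_scenario(regime="low_pH"))
        neutral = neutralization_demand(_scenario(regime="neutral"))
        assert neutral["naoh"] > low["naoh"]
        assert neutral["h2so4"] > 0 and low["h2so4"] == 0.0
        assert neutral["gypsum"] > 0

    def test_reacidulation_regime_between_the_two(self):
        low = neutralization_demand(_scenario(regime="low_pH"))
        mid = neutralization_demand(_scenario(regime="low_pH_with_reacidulation"))
        neutral = neutralization_demand(_scenario(regime="neutral"))
        assert mid["naoh"] == pytest.approx(low["naoh"])
        assert 0 < mid["h2so4"] < neutral["h2so4"]

    def test_unknown_parameter_rejected(self, pilot_scenario):
        with pytest.raises(ValueError, match="unknown parameter"):
            size_biorefinery(pilot_scenario, {"not_a_knob": 1.0})


class TestUtilityBalance:
    def test_steam_first_covers_heating_then_power(self, pilot_scenario):
        sized = size_biorefinery(pilot_scenario)
        u = utility_balance(sized)
        assert u.steam_available > u.heating_demand  # bagasse-rich baseline
        assert u.electricity_generated > 0
        assert u.net_electricity < 0  # exports at baseline

    def test_zero_boiler_efficiency_purchases_all_heat(self, pilot_scenario):
        sized = size_biorefinery(pilot_scenario)
        u = utility_balance(sized, boiler_efficiency=0.0)
        assert u.steam_available == 0.0
        assert u.electricity_generated == 0.0
        assert u.natural_gas > sized.params["dryer_gas_duty"]

    def test_higher_titer_increases_export(self):
        lo = size_biorefinery(_scenario(titer=55.0))
        hi = size_biorefinery(_scenario(titer=90.0))
        assert utility_balance(hi).net_electricity < utility_balance(lo).net_electricity


class TestCapitalCost:
    def test_base_size_gives_base_cost(self):
        b = ProcessBlock("x", "m", base_size=10.0, base_cost=5e6, exponent=0.6)
        assert b.cost(10.0) == pytest.approx(5e6)

    def test_linear_exponent(self):
        b = ProcessBlock("x", "m", base_size=10.0, base_cost=5e6, exponent=1.0)
        assert b.cost(30.0) == pytest.approx(15e6)

    def test_economy_of_scale_favors_one_large_block(self):
        b = ProcessBlock("x", "m", base_size=1.0, base_cost=1e6, exponent=0.6)
        assert b.cost(2.0) == pytest.approx(2 * b.cost(1.0) * 2**0.6 / 2)
        assert b.cost(2.0) < 2 * b.cost(1.0)

    def test_capital_multiplier_applies(self, pilot_scenario):
        base = capital_cost(size_biorefinery(pilot_scenario))
        up = capital_cost(size_biorefinery(pilot_scenario,
                                           {"capital_multiplier": 1.2}))
        assert up == pytest.approx(1.2 * base)


class TestMpspSolver:
    def test_zero_costs_give_zero_price(self):
        assert solve_mpsp(1e6, 0.0, 0.0) == 0.0

    def test_annuity_closed_form_oracle(self):
        """With no tax, no working capital and instantaneous construction
        the MPSP equals (capital x CRF + opex) / production."""
        r, life = 0.10, 20
        capital, opex, production = 150e6, 12e6, 26.8e6
        dcf = DCFParams(internal_rate_of_return=r, plant_life=life,
                        construction_schedule=(1.0,), income_tax_rate=0.0,
                        working_capital_fraction=0.0)
        crf = r * (1 + r) ** life / ((1 + r) ** life - 1)
        expected = (capital * crf + opex) / production
        assert solve_mpsp(production, capital, opex, dcf) == pytest.approx(
            expected, abs=1e-6)

    def test_mpsp_increasing_in_feedstock_price(self, pilot_scenario):
        prices = [0.03, 0.05, 0.07, 0.09]
        mpsps = [run_tea(pilot_scenario, {"sugarcane_price": p}).mpsp
                 for p in prices]
        assert all(a < b for a, b in zip(mpsps, mpsps[1:]))

    def test_no_sign_change_reports_diagnostics(self):
        with pytest.raises(ValueError, match="bracket"):
            solve_mpsp(1e6, 1e9, 1e9, bracket=(0.0, 1e-9))


class TestRunTea:
    def test_breakdown_sums_to_operating_cost(self, pilot_scenario):
        res = run_tea(pilot_scenario)
        assert sum(res.cost_breakdown.values()) == pytest.approx(
            res.annual_operating_cost, rel=1e-12)
        assert res.mpsp > 0
        assert res.electricity_balance < 0  # net exporter at baseline

    @pytest.mark.parametrize("knob, direction", [
        ("fermentation", "yield_"), ("fermentation", "titer"),
        ("fermentation", "productivity"), ("plant", "uptime")])
    def test_mpsp_non_increasing_in_performance(self, knob, direction):
        lo_kw = dict(yield_=0.40, titer=55.0, productivity=0.5, uptime=0.88)
        hi_kw = dict(lo_kw)
        hi_kw[direction] = {"yield_": 0.60, "titer": 90.0,
                            "productivity": 1.2, "uptime": 0.95}[direction]
        lo = run_tea(_scenario(**{k: v for k, v in lo_kw.items()}))
        hi = run_tea(_scenario(**{k: v for k, v in hi_kw.items()}))
        assert hi.mpsp <= lo.mpsp + 1e-9

    def test_low_ph_dominates_neutral(self, rng):
        for _ in range(10):
            kw = dict(yield_=float(rng.uniform(0.35, 0.65)),
                      titer=float(rng.uniform(45, 110)),
                      productivity=float(rng.uniform(0.4, 1.3)))
            low = run_tea(_scenario(regime="low_pH", **kw)).mpsp
            neutral = run_tea(_scenario(regime="neutral", **kw)).mpsp
            assert low <= neutral
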