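"""End-to-end evaluation: parameter vector -> (MPSP, GWP100, FEC).

The bridge the Monte Carlo sampler and the yield-titer landscape drive:
it assembles a scenario from a flat parameter dict (fermentation
performance + plant + price + impact parameters), runs the block-level
TEA, builds the LCA inventory from the same sized plant, and returns
the three headline metrics.
"""

from __future__ import annotations

from typing import Mapping

from .defaults import BASELINE_PARAMETERS
from .lca import ImpactFactorTable, run_lca
from .tea import (BiorefineryScenario, DCFParams, inventory_per_kg, run_tea,
                  size_biorefinery, utility_balance)

__all__ = ["evaluate", "scenario_from_params"]


def scenario_from_params(params: Mapping[str, float],
                         regime: str = "low_pH",
                         fermentation_ph: float = 3.0) -> BiorefineryScenario:
    p = {**BASELINE_PARAMETERS, **params}
    return BiorefineryScenario(
        yield_=p["fermentation_yield"], titer=p["fermentation_titer"],
        productivity=p["fermentation_productivity"], regime=regime,
        capacity=p["plant_capacity"], uptime=p["plant_uptime"],
        fermentation_ph=fermentation_ph)


def evaluate(params: Mapping[str, float] | None = None,
             regime: str = "low_pH",
             dcf: DCFParams | None = None,
             factors: ImpactFactorTable | None = None) -> dict[str, float]:
    """MPSP ($/kg), GWP100 (kg CO2-eq/kg, cradle-to-grave) and FEC
    (MJ/kg, cradle-to-gate) for one parameter vector."""
    p = {**BASELINE_PARAMETERS, **(params or {})}
    scenario = scenario_from_params(p, regime)
    tea = run_tea(scenario, p, dcf)
    sized = size_biorefinery(scenario, p)
    inv = inventory_per_kg(sized, utility_balance(sized))
    if factors is None:
        factors = ImpactFactorTable.default(overrides={
            "electricity": p["grid_electricity_gwp"],
            "sugarcane": p["sugarcane_gwp"],
        })
    lca = run_lca(inv, factors)
    return {"mpsp": tea.mpsp, "gwp100": lca.gwp100, "fec": lca.fec}
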