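"""Life cycle assessment: GWP100 and fossil energy consumption per kg SA.

Both metrics are linear in the inventory: each input flow (sugarcane,
base, acid, natural gas, net grid electricity, waste disposal) is
multiplied by its characterization factor and summed. Exported
electricity enters as a negative flow and displaces grid impacts, so
both metrics can go negative.

Biogenic carbon convention: carbon fixed into the product from
sugarcane is not credited at the factory gate, and the end-of-life
degradation of the product entirely to CO2 is charged stoichiometrically
(C_count x 44.01 / molar mass = 1.49 kg CO2-eq per kg succinic acid),
making GWP100 cradle-to-grave. FEC is cradle-to-gate and has no
end-of-life term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .defaults import DEFAULT_IMPACT_FACTORS
from .stoichiometry import ATOMIC_MASS, SPECIES

__all__ = ["ImpactFactorTable", "LCAResult", "end_of_life_co2",
           "gwp100", "fec", "run_lca"]

_M_CO2 = ATOMIC_MASS["C"] + 2 * ATOMIC_MASS["O"]  # 44.009


@dataclass(frozen=True)
class ImpactFactorTable:
    """flow -> (unit, GWP100 kg CO2-eq/unit, FEC MJ/unit)."""

    factors: Mapping[str, tuple[str, float, float]]

    @classmethod
    def default(cls, overrides: Mapping[str, float] | None = None
                ) -> "ImpactFactorTable":
        """Built-in synthetic-calibrated table; ``overrides`` replaces GWP
        factors by flow name (used to push uncertain factors through)."""
        table = {name: (d["unit"], d["gwp"], d["fec"])
                 for name, d in DEFAULT_IMPACT_FACTORS.items()}
        for flow, gwp in (overrides or {}).items():
            unit, _, f = table[flow]
            table[flow] = (unit, gwp, f)
        return cls(table)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ImpactFactorTable":
        df = pd.read_csv(path)
        return cls({row["flow"]: (row["unit"], float(row["gwp_factor"]),
                                  float(row["fec_factor"]))
                    for _, row in df.iterrows()})

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [{"flow": k, "unit": u, "gwp_factor": g, "fec_factor": f}
             for k, (u, g, f) in self.factors.items()]
        ).to_csv(path, index=False)

    def gwp(self, flow: str) -> float:
        return self._get(flow)[1]

    def fec(self, flow: str) -> float:
        return self._get(flow)[2]

    def _get(self, flow: str) -> tuple[str, float, float]:
        try:
            return self.factors[flow]
        except KeyError:
            raise KeyError(f"no characterization factor for flow {flow!r}") from None


@dataclass
class LCAResult:
    gwp100: float  # kg CO2-eq / kg SA
    fec: float  # MJ / kg SA
    gwp_breakdown: dict[str, float] = field(default_factory=dict)
    fec_breakdown: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"gwp100_kg_co2e_per_kg": self.gwp100,
                "fec_MJ_per_kg": self.fec,
                "gwp_breakdown": dict(self.gwp_breakdown),
                "fec_breakdown": dict(self.fec_breakdown)}


def end_of_life_co2(formula: Mapping[str, int]) -> float:
    """kg CO2 released per kg product on complete degradation to CO2."""
    c = formula.get("C", 0)
    if c < 1:
        raise ValueError("product must contain carbon")
    molar_mass = sum(ATOMIC_MASS[el] * n for el, n in formula.items())
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    return c * _M_CO2 / molar_mass


def gwp100(inventory: Mapping[str, float], factors: ImpactFactorTable,
           include_end_of_life: bool = True,
           product_formula: Mapping[str, int] | None = None
           ) -> tuple[float, dict[str, float]]:
    """GWP100 of the inventory, kg CO2-eq per kg product, with breakdown.

    Cradle-to-grave when ``include_end_of_life``; negative flows
    (electricity export) displace their grid impact symmetrically.
    """
    breakdown = {flow: qty * factors.gwp(flow) for flow, qty in inventory.items()}
    if include_end_of_life:
        formula = product_formula or SPECIES["succinate"].formula
        breakdown["end_of_life"] = end_of_life_co2(formula)
    return sum(breakdown.values()), breakdown


def fec(inventory: Mapping[str, float], factors: ImpactFactorTable
        ) -> tuple[float, dict[str, float]]:
    """Fossil energy consumption, MJ per kg product (cradle-to-gate)."""
    breakdown = {flow: qty * factors.fec(flow) for flow, qty in inventory.items()}
    return sum(breakdown.values()), breakdown


def run_lca(inventory: Mapping[str, float],
            factors: ImpactFactorTable | None = None,
            include_end_of_life: bool = True) -> LCAResult:
    factors = factors or ImpactFactorTable.default()
    g, gb = gwp100(inventory, factors, include_end_of_life)
    f, fb = fec(inventory, factors)
    return LCAResult(g, f, gb, fb)
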