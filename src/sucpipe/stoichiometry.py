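"""Stoichiometric model of the engineered reductive-TCA succinate pathway.

The cytosolic network of an acid-tolerant yeast engineered for succinic
acid (SA) production is lumped into a handful of reactions: glycolysis
splits each hexose into two triose units (DHAP), lower glycolysis
oxidises each triose to pyruvate with one NADH, and the reductive TCA
branch (pyruvate carboxylase -> malate dehydrogenase -> fumarase ->
fumarate reductase) fixes one CO2 and consumes two NADH per succinate.
A heterologous glycerol route (glycerol dehydrogenase + dihydroxyacetone
kinase) feeds glycerol into the triose pool with one extra NADH, which
is why glucose/glycerol co-feeding relieves the cytosolic redox
bottleneck: glucose alone yields 2 pyruvate but only 2 NADH, capping
succinate at 1 mol/mol, while glycerol delivers 2 NADH per pyruvate.

Maximum-yield queries are posed as small linear programs over reaction
fluxes: carbon-only (the theoretical ceiling, CO2 uptake unbounded) or
carbon + cytosolic NADH balance (the redox-limited yield).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "Species",
    "Reaction",
    "MetabolicNetwork",
    "YieldResult",
    "ATOMIC_MASS",
    "SPECIES",
    "KNOCKOUT_TAGS",
    "build_default_network",
    "glucose_equivalent",
    "max_yield_carbon",
    "max_yield_redox",
    "knockout_yield_delta",
]

ATOMIC_MASS = {"C": 12.011, "H": 1.008, "O": 15.999}

_LP_TOL = 1e-9


@dataclass(frozen=True)
class Species:
    """A metabolite with an elemental formula (C, H, O only)."""

    name: str
    formula: Mapping[str, int]

    def __post_init__(self) -> None:
        bad = set(self.formula) - set(ATOMIC_MASS)
        if bad:
            raise ValueError(f"unsupported elements in {self.name}: {sorted(bad)}")

    @property
    def molar_mass(self) -> float:
        return sum(ATOMIC_MASS[el] * n for el, n in self.formula.items())

    @property
    def carbon_atoms(self) -> int:
        return int(self.formula.get("C", 0))


def _sp(name: str, c: int, h: int, o: int) -> Species:
    return Species(name, {"C": c, "H": h, "O": o})


SPECIES: dict[str, Species] = {
    s.name: s
    for s in [
        _sp("glucose", 6, 12, 6),
        _sp("fructose", 6, 12, 6),
        _sp("sucrose", 12, 22, 11),
        _sp("glycerol", 3, 8, 3),
        _sp("water", 0, 2, 1),
        _sp("dhap", 3, 7, 6),  # dihydroxyacetone phosphate, P not tracked
        _sp("pyruvate", 3, 4, 3),
        _sp("oxaloacetate", 4, 4, 5),
        _sp("malate", 4, 6, 5),
        _sp("fumarate", 4, 4, 4),
        _sp("succinate", 4, 6, 4),
        _sp("ethanol", 2, 6, 1),
        _sp("co2", 1, 0, 2),
    ]
}

#: substrates the network can take up, all quoted on the glucose-equivalent
#: mass basis used for yields
SUBSTRATES = ("glucose", "fructose", "sucrose", "glycerol")

#: products allowed to leave the cytosol
_EXPORTS = ("succinate", "ethanol", "pyruvate", "glycerol")


@dataclass(frozen=True)
class Reaction:
    """One lumped reaction: signed species stoichiometry plus cofactor deltas.

    ``nadh_delta``/``atp_delta``/``co2_delta`` are mol produced (+) or
    consumed (-) per unit flux; CO2 consumption also appears in ``stoich``
    so that carbon is conserved species-wise.
    """

    name: str
    stoich: Mapping[str, float]
    nadh_delta: float = 0.0
    atp_delta: float = 0.0
    deletable_tag: str | None = None

    @property
    def co2_delta(self) -> float:
        return float(self.stoich.get("co2", 0.0))

    def carbon_imbalance(self) -> float:
        return sum(SPECIES[s].carbon_atoms * c for s, c in self.stoich.items())


def _default_reactions() -> list[Reaction]:
    return [
        # invertase: sucrose + H2O -> glucose + fructose
        Reaction("suc2_invertase", {"sucrose": -1, "water": -1, "glucose": 1, "fructose": 1},
                 deletable_tag="SUC2"),
        # upper glycolysis (hexose -> 2 triose), 2 ATP invested
        Reaction("glycolysis_upper_glc", {"glucose": -1, "dhap": 2, "water": 1}, atp_delta=-2),
        Reaction("glycolysis_upper_frc", {"fructose": -1, "dhap": 2, "water": 1}, atp_delta=-2),
        # lower glycolysis: DHAP -> pyruvate + NADH (+2 ATP)
        Reaction("glycolysis_lower", {"dhap": -1, "pyruvate": 1, "water": 1},
                 nadh_delta=1, atp_delta=2),
        # heterologous glycerol route: glycerol -> DHA -> DHAP, one NADH out
        Reaction("glycerol_pagdh_dak", {"glycerol": -1, "dhap": 1, "water": -1},
                 nadh_delta=1, atp_delta=-1, deletable_tag="PaGDH-DAK"),
        # glycerol-3-phosphate shunt back to glycerol (NADH drain)
        Reaction("gpd_glycerol_formation", {"dhap": -1, "glycerol": 1, "water": 1},
                 nadh_delta=-1, deletable_tag="GPD"),
        # reductive TCA lump: PYC/MDH/FUMR/FRD, fixes 1 CO2, eats 2 NADH
        Reaction("rtca_succinate", {"pyruvate": -1, "co2": -1, "succinate": 1},
                 nadh_delta=-2, atp_delta=-1, deletable_tag="FRD"),
        # pyruvate decarboxylase + alcohol dehydrogenase lump
        Reaction("pdc_adh_ethanol", {"pyruvate": -1, "ethanol": 1, "co2": 1},
                 nadh_delta=-1, deletable_tag="PDC"),
        # external NADH dehydrogenase: cytosolic NADH sink
        Reaction("nde_nadh_oxidation", {}, nadh_delta=-1, deletable_tag="NDE"),
    ]


KNOCKOUT_TAGS = frozenset(
    r.deletable_tag for r in _default_reactions() if r.deletable_tag
) | {"g3473"}  # dicarboxylic acid importer: uptake never modelled, no-op tag


@dataclass
class MetabolicNetwork:
    """Lumped cytosolic network with substrate/product declarations."""

    species: dict[str, Species]
    reactions: list[Reaction]
    substrates: tuple[str, ...] = SUBSTRATES
    objective_product: str = "succinate"

    def __post_init__(self) -> None:
        names = [r.name for r in self.reactions]
        if len(names) != len(set(names)):
            raise ValueError("duplicate reaction names in network")
        for r in self.reactions:
            if abs(r.carbon_imbalance()) > 1e-9:
                raise ValueError(f"reaction {r.name} does not conserve carbon")

    def without(self, tags: Iterable[str]) -> "MetabolicNetwork":
        tags = set(tags)
        unknown = tags - KNOCKOUT_TAGS
        if unknown:
            raise ValueError(f"unknown knockout label(s): {sorted(unknown)}")
        kept = [r for r in self.reactions if r.deletable_tag not in tags]
        return MetabolicNetwork(self.species, kept, self.substrates,
                                self.objective_product)

    def reaction(self, name: str) -> Reaction:
        for r in self.reactions:
            if r.name == name:
                return r
        raise KeyError(name)

    def to_dict(self) -> dict:
        """Serializable form (species, reactions, tags) for config files."""
        return {
            "species": {s.name: dict(s.formula) for s in self.species.values()},
            "reactions": [
                {"name": r.name, "stoich": dict(r.stoich),
                 "nadh_delta": r.nadh_delta, "atp_delta": r.atp_delta,
                 "deletable_tag": r.deletable_tag}
                for r in self.reactions
            ],
            "substrates": list(self.substrates),
            "objective_product": self.objective_product,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "MetabolicNetwork":
        species = {name: Species(name, dict(formula))
                   for name, formula in data["species"].items()}
        reactions = [Reaction(r["name"], dict(r["stoich"]),
                              float(r.get("nadh_delta", 0.0)),
                              float(r.get("atp_delta", 0.0)),
                              r.get("deletable_tag"))
                     for r in data["reactions"]]
        return cls(species, reactions, tuple(data["substrates"]),
                   data["objective_product"])


@dataclass
class YieldResult:
    """Outcome of a maximum-yield LP.

    molar_yield is mol product per mol limiting substrate (single
    substrate) or per mol total substrate (mixes); mass_yield is on the
    g/g glucose-equivalent basis used throughout for fermentation yields.
    """

    molar_yield: float
    mass_yield: float
    binding_constraint: str  # "carbon" | "NADH" | "none"
    fluxes: dict[str, float] = field(default_factory=dict)
    product_mol: float = 0.0

    def to_dict(self) -> dict:
        return {
            "molar_yield": self.molar_yield,
            "mass_yield_g_per_g_glucose_equivalent": self.mass_yield,
            "binding_constraint": self.binding_constraint,
            "product_mol": self.product_mol,
            "fluxes": dict(self.fluxes),
        }


def build_default_network(knockouts: Iterable[str] = ()) -> MetabolicNetwork:
    """The engineered-pathway network with the given gene tags deleted.

    Tags: PDC, GPD, NDE, FRD, SUC2, PaGDH-DAK, g3473 (importer; carried
    for strain bookkeeping, no modelled reaction).
    """
    net = MetabolicNetwork(dict(SPECIES), _default_reactions())
    return net.without(knockouts) if knockouts else net


def glucose_equivalent(substrate_masses: Mapping[str, float]) -> float:
    """Total substrate mass on the glucose-equivalent basis (grams).

    Glucose, fructose and glycerol count 1:1 by mass (the carbon-equivalent
    convention under which 1 g glycerol == 1 g glucose); sucrose counts on
    the hydrolysis basis, gaining one water per glycosidic bond
    (x 2*M_glucose/M_sucrose ~= 1.0527).
    """
    total = 0.0
    for name, mass in substrate_masses.items():
        if name not in SUBSTRATES:
            raise ValueError(f"unknown substrate: {name!r}")
        if mass < 0:
            raise ValueError(f"negative mass for {name}: {mass}")
        if name == "sucrose":
            factor = 2 * SPECIES["glucose"].molar_mass / SPECIES["sucrose"].molar_mass
        else:
            factor = 1.0
        total += mass * factor
    return total


def _solve_lp(net: MetabolicNetwork, substrate_mol: Mapping[str, float],
              redox_balance: bool, nde_flux: float | None = None) -> YieldResult | None:
    """Maximize succinate export for a fixed substrate charge (mol).

    Variables: one flux per reaction (>=0) plus one export flux per
    product. Internal species balance exactly; substrates are supplied
    as a fixed external charge; CO2 exchanges freely in both directions.
    Alternate optima are resolved by a secondary minimum-total-flux pass.
    """
    rxns = net.reactions
    exports = [p for p in _EXPORTS if p in net.species]
    n_r, n_e = len(rxns), len(exports)
    n = n_r + n_e

    internal = [s for s in net.species
                if s not in ("co2", "water") and s not in net.substrates]
    rows, rhs = [], []
    for sp in internal:
        row = np.zeros(n)
        for j, r in enumerate(rxns):
            row[j] = r.stoich.get(sp, 0.0)
        for k, p in enumerate(exports):
            if p == sp:
                row[n_r + k] = -1.0
        rows.append(row)
        rhs.append(0.0)
    # substrates: consumption must not exceed the supplied charge
    a_ub, b_ub = [], []
    for sub in net.substrates:
        row = np.zeros(n)
        for j, r in enumerate(rxns):
            row[j] = -r.stoich.get(sub, 0.0)  # uptake is negative stoich
        for k, p in enumerate(exports):
            if p == sub:
                row[n_r + k] = 1.0  # re-export counts against the charge
        a_ub.append(row)
        b_ub.append(float(substrate_mol.get(sub, 0.0)))
    if redox_balance:
        row = np.zeros(n)
        for j, r in enumerate(rxns):
            row[j] = r.nadh_delta
        rows.append(row)
        rhs.append(0.0)
    if nde_flux is not None:
        row = np.zeros(n)
        for j, r in enumerate(rxns):
            if r.deletable_tag == "NDE":
                row[j] = 1.0
        if not row.any():
            raise ValueError("cannot force NDE flux: NDE reaction not in network")
        rows.append(row)
        rhs.append(float(nde_flux))

    try:
        obj_idx = n_r + exports.index(net.objective_product)
    except ValueError:
        return None
    c = np.zeros(n)
    c[obj_idx] = -1.0
    res = linprog(c, A_ub=np.array(a_ub), b_ub=np.array(b_ub),
                  A_eq=np.array(rows), b_eq=np.array(rhs),
                  bounds=[(0, None)] * n, method="highs",
                  options={"primal_feasibility_tolerance": _LP_TOL})
    if not res.success:
        return None
    best = -res.fun
    # secondary objective: minimum total flux at the optimum (determinism)
    a_eq2 = np.vstack([np.array(rows), c.reshape(1, -1)])
    b_eq2 = np.append(np.array(rhs), -best)
    res2 = linprog(np.ones(n), A_ub=np.array(a_ub), b_ub=np.array(b_ub),
                   A_eq=a_eq2, b_eq=b_eq2, bounds=[(0, None)] * n,
                   method="highs")
    x = res2.x if res2.success else res.x
    fluxes = {r.name: float(x[j]) for j, r in enumerate(rxns)}
    fluxes.update({f"export_{p}": float(x[n_r + k]) for k, p in enumerate(exports)})
    return YieldResult(0.0, 0.0, "none", fluxes, product_mol=float(best))


def _finalize(net: MetabolicNetwork, substrate_mol: Mapping[str, float],
              result: YieldResult | None, redox: bool,
              nde_flux: float | None = None) -> YieldResult:
    if result is None or result.product_mol <= _LP_TOL * 10:
        return YieldResult(0.0, 0.0, "none", result.fluxes if result else {})
    total_mol = sum(substrate_mol.values())
    ge_mass = glucose_equivalent({
        s: m * net.species[s].molar_mass for s, m in substrate_mol.items()
    })
    prod_mass = result.product_mol * net.species[net.objective_product].molar_mass
    result.molar_yield = result.product_mol / total_mol
    result.mass_yield = prod_mass / ge_mass if ge_mass > 0 else 0.0
    if redox:
        ceiling = _solve_lp(net, substrate_mol, redox_balance=False)
        carbon_max = ceiling.product_mol if ceiling else 0.0
        result.binding_constraint = (
            "NADH" if result.product_mol < carbon_max - 1e-7 else "carbon"
        )
    else:
        result.binding_constraint = "carbon"
    return result


def max_yield_carbon(net: MetabolicNetwork, substrate: str) -> YieldResult:
    """Theoretical maximum yield under carbon balance only.

    CO2 uptake is unbounded and the NADH balance is relaxed, so this is
    the carbon-ceiling yield (1.31 g/g for glucose via the CO2-fixing
    reductive TCA branch: 2 mol succinate per mol glucose).
    """
    if substrate not in net.substrates:
        raise ValueError(f"unknown substrate: {substrate!r}")
    mol = {substrate: 1.0}
    res = _solve_lp(net, mol, redox_balance=False)
    return _finalize(net, mol, res, redox=False)


def max_yield_redox(net: MetabolicNetwork,
                    substrate_masses: Mapping[str, float],
                    nde_flux: float | None = None) -> YieldResult:
    """Maximum yield under carbon AND cytosolic NADH balance.

    ``nde_flux`` forces that many mol NADH per mol total substrate through
    the external NADH dehydrogenase drain (if present in the network).
    """
    masses = {s: m for s, m in substrate_masses.items() if m != 0}
    for s, m in masses.items():
        if s not in net.substrates:
            raise ValueError(f"unknown substrate: {s!r}")
        if m < 0:
            raise ValueError(f"negative substrate mass: {s}={m}")
    if not masses:
        raise ValueError("all substrate masses are zero")
    mol = {s: m / net.species[s].molar_mass for s, m in masses.items()}
    forced = None if nde_flux is None else nde_flux * sum(mol.values())
    res = _solve_lp(net, mol, redox_balance=True, nde_flux=forced)
    return _finalize(net, mol, res, redox=True, nde_flux=nde_flux)


def knockout_yield_delta(net: MetabolicNetwork, gene: str,
                         substrate_masses: Mapping[str, float],
                         forced_flux: float = 0.0) -> float:
    """Change in redox-limited mass yield when ``gene`` is knocked out.

    The wild-type reference forces ``forced_flux`` mol per mol substrate
    through the gene's reaction when it is a pure drain (NDE); the
    knockout removes the reaction entirely.
    """
    if gene not in KNOCKOUT_TAGS:
        raise ValueError(f"unknown gene label: {gene!r}")
    with_gene = max_yield_redox(
        net, substrate_masses,
        nde_flux=forced_flux if gene == "NDE" else None,
    )
    without = max_yield_redox(net.without({gene}), substrate_masses)
    return without.mass_yield - with_gene.mass_yield
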