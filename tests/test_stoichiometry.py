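"""Stoichiometric network construction and maximum-yield LPs.

The closed-form oracle used throughout: with the lumped network, each
hexose gives 2 pyruvate + 2 NADH, each sucrose hydrolyses to two
hexoses, and each glycerol gives 1 pyruvate + 2 NADH via the
heterologous route; succinate consumes 1 pyruvate + 1 CO2 + 2 NADH, so
the redox-limited optimum is min(total NADH / 2, total pyruvate) and
the carbon-only optimum is total pyruvate (CO2 uptake unbounded).
"""

import numpy as np
import pytest

from sucpipe.stoichiometry import (SPECIES, build_default_network,
                                   glucose_equivalent, knockout_yield_delta,
                                   max_yield_carbon, max_yield_redox)

M_GLC = SPECIES["glucose"].molar_mass
M_SUC = SPECIES["succinate"].molar_mass


def _oracle_succinate_mol(mol):
    """Independent closed form for the redox-limited succinate optimum."""
    n_g = mol.get("glucose", 0.0)
    n_f = mol.get("fructose", 0.0)
    n_s = mol.get("sucrose", 0.0)
    n_y = mol.get("glycerol", 0.0)
    pyruvate = 2 * n_g + 2 * n_f + 4 * n_s + n_y
    nadh = 2 * n_g + 2 * n_f + 4 * n_s + 2 * n_y
    return min(nadh / 2.0, pyruvate)


class TestNetworkConstruction:
    def test_full_network_has_all_reactions(self, network):
        names = {r.name for r in network.reactions}
        assert {"rtca_succinate", "pdc_adh_ethanol", "gpd_glycerol_formation",
                "nde_nadh_oxidation", "suc2_invertase",
                "glycerol_pagdh_dak"} <= names

    def test_knockouts_remove_tagged_reactions(self):
        net = build_default_network({"PDC", "GPD", "g3473"})
        names = {r.name for r in net.reactions}
        assert "pdc_adh_ethanol" not in names
        assert "gpd_glycerol_formation" not in names
        assert "rtca_succinate" in names

    def test_unknown_knockout_label_is_named_in_error(self):
        with pytest.raises(ValueError, match="NOPE"):
            build_default_network({"NOPE"})

    def test_every_reaction_conserves_carbon(self, network):
        for r in network.reactions:
            assert r.carbon_imbalance() == pytest.approx(0.0, abs=1e-12)

    def test_network_config_round_trip(self, network, tmp_path):
        import yaml

        from sucpipe.stoichiometry import MetabolicNetwork

        path = tmp_path / "network.yaml"
        path.write_text(yaml.safe_dump(network.to_dict()))
        back = MetabolicNetwork.from_dict(yaml.safe_load(path.read_text()))
        assert [r.name for r in back.reactions] == [r.name for r in network.reactions]
        res = max_yield_redox(back, {"glucose": M_GLC})
        assert res.molar_yield == pytest.approx(1.0, abs=1e-9)

    def test_species_masses_consistent_with_formulas(self):
        # spot-check against standard molar masses
        assert SPECIES["glucose"].molar_mass == pytest.approx(180.16, abs=0.1)
        assert SPECIES["succinate"].molar_mass == pytest.approx(118.09, abs=0.1)
        assert SPECIES["sucrose"].molar_mass == pytest.approx(342.30, abs=0.1)
        assert SPECIES["glycerol"].carbon_atoms == 3


class TestGlucoseEquivalent:
    @pytest.mark.parametrize("masses, expected", [
        ({"glucose": 50.0, "glycerol": 20.0}, 70.0),
        ({"glucose": 50.0}, 50.0),
        ({"fructose": 30.0, "glucose": 10.0}, 40.0),
        ({}, 0.0),
    ])
    def test_mass_basis(self, masses, expected):
        assert glucose_equivalent(masses) == pytest.approx(expected)

    def test_sucrose_hydrolysis_gain(self):
        # 100 g sucrose -> 2 glucose units per sucrose, water gained
        expected = 100.0 * 2 * SPECIES["glucose"].molar_mass / SPECIES["sucrose"].molar_mass
        assert glucose_equivalent({"sucrose": 100.0}) == pytest.approx(expected)
        assert expected == pytest.approx(105.27, abs=0.01)

    def test_negative_mass_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            glucose_equivalent({"glucose": -1.0})

    def test_unknown_substrate_rejected(self):
        with pytest.raises(ValueError, match="xylose"):
            glucose_equivalent({"xylose": 10.0})


class TestCarbonCeiling:
    def test_glucose_ceiling_two_mol_per_mol(self, network):
        res = max_yield_carbon(network, "glucose")
        assert res.molar_yield == pytest.approx(2.0, abs=1e-9)
        assert res.mass_yield == pytest.approx(2 * M_SUC / M_GLC, abs=1e-9)
        assert res.mass_yield == pytest.approx(1.31, abs=0.005)
        assert res.binding_constraint == "carbon"

    def test_glycerol_ceiling_one_mol_per_mol(self, network):
        assert max_yield_carbon(network, "glycerol").molar_yield == pytest.approx(1.0, abs=1e-9)

    def test_frd_knockout_gives_zero_not_exception(self):
        net = build_default_network({"FRD"})
        res = max_yield_carbon(net, "glucose")
        assert res.mass_yield == 0.0
        assert res.binding_constraint == "none"

    def test_unknown_substrate_errors(self, network):
        with pytest.raises(ValueError):
            max_yield_carbon(network, "starch")


class TestRedoxLimitedYield:
    def test_glucose_limited_to_one_mol_per_mol(self, network):
        res = max_yield_redox(network, {"glucose": M_GLC})
        assert res.molar_yield == pytest.approx(1.0, abs=1e-9)
        assert res.binding_constraint == "NADH"

    def test_glycerol_nadh_exactly_balanced(self, network):
        res = max_yield_redox(network, {"glycerol": SPECIES["glycerol"].molar_mass})
        assert res.molar_yield == pytest.approx(1.0, abs=1e-9)
        # 2 NADH produced (route + lower glycolysis), 2 consumed by rTCA
        net_nadh = sum(r.nadh_delta * res.fluxes[r.name] for r in network.reactions)
        assert net_nadh == pytest.approx(0.0, abs=1e-9)

    def test_glucose_glycerol_mix_yield(self, network):
        res = max_yield_redox(network, {"glucose": 50.0, "glycerol": 20.0})
        assert res.product_mol == pytest.approx(0.4947, abs=2e-4)
        assert res.mass_yield == pytest.approx(0.835, abs=1e-3)
        assert res.binding_constraint == "NADH"

    def test_all_zero_substrates_error(self, network):
        with pytest.raises(ValueError):
            max_yield_redox(network, {"glucose": 0.0})

    def test_lp_matches_closed_form_on_random_mixes(self, network, rng):
        """LP vs independent closed-form optimum on 100 random mixes."""
        subs = ["glucose", "fructose", "sucrose", "glycerol"]
        for _ in range(100):
            masses = {s: float(m) for s, m in
                      zip(subs, rng.uniform(0.0, 100.0, 4))
                      if m > 1e-6}
            if not masses:
                continue
            mol = {s: m / SPECIES[s].molar_mass for s, m in masses.items()}
            res = max_yield_redox(network, masses)
            assert res.product_mol == pytest.approx(
                _oracle_succinate_mol(mol), rel=1e-7, abs=1e-9)

    def test_redox_never_exceeds_carbon_ceiling(self, network, rng):
        for _ in range(25):
            masses = {"glucose": float(rng.uniform(1, 100)),
                      "glycerol": float(rng.uniform(0, 100))}
            redox = max_yield_redox(network, masses)
            mol = {s: m / SPECIES[s].molar_mass for s, m in masses.items()}
            carbon_opt = 2 * mol["glucose"] + mol.get("glycerol", 0.0)
            assert redox.product_mol <= carbon_opt + 1e-9

    def test_carbon_conservation_in_lp_solution(self, network):
        """Substrate carbon + fixed CO2 == product carbon + released CO2."""
        res = max_yield_redox(network, {"glucose": 90.0, "glycerol": 30.0})
        f = res.fluxes
        consumed_c = 0.0
        for r in network.reactions:
            for sp, coeff in r.stoich.items():
                if sp in ("glucose", "fructose", "sucrose", "glycerol") and coeff < 0:
                    consumed_c += -coeff * f[r.name] * SPECIES[sp].carbon_atoms
        export_c = sum(f[f"export_{p}"] * SPECIES[p].carbon_atoms
                       for p in ("succinate", "ethanol", "pyruvate", "glycerol"))
        net_co2_released = sum(r.co2_delta * f[r.name] for r in network.reactions)
        assert consumed_c + max(-net_co2_released, 0.0) == pytest.approx(
            export_c + max(net_co2_released, 0.0), rel=1e-9)


class TestKnockoutDeltas:
    def test_inactive_nde_drain_changes_nothing(self, network):
        delta = knockout_yield_delta(network, "NDE", {"glucose": M_GLC},
                                     forced_flux=0.0)
        assert delta == pytest.approx(0.0, abs=1e-9)

    def test_forced_nde_flux_costs_half_its_nadh_in_succinate(self, network):
        # 0.2 mol NADH drained per mol glucose -> 0.1 mol succinate lost
        delta = knockout_yield_delta(network, "NDE", {"glucose": M_GLC},
                                     forced_flux=0.2)
        assert delta == pytest.approx(0.1 * M_SUC / M_GLC, abs=1e-9)

    def test_pdc_knockout_neutral_at_lp_optimum(self, network):
        # the optimum never routes carbon to ethanol, so removing PDC is free
        delta = knockout_yield_delta(network, "PDC", {"glucose": 100.0})
        assert delta == pytest.approx(0.0, abs=1e-9)

    def test_unknown_gene_errors(self, network):
        with pytest.raises(ValueError):
            knockout_yield_delta(network, "XYZ", {"glucose": 10.0})
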