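"""Default parameter, price and impact-factor tables for the block-level
sugarcane-to-succinic-acid biorefinery surrogate.

Every entry is a model parameter a user can override via config; the
table doubles as the uncertain-parameter set for Monte Carlo (name ->
(baseline, kind, lower, mode, upper)). Baselines anchored to printed
process anchors where available (sugarcane at $49.3 per dry metric ton,
annual capacity 26,800 t SA, pilot fermentation 0.473 g/g, 63.1 g/L,
0.657 g/L/h); the remaining coefficients are documented surrogate
choices calibrated so that the default pilot scenario lands in a
plausible cost/impact range, and they carry synthetic uncertainty
bounds. Impact factors are a synthetic-calibrated placeholder table;
users supply real characterization factors via config for serious LCA.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Uncertain / tunable model parameters.
# kind: "triangular" (lower, mode, upper) or "uniform" (lower, upper).
# Units in the comment; "per kg" means per kg succinic acid product.
DEFAULT_PARAMETERS: dict[str, dict] = {
    # fermentation performance (pilot batch baseline)
    "fermentation_yield":        dict(baseline=0.473, kind="triangular", lower=0.40, mode=0.473, upper=0.55),   # g/g glucose-eq
    "fermentation_titer":        dict(baseline=63.1,  kind="triangular", lower=50.0, mode=63.1,  upper=80.0),   # g/L
    "fermentation_productivity": dict(baseline=0.657, kind="triangular", lower=0.50, mode=0.657, upper=1.0),    # g/L/h
    # plant
    "plant_uptime":              dict(baseline=0.90,  kind="uniform",    lower=0.85, upper=0.96),               # fraction of year
    "plant_capacity":            dict(baseline=26800.0, kind="triangular", lower=21440.0, mode=26800.0, upper=32160.0),  # t SA/y
    # engineering setting, excluded from the uncertain set
    "working_volume_fraction":   dict(baseline=0.80,  kind="uniform",    lower=0.70, upper=0.90, uncertain=False),
    "dsp_recovery":              dict(baseline=0.92,  kind="triangular", lower=0.85, mode=0.92, upper=0.97),    # SA recovered overall
    # feedstock & conversion coefficients
    "sugarcane_price":           dict(baseline=0.0493, kind="triangular", lower=0.040, mode=0.0493, upper=0.060),  # $/kg dry
    "juice_sugar_content":       dict(baseline=0.45,  kind="triangular", lower=0.40, mode=0.45, upper=0.50),    # kg sugar/kg dry cane
    "bagasse_fraction":          dict(baseline=0.42,  kind="triangular", lower=0.37, mode=0.42, upper=0.47),    # kg fuel/kg dry cane
    "bagasse_lhv":               dict(baseline=18.0,  kind="triangular", lower=16.0, mode=18.0, upper=19.5),    # MJ/kg
    # utilities
    "boiler_efficiency":         dict(baseline=0.80,  kind="triangular", lower=0.70, mode=0.80, upper=0.85),
    "turbine_efficiency":        dict(baseline=0.30,  kind="triangular", lower=0.24, mode=0.30, upper=0.35),
    "steam_per_kg_water":        dict(baseline=0.55,  kind="triangular", lower=0.40, mode=0.55, upper=0.75),    # MJ steam/kg water evaporated (multi-effect)
    "process_heat_fixed":        dict(baseline=1.00,  kind="triangular", lower=0.70, mode=1.00, upper=1.40),    # MJ/kg (sterilization etc.)
    "dryer_gas_duty":            dict(baseline=0.80,  kind="triangular", lower=0.60, mode=0.80, upper=1.10),    # MJ natural gas/kg (direct-fired)
    "electricity_fixed":         dict(baseline=0.20,  kind="triangular", lower=0.15, mode=0.20, upper=0.28),    # kWh/kg (pumps, filtration)
    "fermenter_power":           dict(baseline=220.0, kind="triangular", lower=160.0, mode=220.0, upper=300.0), # W/m3 broth
    # chemical & energy prices (2016$)
    "naoh_price":                dict(baseline=0.50,  kind="triangular", lower=0.40, mode=0.50, upper=0.65),    # $/kg
    "h2so4_price":               dict(baseline=0.090, kind="triangular", lower=0.070, mode=0.090, upper=0.115), # $/kg
    "gypsum_disposal_price":     dict(baseline=0.030, kind="triangular", lower=0.020, mode=0.030, upper=0.045), # $/kg
    "natural_gas_price":         dict(baseline=0.0040, kind="triangular", lower=0.0030, mode=0.0040, upper=0.0055),  # $/MJ
    "electricity_price":         dict(baseline=0.068, kind="triangular", lower=0.055, mode=0.068, upper=0.085), # $/kWh
    "other_materials_cost":      dict(baseline=0.020, kind="triangular", lower=0.012, mode=0.020, upper=0.030), # $/kg (water, nutrients, seed)
    # financial
    "fixed_opex_fraction":       dict(baseline=0.060, kind="triangular", lower=0.045, mode=0.060, upper=0.080), # /y of installed capital
    "capital_multiplier":        dict(baseline=1.00,  kind="triangular", lower=0.80, mode=1.00, upper=1.30),
    "income_tax_rate":           dict(baseline=0.21,  kind="uniform",    lower=0.18, upper=0.28),
    # key impact factors carried as uncertain parameters
    "grid_electricity_gwp":      dict(baseline=0.48,  kind="triangular", lower=0.40, mode=0.48, upper=0.58),    # kg CO2-eq/kWh
    "sugarcane_gwp":             dict(baseline=0.045, kind="triangular", lower=0.030, mode=0.045, upper=0.065), # kg CO2-eq/kg dry
}

#: flat baseline values, the form most model calls take
BASELINE_PARAMETERS: dict[str, float] = {
    name: entry["baseline"] for name, entry in DEFAULT_PARAMETERS.items()
}

#: the 28 parameters carrying uncertainty in the Monte Carlo analysis
UNCERTAIN_PARAMETERS: tuple[str, ...] = tuple(
    name for name, entry in DEFAULT_PARAMETERS.items()
    if entry.get("uncertain", True)
)

# ---------------------------------------------------------------------------
# Life-cycle characterization factors per unit flow. Electricity and
# sugarcane GWP are overridden by the parameter table at run time so that
# they participate in the uncertainty analysis.
DEFAULT_IMPACT_FACTORS: dict[str, dict] = {
    # flow: unit, GWP100 (kg CO2-eq/unit), FEC (MJ fossil/unit)
    "sugarcane":    dict(unit="kg dry", gwp=0.045, fec=0.60),
    "naoh":         dict(unit="kg",     gwp=1.10,  fec=20.0),
    "h2so4":        dict(unit="kg",     gwp=0.13,  fec=1.6),
    "gypsum":       dict(unit="kg",     gwp=0.02,  fec=0.20),
    "natural_gas":  dict(unit="MJ",     gwp=0.068, fec=1.12),
    "electricity":  dict(unit="kWh",    gwp=0.48,  fec=8.0),
}

# ---------------------------------------------------------------------------
# Process blocks: installed base cost ($, 2016) at a base size, with a
# power-law scaling exponent. Base sizes correspond to the pilot-baseline
# plant (26,800 t/y) so the default scenario prices the base plant.
DEFAULT_BLOCKS: list[dict] = [
    dict(name="feedstock_juicing", size_metric="cane_flow_kg_h",
         base_size=17500.0, base_cost=40e6, exponent=0.6),
    dict(name="fermentation", size_metric="fermenter_volume_m3",
         base_size=6500.0, base_cost=42e6, exponent=0.6),
    dict(name="separation", size_metric="water_evaporated_kg_h",
         base_size=50000.0, base_cost=32e6, exponent=0.6),
    dict(name="chp", size_metric="fuel_MJ_h",
         base_size=125000.0, base_cost=40e6, exponent=0.6),
    dict(name="facilities", size_metric="production_kg_h",
         base_size=3400.0, base_cost=22e6, exponent=0.6),
]

# ---------------------------------------------------------------------------
# The three fermentation scenarios of the study (yield g/g glucose-eq,
# titer g/L, productivity g/L/h), all low-pH.
NAMED_SCENARIOS: dict[str, dict] = {
    "lab_batch":     dict(yield_=0.60,  titer=41.9,  productivity=0.44),
    "lab_fed_batch": dict(yield_=0.63,  titer=104.6, productivity=1.25),
    "pilot_batch":   dict(yield_=0.473, titer=63.1,  productivity=0.657),
}

#: carbon-balance theoretical maximum yield, g/g glucose-equivalent
#: (2 mol succinate per mol glucose via the CO2-fixing reductive TCA route)
THEORETICAL_MAX_YIELD = 2 * 118.088 / 180.156
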