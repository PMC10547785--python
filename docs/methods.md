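# Methods

This note documents the models behind `sucpipe`, their assumptions,
the defaults that matter, and what the synthetic-data generators do and
do not emulate.

## Stoichiometric yield model

The engineered pathway is lumped into nine cytosolic reactions:
invertase (SUC2), upper glycolysis for glucose and fructose (hexose →
2 triose), lower glycolysis (DHAP → pyruvate, +1 NADH), the
heterologous glycerol route (glycerol → DHAP, +1 NADH; so 2 NADH per
pyruvate from glycerol), glycerol formation (GPD, −1 NADH), the
reductive TCA lump (pyruvate + CO2 + 2 NADH → succinate, collapsing
pyruvate carboxylase / malate dehydrogenase / fumarase / fumarate
reductase; the intermediates OAA, malate and fumarate are represented
as species but never accumulate), ethanol formation (PDC+ADH, −1
NADH), and an external NADH dehydrogenase drain (NDE). Each reaction
carries a deletable gene tag so knockouts are a mask over the network.

Maximum-yield queries are linear programs (scipy HiGHS, feasibility
tolerance 1e-9) over non-negative fluxes with steady-state balances on
internal species. CO2 and water exchange freely; pyruvate, ethanol,
glycerol and succinate may be exported. Carbon-only mode drops the
NADH row (the theoretical ceiling); redox mode enforces net cytosolic
NADH = 0. Degenerate alternate optima are resolved by a second LP
minimizing total flux at the fixed optimum, so flux vectors are
deterministic. ATP is tracked per reaction but not constrained: the
yield arguments rest on carbon and redox only, and an ATP balance
would require a maintenance model the data do not support.

Choices worth noting:

- **Glucose-equivalent basis.** Glucose, fructose and glycerol count
  1:1 by mass; sucrose counts ×2·M_glc/M_sucrose = 1.0527 (hydrolysis
  gains one water per glycosidic bond). The convention for sucrose is
  not standardized in the field; the hydrolysis basis is used because
  fermentation sees the hydrolysed monomers.
- **Fructose** is treated as glycolytically identical to glucose.
- **Biomass** is excluded from the ceiling calculation: the 1.31 g/g
  carbon ceiling is a pathway property, not a fermentation prediction.
- The closed form used as a test oracle: succinate = min(NADH/2,
  pyruvate) with NADH = 2·hexose + 2·glycerol (+4·sucrose) and
  pyruvate = 2·hexose + glycerol (+4·sucrose).

## Fermentation metrics

Titer is the product concentration at the end of the evaluation
interval; productivity is overall (Δproduct / Δt), which is how batch
numbers like 46.0 g/L at 48 h → 0.96 g/L/h reconcile; yield divides
product formed by glucose-equivalent substrate *consumed* (initial
charge + feeds − residual), both expressed per litre of **final**
working volume. The dilution convention for fed-batch yields is not
uniquely determined by endpoint data; final working volume is used
because product and residual substrate are measured in it. Negative
computed consumption beyond 1e-6 is treated as a mass-balance error
rather than clipped.

## Scale-up

Standard ungassed stirred-tank correlations with water-like rheology:
Re = ρND²/μ, P = Np·ρN³D⁵ (turbulent power number, default Np = 5.0,
Rushton-type), tip speed πND. Power per volume and Reynolds number
cannot in general be matched simultaneously with fixed geometry, so
`match_scale` matches P/V exactly (solving N_pilot = (P/V ·
V/(Np·ρ·D⁵))^{1/3}) and reports the Reynolds ratio as the quantified
compromise. Gassed-power corrections and kLa/oxygen transfer are out
of scope.

## Downstream processing

Diprotic speciation uses the standard equilibrium fractions with
denominator 1 + 10^(pH−pKa1) + 10^(2pH−pKa1−pKa2); defaults pKa1 =
4.21, pKa2 = 5.64 (25 °C literature values, configurable). At pH 3
this gives 94.2% fully protonated acid; reports of "approximately 90%"
in the literature imply a slightly different assumed pKa1, so the pKa
values are exposed as parameters rather than hard-coded.

The crystallization train treats stage yields as empirical inputs
(settings: 1% w/v seed loading, seed at 10 °C, 4 h, 0.56 g relative
agitation, crystallization at 0 °C are carried as stage metadata
defaults). Stages compose sequentially on the SA remaining in the
filtrate — overall recovery 1 − Π(1 − yᵢ), e.g. stage yields 31.0% and
47.7% → 63.9% ≈ 64% — with a vacuum-concentration step (default to
50% of volume, no SA loss to vapour) between stages. Published
stage-wise masses (1.98 g + 2.10 g from 6.31 g) sum to a slightly
different overall figure than the composed yields (64.7% vs 64.0%),
reflecting rounding of the reported stage yields; the sequential
composition is adopted as the defining identity. No nucleation or
solubility model is fitted: predicting stage yields from
thermodynamics is explicitly out of scope.

## Block-level TEA

The biorefinery is a set of block surrogates, not a rigorous
flowsheet. Per kg SA product: sugar demand 1/Y; dry sugarcane demand
(1/Y)/juice-sugar-content (default 0.45 kg fermentable sugar per kg
dry cane); bagasse fuel 0.42 kg/kg dry cane at 18 MJ/kg; broth to
separate 1000/(T·r_dsp) L with r_dsp = 0.92 the separation recovery;
evaporation water ≈ broth × (1 − T/1000); multi-effect evaporation
steam economy 0.55 MJ steam per kg water; a direct-fired dryer burns
0.8 MJ natural gas per kg. Neutralization chemistry by regime:

- **low_pH** — base only for the deprotonated fraction at the
  fermentation pH (from the speciation model; ≈ 0.058 equivalents per
  SA at pH 3), no acidulation;
- **neutral** — 2 OH⁻ equivalents per SA plus full re-acidulation
  (1 mol H2SO4 per SA, producing a gypsum-equivalent waste stream);
- **low_pH_with_reacidulation** — low-pH base plus acid for that same
  fraction.

The boiler burns bagasse at 80% efficiency; steam covers heating
first and the surplus drives a turbogenerator (30% to electricity);
heat deficits are purchased as natural gas, electricity deficits from
the grid, surpluses exported. Installed capital is a sum of block
power laws (exponent 0.6) over cane flow, fermenter volume (sized
from capacity/(productivity·uptime·hours), working-volume fraction
0.8), water evaporated, fuel firing rate and production rate —
roughly $175M at the 26,800 t/y base plant.

MPSP is solved by root-finding (Brent, 1e-6 $/kg) on the NPV at the
target IRR (default 10%, 2016$), with a 3-year construction schedule
(8/60/32%), 30 operating years, 5% working capital, straight-line
depreciation over 10 years and a 21% income tax rate — all
conventional project assumptions exposed in `DCFParams`; only the IRR
and cost year are fixed by the study design.

The surrogate coefficients were calibrated once so that the three
reference fermentation scenarios (laboratory batch, laboratory
fed-batch, pilot batch) fall inside published 5th–95th percentile
uncertainty bands for MPSP, GWP100 and FEC simultaneously; baseline
dollar and impact values are therefore *calibration references*, and
no test asserts them. Structural properties are asserted instead:
MPSP non-increasing in yield, titer, productivity and uptime;
non-decreasing in every price; low-pH dominating neutral pointwise;
breakdowns summing exactly; and the DCF solver agreeing with the
annuity closed form (capital·CRF + opex)/production when tax, working
capital and construction staging are switched off.

## LCA

GWP100 and FEC are linear in the inventory (sugarcane, NaOH, H2SO4,
gypsum disposal, natural gas, net electricity). Biogenic carbon fixed
into the product is not credited at gate; end-of-life degradation of
SA entirely to CO2 adds C·M_CO2/M_SA = 4 × 44.01/118.09 = 1.49 kg
CO2-eq/kg to the cradle-to-grave GWP100. FEC is cradle-to-gate with no
end-of-life term and can be negative when electricity export credits
dominate. The shipped characterization-factor table is a documented
synthetic-calibrated placeholder (grid electricity 0.48 kg CO2-eq/kWh
and 8.0 MJ/kWh, etc.); serious assessments should supply factors from
a real LCI database via the CSV interface.

## Uncertainty and sensitivity

28 parameters carry triangular or uniform distributions (the
working-volume fraction is held as a fixed engineering setting).
Latin hypercube sampling partitions [0,1) into N equal-probability
strata per parameter, draws one uniform point *within* each stratum
(random-within-stratum rather than midpoints), permutes strata
independently per parameter, and maps through the inverse CDF —
every marginal is exactly stratified, columns are mutually shuffled,
and the whole matrix is reproducible from the seed. Parameters are
sampled independently; no correlation structure is imposed.
Percentiles (5/25/50/75/95) use linear interpolation between order
statistics. Failed model evaluations are recorded with their sample
indices; more than 1% failures aborts the run. Spearman's ρ is the
Pearson correlation of average ranks (scipy), cross-checked in the
tests against an independent brute-force rank formula; constant
vectors yield an undefined ρ reported as NaN.

## Landscapes

`evaluate_landscape` evaluates the deterministic baseline model over a
yield–titer grid (default 50×50 = 2500 combinations) at fixed
productivity for either regime. The yield axis is bounded by the
1.311 g/g carbon ceiling and reported both in g/g and as
%-of-theoretical. The default productivity range for multi-surface
sweeps is 0.2–2.0 g/L/h. Marginal improvements are finite differences
of the MPSP surface for relative steps in yield and titer.

## Synthetic data

`generate_time_course` produces fermentation records whose endpoint
metrics equal the generating (titer, yield, productivity) *exactly*:
product follows a logistic curve pinned to 0 at t=0 and the target
titer at the end, substrate is depleted at exactly the target yield on
the glucose-equivalent basis, substrates consumed in declaration order
(emulating the observed glucose-then-glycerol phasing), feeds applied
as pulses, Gaussian observation noise added under a seed with the
noise-free truth retained alongside. It emulates the *shape* of real
time courses — not mechanistic Monod kinetics, lag phases, byproduct
dynamics, or the error structure of HPLC measurements — so passing
round-trip tests demonstrates the correctness of the metric
arithmetic, not the realism of any kinetic model. Infeasible plans
(insufficient substrate for the target titer at the target yield) are
rejected.

## Problem sizes and numerical settings

The yield LPs have ~13 variables and solve in milliseconds; Monte
Carlo runs use the full N=2000 with the complete TEA/LCA model
(≈0.2 ms per evaluation); landscape tests use reduced grids (up to
10×10) while the library default remains 50×50. LP tolerance 1e-9;
MPSP root tolerance 1e-6 $/kg; mass-balance violation threshold 1e-6;
speciation fractions sum to 1 within 1e-12.

## Known limitations

- Block surrogates cannot resolve equipment-level trade-offs (column
  staging, heat integration, gassed power); absolute dollar and
  impact values are indicative, relative comparisons (regimes, yield
  vs titer priorities) are the intended use.
- The stoichiometric model is cytosolic and steady-state: no
  mitochondrial exchange, growth coupling or dynamic flux.
- Stage yields in the crystallization train are inputs; temperature
  and seeding settings are carried but not used predictively.
- Characterization factors and uncertainty bounds for the non-anchored
  parameters are synthetic placeholders, clearly marked.
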