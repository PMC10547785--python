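"""Synthetic input generators: fermentation time courses with known
ground-truth metrics, uncertain-parameter files, and price / impact
tables.

The time-course generator emulates the shape of batch and fed-batch
succinate fermentations (an initial 50 g/L glucose + 20 g/L glycerol
charge or sugarcane-juice sugars, feed pulses, ~100 g/L final titers):
product follows a logistic curve pinned to hit the target titer at the
end of the run, and substrate is depleted at exactly the target yield
on the glucose-equivalent basis, substrates consumed in declaration
order (glucose phase before glycerol phase, as observed). Because the
endpoints are exact by construction, metrics computed on a noise-free
record recover the generating (titer, yield, productivity) identically
— the generator guarantees endpoint metrics rather than fitting
mechanistic kinetics, for which no parameters are available.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .defaults import (BASELINE_PARAMETERS, DEFAULT_IMPACT_FACTORS,
                       DEFAULT_PARAMETERS, THEORETICAL_MAX_YIELD,
                       UNCERTAIN_PARAMETERS)
from .fermentation import FeedEvent, FermentationRecord
from .stoichiometry import glucose_equivalent
from .uncertainty import ParameterDistribution

__all__ = ["KineticSpec", "SyntheticTimeCourse", "generate_time_course",
           "generate_parameter_distributions", "generate_parameter_file",
           "generate_tables"]


@dataclass(frozen=True)
class KineticSpec:
    """Ground truth for one synthetic run.

    ``initial_substrates`` in g/L at ``initial_volume``; feeds are
    (time h, {substrate: grams}, volume added L). ``max_specific_rate``
    is the logistic steepness (1/h); 0 gives flat trajectories.
    """

    target_yield: float  # g/g glucose-equivalent
    target_titer: float  # g/L at end of run
    duration: float  # h
    initial_substrates: Mapping[str, float]
    initial_volume: float = 1.0
    feeds: Sequence[tuple[float, Mapping[str, float], float]] = ()
    max_specific_rate: float = 0.15
    noise_sd: float = 0.0
    seed: int = 0
    n_points: int = 25

    def __post_init__(self) -> None:
        if not 0.0 < self.target_yield <= THEORETICAL_MAX_YIELD:
            raise ValueError("target yield outside (0, carbon ceiling]")
        if self.target_titer < 0 or self.noise_sd < 0:
            raise ValueError("titer and noise must be non-negative")
        if self.duration <= 0 or self.initial_volume <= 0:
            raise ValueError("duration and volume must be positive")
        if self.n_points < 2:
            raise ValueError("need at least 2 time points")


@dataclass
class SyntheticTimeCourse:
    record: FermentationRecord  # observed (noisy) record
    truth: FermentationRecord  # noise-free ground truth
    spec: KineticSpec


def _logistic_shape(t: np.ndarray, rate: float, duration: float) -> np.ndarray:
    """0 at t=0, 1 at t=duration, sigmoidal in between (flat if rate 0)."""
    if rate == 0.0:
        return np.zeros_like(t)
    f = 1.0 / (1.0 + np.exp(-rate * (t - duration / 2.0)))
    f0, f1 = f[0], f[-1]
    return (f - f0) / (f1 - f0)


def generate_time_course(spec: KineticSpec) -> SyntheticTimeCourse:
    """Build a fermentation record whose endpoint metrics equal the spec.

    Raises if the substrate plan cannot support the target titer at the
    target yield (mass balance infeasible).
    """
    times = np.linspace(0.0, spec.duration, spec.n_points)
    order = list(spec.initial_substrates)
    feeds = sorted(spec.feeds, key=lambda e: e[0])
    for t_feed, masses, _ in feeds:
        for s in masses:
            if s not in order:
                order.append(s)

    # available substrate mass per time (initial charge + feeds so far)
    volume = np.full_like(times, spec.initial_volume)
    avail = {s: np.full_like(times, spec.initial_substrates.get(s, 0.0)
                             * spec.initial_volume) for s in order}
    for t_feed, masses, vol_added in feeds:
        after = times >= t_feed - 1e-12
        volume[after] += vol_added
        for s, g in masses.items():
            avail[s][after] += g

    final_volume = volume[-1]
    product_mass_end = spec.target_titer * final_volume
    need_ge = product_mass_end / spec.target_yield
    supplied_ge = glucose_equivalent({s: avail[s][-1] for s in order})
    if need_ge > supplied_ge * (1 + 1e-9):
        raise ValueError(
            f"infeasible plan: target titer needs {need_ge:.1f} g "
            f"glucose-equivalent but only {supplied_ge:.1f} g supplied")

    shape = _logistic_shape(times, spec.max_specific_rate, spec.duration)
    product_mass = product_mass_end * shape
    consumed_ge = product_mass / spec.target_yield  # cumulative, g GE

    # deplete substrates sequentially in declaration order
    residual = {s: np.array(avail[s]) for s in order}
    for i, c in enumerate(consumed_ge):
        left = c
        for s in order:
            if left <= 0:
                break
            # convert this substrate's mass to its glucose-equivalent
            ge_per_g = glucose_equivalent({s: 1.0})
            have_ge = avail[s][i] * ge_per_g
            used_ge = min(left, have_ge)
            residual[s][i] = (have_ge - used_ge) / ge_per_g
            left -= used_ge

    product_conc = product_mass / volume
    substrate_concs = {s: residual[s] / volume for s in order}
    events = [FeedEvent(t, dict(m), v) for t, m, v in feeds]
    truth = FermentationRecord(times, product_conc.copy(),
                               {s: a.copy() for s, a in substrate_concs.items()},
                               volume.copy(), list(events))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noisy_p = np.clip(product_conc + rng.normal(0, spec.noise_sd,
                                                    len(times)), 0, None)
        noisy_s = {s: np.clip(a + rng.normal(0, spec.noise_sd, len(times)),
                              0, None)
                   for s, a in substrate_concs.items()}
        observed = FermentationRecord(times, noisy_p, noisy_s, volume.copy(),
                                      list(events))
    else:
        observed = truth
    return SyntheticTimeCourse(observed, truth, spec)


def generate_parameter_distributions(n_params: int = 28, seed: int = 0
                                     ) -> list[ParameterDistribution]:
    """The uncertain-parameter set as distributions.

    The first entries are the model's documented parameters (including
    the sugarcane price anchored at $49.3/dry metric ton baseline and
    plant capacity at 26,800 t/y); if more are requested, synthetic
    placeholder parameters are appended (triangular around 1).
    """
    if n_params < 1:
        raise ValueError("need at least one parameter")
    dists: list[ParameterDistribution] = []
    for name in UNCERTAIN_PARAMETERS[:n_params]:
        entry = DEFAULT_PARAMETERS[name]
        dists.append(ParameterDistribution(
            name=name, kind=entry["kind"], baseline=entry["baseline"],
            lower=entry["lower"], upper=entry["upper"],
            mode=entry.get("mode")))
    rng = np.random.default_rng(seed)
    for i in range(len(dists), n_params):
        lo, hi = sorted(rng.uniform(0.5, 1.5, 2))
        if hi - lo < 1e-6:
            hi = lo + 0.1
        mode = rng.uniform(lo, hi)
        dists.append(ParameterDistribution(
            name=f"synthetic_param_{i}", kind="triangular", baseline=mode,
            lower=lo, upper=hi, mode=mode))
    return dists


def generate_parameter_file(path: str | Path, n_params: int = 28,
                            seed: int = 0) -> list[ParameterDistribution]:
    """Write the parameter-distribution CSV and return the distributions."""
    from .uncertainty import write_parameter_csv

    dists = generate_parameter_distributions(n_params, seed)
    write_parameter_csv(dists, path)
    return dists


def generate_tables(directory: str | Path, seed: int = 0
                    ) -> tuple[Path, Path]:
    """Emit the default price table and impact-factor table as CSV.

    Deterministic for a given seed (the defaults themselves are fixed;
    the seed is accepted for interface uniformity with the other
    generators).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    prices = directory / "prices.csv"
    price_rows = [
        {"name": name, "value": BASELINE_PARAMETERS[name],
         "unit": unit}
        for name, unit in [
            ("sugarcane_price", "$/kg dry"), ("naoh_price", "$/kg"),
            ("h2so4_price", "$/kg"), ("gypsum_disposal_price", "$/kg"),
            ("natural_gas_price", "$/MJ"), ("electricity_price", "$/kWh"),
            ("other_materials_cost", "$/kg product"),
        ]
    ]
    pd.DataFrame(price_rows).to_csv(prices, index=False)
    factors = directory / "impact_factors.csv"
    pd.DataFrame([
        {"flow": flow, "unit": d["unit"], "gwp_factor": d["gwp"],
         "fec_factor": d["fec"]}
        for flow, d in DEFAULT_IMPACT_FACTORS.items()
    ]).to_csv(factors, index=False)
    return prices, factors
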