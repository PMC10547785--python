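"""Downstream processing: diprotic speciation, vacuum concentration and the
multi-stage direct-crystallization train.

Succinic acid is a diprotic acid (default pKa1 = 4.21, pKa2 = 5.64 at
25 degC); at fermentation pH 3 ~94% of the dissolved acid is fully
protonated, which is what makes direct crystallization from low-pH
broth possible without acidulation. Stage yields are empirical inputs;
the train composes them sequentially on the succinate remaining in the
filtrate, with a vacuum-concentration step between stages.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

__all__ = [
    "PKA1_DEFAULT", "PKA2_DEFAULT",
    "SpeciationResult", "CrystallizationStage", "BrothState", "TrainResult",
    "speciate", "concentrate", "stage_recovery_percent",
    "train_recovery_percent", "purity_percent", "simulate_train",
]

PKA1_DEFAULT = 4.21
PKA2_DEFAULT = 5.64


@dataclass(frozen=True)
class SpeciationResult:
    """Equilibrium fractions of H2A (fully protonated), HA- and A2-."""

    fraction_H2A: float
    fraction_HA: float
    fraction_A: float

    @property
    def charge_equivalents(self) -> float:
        """Mol base equivalents needed per mol total acid at this pH."""
        return self.fraction_HA + 2.0 * self.fraction_A


def speciate(pH: float, pKa1: float = PKA1_DEFAULT,
             pKa2: float = PKA2_DEFAULT) -> SpeciationResult:
    """Diprotic acid speciation at the given pH.

    Denominator 1 + 10^(pH-pKa1) + 10^(2pH-pKa1-pKa2); fractions sum to 1.
    """
    if pKa2 <= pKa1:
        raise ValueError("pKa2 must exceed pKa1")
    r1 = 10.0 ** (pH - pKa1)
    r2 = 10.0 ** (2.0 * pH - pKa1 - pKa2)
    denom = 1.0 + r1 + r2
    return SpeciationResult(1.0 / denom, r1 / denom, r2 / denom)


@dataclass(frozen=True)
class CrystallizationStage:
    """Operating settings plus the empirical stage yield (fraction of the
    SA entering the stage that crystallizes).

    Defaults are the optimized direct-crystallization settings: 1% w/v
    seed loading, 10 degC seed temperature, 4 h at 0.56 g relative
    agitation, crystallization at 0 degC.
    """

    stage_yield: float
    temperature: float = 0.0
    seed_loading: float = 1.0
    seed_temperature: float = 10.0
    duration: float = 4.0
    agitation: float = 0.56

    def __post_init__(self) -> None:
        if not 0.0 <= self.stage_yield <= 1.0:
            raise ValueError("stage_yield must be in [0, 1]")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass(frozen=True)
class BrothState:
    """Clarified broth: volume (L), SA mass (g) and lumped impurities (g)."""

    volume: float
    sa_mass: float
    impurity_mass: float = 0.0

    def __post_init__(self) -> None:
        if self.volume < 0 or self.sa_mass < 0 or self.impurity_mass < 0:
            raise ValueError("broth quantities must be non-negative")

    @property
    def sa_concentration(self) -> float:
        return self.sa_mass / self.volume if self.volume > 0 else 0.0


def concentrate(broth: BrothState, volume_fraction: float) -> BrothState:
    """Vacuum distillation to ``volume_fraction`` of the current volume.

    SA is non-volatile: solute masses are conserved, only water leaves.
    """
    if not 0.0 < volume_fraction <= 1.0:
        raise ValueError("volume fraction must be in (0, 1]")
    return replace(broth, volume=broth.volume * volume_fraction)


def stage_recovery_percent(recovered_mass: float, initial_mass: float) -> float:
    """% recovery = recovered SA / SA initially present x 100."""
    if initial_mass <= 0:
        raise ValueError("initial mass must be positive")
    if recovered_mass < 0 or recovered_mass > initial_mass * (1 + 1e-12):
        raise ValueError("recovered mass must be within [0, initial mass]")
    return 100.0 * recovered_mass / initial_mass


def train_recovery_percent(stage_yields: Sequence[float]) -> float:
    """Overall recovery of a sequential train: 100*(1 - prod(1 - y_i)).

    Each stage yield applies to the SA left in the filtrate of the
    previous stage; e.g. printed stage yields of 31.0% and 47.7% compose
    to an overall recovery of ~64%.
    """
    if len(stage_yields) == 0:
        raise ValueError("at least one stage required")
    remaining = 1.0
    for y in stage_yields:
        if not 0.0 <= y <= 1.0:
            raise ValueError(f"stage yield out of [0, 1]: {y}")
        remaining *= 1.0 - y
    return 100.0 * (1.0 - remaining)


def purity_percent(sa_mass_in_crystal: float, crystal_mass: float) -> float:
    """% purity = SA mass in the recovered crystal / crystal mass x 100."""
    if crystal_mass <= 0:
        raise ValueError("crystal mass must be positive")
    if not 0.0 <= sa_mass_in_crystal <= crystal_mass:
        raise ValueError("SA mass must be within [0, crystal mass]")
    return 100.0 * sa_mass_in_crystal / crystal_mass


@dataclass(frozen=True)
class TrainResult:
    crystal_masses: tuple[float, ...]  # g per stage
    final_filtrate: BrothState
    overall_recovery_percent: float

    def to_dict(self) -> dict:
        return {
            "crystal_masses_g": list(self.crystal_masses),
            "final_filtrate_volume_L": self.final_filtrate.volume,
            "final_filtrate_sa_g": self.final_filtrate.sa_mass,
            "overall_recovery_percent": self.overall_recovery_percent,
        }


def simulate_train(broth: BrothState,
                   stages: Sequence[CrystallizationStage],
                   concentrate_fraction_between: float = 0.5) -> TrainResult:
    """Run the crystallization train on a broth.

    Each stage removes ``stage_yield`` of the SA currently in solution as
    crystal; the filtrate is concentrated between stages (default to 50%
    of its volume). Overall recovery is consistent with
    :func:`train_recovery_percent` by construction.
    """
    if len(stages) == 0:
        raise ValueError("at least one stage required")
    initial_sa = broth.sa_mass
    if initial_sa <= 0:
        raise ValueError("broth contains no SA")
    state = broth
    crystals: list[float] = []
    for i, stage in enumerate(stages):
        crystal = state.sa_mass * stage.stage_yield
        crystals.append(crystal)
        state = replace(state, sa_mass=state.sa_mass - crystal)
        if i < len(stages) - 1:
            state = concentrate(state, concentrate_fraction_between)
    overall = stage_recovery_percent(sum(crystals), initial_sa)
    return TrainResult(tuple(crystals), state, overall)
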