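"""Stirred-tank hydrodynamics and bench-to-pilot scale-up matching.

Standard ungassed correlations for water-like broths: impeller Reynolds
number Re = rho*N*D^2/mu, power draw P = Np*rho*N^3*D^5, tip speed
pi*N*D. Scale-up solves the pilot agitation speed that reproduces the
bench power input per unit working volume (P/V) exactly and reports the
resulting Reynolds-number ratio — with fixed geometry the two criteria
are generally not simultaneously satisfiable, so the report quantifies
the compromise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = ["ReactorSpec", "reynolds", "power", "power_per_volume",
           "tip_speed", "vvm_to_flow", "match_scale", "ScaleReport"]


@dataclass(frozen=True)
class ReactorSpec:
    """Geometry, agitation and fluid properties of a stirred tank.

    Volumes in litres, impeller diameter in metres, agitation in 1/s,
    SI fluid properties; ``power_number`` is the dimensionless turbulent
    Np of the impeller; ``gas_flow_vvm`` in volume per working volume
    per minute.
    """

    vessel_volume: float
    working_volume: float
    impeller_diameter: float
    agitation_speed: float
    fluid_density: float = 1000.0
    fluid_viscosity: float = 1.0e-3
    power_number: float = 5.0
    gas_flow_vvm: float = 0.0

    def __post_init__(self) -> None:
        if self.working_volume > self.vessel_volume:
            raise ValueError("working volume exceeds vessel volume")
        for name in ("vessel_volume", "working_volume", "impeller_diameter",
                     "fluid_density", "fluid_viscosity", "power_number"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.agitation_speed < 0 or self.gas_flow_vvm < 0:
            raise ValueError("agitation and gas flow must be non-negative")


def reynolds(spec: ReactorSpec) -> float:
    """Impeller Reynolds number rho*N*D^2/mu."""
    return (spec.fluid_density * spec.agitation_speed
            * spec.impeller_diameter ** 2 / spec.fluid_viscosity)


def power(spec: ReactorSpec) -> float:
    """Ungassed agitation power Np*rho*N^3*D^5 (W)."""
    return (spec.power_number * spec.fluid_density
            * spec.agitation_speed ** 3 * spec.impeller_diameter ** 5)


def power_per_volume(spec: ReactorSpec) -> float:
    """Power input per unit working volume (W/m^3)."""
    return power(spec) / (spec.working_volume / 1000.0)


def tip_speed(spec: ReactorSpec) -> float:
    """Impeller tip speed pi*N*D (m/s)."""
    return math.pi * spec.agitation_speed * spec.impeller_diameter


def vvm_to_flow(vvm: float, working_volume: float) -> float:
    """Gas flow (L/min) from vvm and working volume (L)."""
    if vvm < 0 or working_volume < 0:
        raise ValueError("vvm and working volume must be non-negative")
    return vvm * working_volume


@dataclass(frozen=True)
class ScaleReport:
    pilot_agitation: float  # 1/s matching bench P/V
    pv_ratio: float  # pilot P/V over bench P/V (1 by construction)
    re_ratio: float  # pilot Re over bench Re at the matched agitation
    scale_factor: float  # pilot over bench working volume

    def to_dict(self) -> dict:
        return {"pilot_agitation_per_s": self.pilot_agitation,
                "power_per_volume_ratio": self.pv_ratio,
                "reynolds_ratio": self.re_ratio,
                "volume_scale_factor": self.scale_factor}


def match_scale(bench: ReactorSpec, pilot: ReactorSpec) -> ScaleReport:
    """Solve pilot agitation so that pilot P/V equals bench P/V.

    P/V = Np*rho*N^3*D^5/V gives N = (PV_bench * V / (Np*rho*D^5))^(1/3).
    The achieved Reynolds ratio is reported; it equals 1 only for
    geometrically degenerate pairs.
    """
    pv = power_per_volume(bench)
    n_pilot = (pv * (pilot.working_volume / 1000.0)
               / (pilot.power_number * pilot.fluid_density
                  * pilot.impeller_diameter ** 5)) ** (1.0 / 3.0)
    matched = replace(pilot, agitation_speed=n_pilot)
    return ScaleReport(
        pilot_agitation=n_pilot,
        pv_ratio=power_per_volume(matched) / pv,
        re_ratio=reynolds(matched) / reynolds(bench),
        scale_factor=pilot.working_volume / bench.working_volume,
    )
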