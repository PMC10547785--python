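"""Structured config loading, validation and run manifests.

Configs are YAML mappings with explicit units encoded in the key names
(``*_L``, ``*_m``, ``*_per_s``...). Every CLI run emits one manifest
recording the command, a hash of the resolved configuration, the seed
and the output paths, so deterministic commands are reproducible
byte-for-byte from the manifest alone.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Mapping

import yaml

from .downstream import BrothState, CrystallizationStage
from .scaleup import ReactorSpec
from .tea import BiorefineryScenario

__all__ = ["load_yaml", "reactor_spec_from_config", "broth_from_config",
           "stages_from_config", "scenario_from_config", "RunManifest"]


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level, "
                         f"got {type(data).__name__}")
    return data


def _require(data: Mapping[str, Any], fields: dict[str, type],
             context: str) -> dict:
    out = {}
    for key, typ in fields.items():
        if key not in data:
            raise ValueError(f"{context}: missing required field {key!r}")
        try:
            out[key] = typ(data[key])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{context}.{key}: {exc}") from None
    return out


def reactor_spec_from_config(data: Mapping[str, Any]) -> ReactorSpec:
    req = _require(data, {"vessel_volume_L": float, "working_volume_L": float,
                          "impeller_diameter_m": float}, "reactor")
    return ReactorSpec(
        vessel_volume=req["vessel_volume_L"],
        working_volume=req["working_volume_L"],
        impeller_diameter=req["impeller_diameter_m"],
        agitation_speed=float(data.get("agitation_per_s", 0.0)),
        fluid_density=float(data.get("fluid_density_kg_m3", 1000.0)),
        fluid_viscosity=float(data.get("fluid_viscosity_Pa_s", 1.0e-3)),
        power_number=float(data.get("power_number", 5.0)),
        gas_flow_vvm=float(data.get("gas_flow_vvm", 0.0)),
    )


def broth_from_config(data: Mapping[str, Any]) -> BrothState:
    req = _require(data, {"volume_L": float, "sa_concentration_gL": float},
                   "broth")
    return BrothState(volume=req["volume_L"],
                      sa_mass=req["volume_L"] * req["sa_concentration_gL"],
                      impurity_mass=float(data.get("impurity_g", 0.0)))


def stages_from_config(data: Mapping[str, Any]) -> list[CrystallizationStage]:
    stages = data.get("stages")
    if not stages:
        raise ValueError("train: at least one stage required")
    out = []
    for i, st in enumerate(stages):
        req = _require(st, {"stage_yield": float}, f"train.stages[{i}]")
        out.append(CrystallizationStage(
            stage_yield=req["stage_yield"],
            temperature=float(st.get("temperature_C", 0.0)),
            seed_loading=float(st.get("seed_loading_pct_wv", 1.0)),
            seed_temperature=float(st.get("seed_temperature_C", 10.0)),
            duration=float(st.get("duration_h", 4.0)),
            agitation=float(st.get("agitation_g", 0.56)),
        ))
    return out


def scenario_from_config(data: Mapping[str, Any]) -> BiorefineryScenario:
    req = _require(data, {"yield_g_per_g": float, "titer_gL": float,
                          "productivity_gLh": float}, "scenario")
    return BiorefineryScenario(
        yield_=req["yield_g_per_g"], titer=req["titer_gL"],
        productivity=req["productivity_gLh"],
        regime=str(data.get("regime", "low_pH")),
        capacity=float(data.get("capacity_t_per_y", 26800.0)),
        uptime=float(data.get("uptime", 0.90)),
        fermentation_ph=float(data.get("fermentation_pH", 3.0)),
    )


@dataclass
class RunManifest:
    command: str
    config_hash: str
    seed: int | None
    package_version: str
    timestamp: str
    output_paths: list[str]

    @classmethod
    def create(cls, command: str, config: Any, seed: int | None,
               outputs: list[str]) -> "RunManifest":
        from . import __version__

        blob = json.dumps(config, sort_keys=True, default=str).encode()
        return cls(command=command,
                   config_hash=hashlib.sha256(blob).hexdigest()[:16],
                   seed=seed, package_version=__version__,
                   timestamp=datetime.now(timezone.utc).isoformat(),
                   output_paths=list(outputs))

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
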