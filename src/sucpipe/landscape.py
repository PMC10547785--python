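"""MPSP / GWP100 / FEC surfaces across yield-titer grids.

Deterministic baseline evaluations (no Monte Carlo) of the biorefinery
model over a grid of fermentation yield and titer at fixed productivity,
for the low-pH or neutral regime. Yields are reported both in g/g
glucose-equivalent and as % of the 1.311 g/g carbon-balance ceiling.
The default 50 x 50 grid gives 2500 yield-titer combinations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .defaults import THEORETICAL_MAX_YIELD
from .pipeline import evaluate

__all__ = ["LandscapeGrid", "evaluate_landscape", "marginal_improvement"]

_OUTPUTS = ("mpsp", "gwp100", "fec")


@dataclass
class LandscapeGrid:
    yields: np.ndarray  # g/g glucose-equivalent
    titers: np.ndarray  # g/L
    productivity: float  # g/L/h
    regime: str
    surfaces: dict[str, np.ndarray]  # output -> (n_yield, n_titer)
    infeasible: list[tuple[int, int]] = field(default_factory=list)

    @property
    def yields_percent_theoretical(self) -> np.ndarray:
        return 100.0 * self.yields / THEORETICAL_MAX_YIELD

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {
            name: pd.DataFrame(m, index=np.round(self.yields, 6),
                               columns=np.round(self.titers, 6))
            for name, m in self.surfaces.items()
        }

    def write_csv(self, directory: str | Path, prefix: str = "landscape") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, frame in self.to_frames().items():
            frame.to_csv(directory / f"{prefix}_{name}.csv",
                         index_label="yield_g_per_g")


def evaluate_landscape(yield_range: tuple[float, float] = (0.3, 1.0),
                       titer_range: tuple[float, float] = (30.0, 200.0),
                       productivity: float = 0.657,
                       regime: str = "low_pH",
                       n_yield: int = 50, n_titer: int = 50,
                       params: Mapping[str, float] | None = None
                       ) -> LandscapeGrid:
    """Evaluate every grid point; infeasible points become NaN and are
    recorded by index."""
    if n_yield < 1 or n_titer < 1:
        raise ValueError("grid must have at least one point per axis")
    y_lo, y_hi = yield_range
    t_lo, t_hi = titer_range
    if not (0.0 < y_lo <= y_hi <= THEORETICAL_MAX_YIELD + 1e-9):
        raise ValueError("yield range outside (0, carbon ceiling]")
    if not 0.0 < t_lo <= t_hi:
        raise ValueError("titer range must be positive and ordered")
    yields = np.linspace(y_lo, y_hi, n_yield)
    titers = np.linspace(t_lo, t_hi, n_titer)
    surfaces = {name: np.full((n_yield, n_titer), np.nan) for name in _OUTPUTS}
    infeasible: list[tuple[int, int]] = []
    base = dict(params or {})
    base["fermentation_productivity"] = productivity
    for i, y in enumerate(yields):
        for j, t in enumerate(titers):
            point = {**base, "fermentation_yield": float(y),
                     "fermentation_titer": float(t)}
            try:
                out = evaluate(point, regime=regime)
            except (ValueError, RuntimeError):
                infeasible.append((i, j))
                continue
            for name in _OUTPUTS:
                surfaces[name][i, j] = out[name]
    return LandscapeGrid(yields, titers, productivity, regime, surfaces,
                         infeasible)


def marginal_improvement(yield_: float, titer: float,
                         delta_yield_rel: float = 0.10,
                         delta_titer_rel: float = 0.10,
                         productivity: float = 0.657,
                         regime: str = "low_pH",
                         params: Mapping[str, float] | None = None
                         ) -> tuple[float, float]:
    """Finite-difference MPSP change for relative yield / titer steps.

    Returns (delta_mpsp_per_yield_step, delta_mpsp_per_titer_step), both
    <= 0 at feasible points since MPSP is non-increasing along each axis.
    """
    y1 = yield_ * (1.0 + delta_yield_rel)
    t1 = titer * (1.0 + delta_titer_rel)
    if y1 > THEORETICAL_MAX_YIELD + 1e-9:
        raise ValueError("yield step exceeds the carbon-balance ceiling")
    base = dict(params or {})
    base["fermentation_productivity"] = productivity

    def mpsp(y: float, t: float) -> float:
        return evaluate({**base, "fermentation_yield": y,
                         "fermentation_titer": t}, regime=regime)["mpsp"]

    m0 = mpsp(yield_, titer)
    return mpsp(y1, titer) - m0, mpsp(yield_, t1) - m0
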