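"""Titer, yield and productivity from batch / fed-batch fermentation records.

Yields are quoted in g product per g glucose-equivalent consumed, the
convention under which glycerol counts 1:1 with glucose by mass and
sucrose on its hydrolysis basis; productivity is the overall rate
(product formed over the evaluation interval divided by elapsed time),
which is how printed batch numbers reconcile (46.0 g/L at 48 h ->
0.96 g/L/h).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .stoichiometry import glucose_equivalent

__all__ = [
    "FeedEvent",
    "FermentationRecord",
    "PerformanceMetrics",
    "compute_metrics",
    "substrate_consumed",
    "percent_theoretical",
]

_NEG_TOL = 1e-6


@dataclass(frozen=True)
class FeedEvent:
    """A pulse addition: substrate masses in grams plus volume added (L)."""

    time: float
    substrate_masses: Mapping[str, float]
    volume_added: float = 0.0


@dataclass
class FermentationRecord:
    """Time course of one fermentation run.

    Concentrations are g/L at each sampling time; ``working_volume`` is
    the broth volume (L) at each time, already including feed additions
    up to that time.
    """

    times: np.ndarray
    product_conc: np.ndarray
    substrate_concs: dict[str, np.ndarray]
    working_volume: np.ndarray
    feed_events: list[FeedEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.product_conc = np.asarray(self.product_conc, dtype=float)
        self.working_volume = np.asarray(self.working_volume, dtype=float)
        self.substrate_concs = {
            k: np.asarray(v, dtype=float) for k, v in self.substrate_concs.items()
        }
        n = len(self.times)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name, arr in [("product_conc", self.product_conc),
                          ("working_volume", self.working_volume),
                          *self.substrate_concs.items()]:
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != times length {n}")
        if np.any(self.product_conc < -_NEG_TOL):
            raise ValueError("negative product concentration")
        if np.any(self.working_volume <= 0):
            raise ValueError("working volume must be positive")
        for t in (e.time for e in self.feed_events):
            if not (self.times[0] <= t <= self.times[-1]):
                raise ValueError(f"feed at t={t} outside record time range")

    def _interp(self, arr: np.ndarray, t: float) -> float:
        return float(np.interp(t, self.times, arr))

    @classmethod
    def from_csv(cls, timecourse: str | Path,
                 feeds: str | Path | None = None) -> "FermentationRecord":
        """Read a record from ``time_h, product_gL, <sub>_gL..., volume_L``
        columns, plus an optional feeds CSV
        (``time_h, <sub>_g..., volume_added_L``)."""
        df = pd.read_csv(timecourse)
        subs = {
            c[:-3]: df[c].to_numpy()
            for c in df.columns
            if c.endswith("_gL") and c != "product_gL"
        }
        events: list[FeedEvent] = []
        if feeds is not None:
            fdf = pd.read_csv(feeds)
            for _, row in fdf.iterrows():
                masses = {c[:-2]: float(row[c]) for c in fdf.columns
                          if c.endswith("_g")}
                events.append(FeedEvent(float(row["time_h"]), masses,
                                        float(row.get("volume_added_L", 0.0))))
        return cls(df["time_h"].to_numpy(), df["product_gL"].to_numpy(),
                   subs, df["volume_L"].to_numpy(), events)

    def to_csv(self, timecourse: str | Path,
               feeds: str | Path | None = None) -> None:
        cols = {"time_h": self.times, "product_gL": self.product_conc}
        cols.update({f"{s}_gL": v for s, v in self.substrate_concs.items()})
        cols["volume_L"] = self.working_volume
        pd.DataFrame(cols).to_csv(timecourse, index=False)
        if feeds is not None:
            subs = sorted({s for e in self.feed_events for s in e.substrate_masses})
            rows = [
                {"time_h": e.time,
                 **{f"{s}_g": e.substrate_masses.get(s, 0.0) for s in subs},
                 "volume_added_L": e.volume_added}
                for e in self.feed_events
            ]
            pd.DataFrame(rows, columns=["time_h", *(f"{s}_g" for s in subs),
                                        "volume_added_L"]).to_csv(feeds, index=False)


@dataclass(frozen=True)
class PerformanceMetrics:
    titer: float  # g/L at end of interval
    yield_: float  # g/g glucose-equivalent consumed
    productivity: float  # g/L/h over the interval

    def to_dict(self) -> dict:
        return {"titer_gL": self.titer,
                "yield_g_per_g_glucose_equivalent": self.yield_,
                "productivity_gLh": self.productivity}


def substrate_consumed(record: FermentationRecord,
                       interval: tuple[float, float] | None = None) -> float:
    """Glucose-equivalent substrate consumed over the interval, g per L of
    final working volume.

    Mass balance: initial charge + feeds in the interval - residual at
    t_end, each substrate converted to glucose-equivalent mass.
    """
    t0, t1 = _check_interval(record, interval)
    v0 = record._interp(record.working_volume, t0)
    v1 = record._interp(record.working_volume, t1)
    consumed_g: dict[str, float] = {}
    for sub, conc in record.substrate_concs.items():
        m0 = record._interp(conc, t0) * v0
        m1 = record._interp(conc, t1) * v1
        fed = sum(e.substrate_masses.get(sub, 0.0) for e in record.feed_events
                  if t0 < e.time <= t1)
        consumed_g[sub] = m0 + fed - m1
    total = glucose_equivalent({s: max(m, 0.0) for s, m in consumed_g.items()})
    worst = min(consumed_g.values(), default=0.0)
    if worst < -_NEG_TOL * max(1.0, total):
        raise ValueError(
            f"mass balance violation: negative consumption {worst:.3g} g")
    return total / v1


def compute_metrics(record: FermentationRecord,
                    interval: tuple[float, float] | None = None
                    ) -> PerformanceMetrics:
    """Titer / yield / productivity over ``interval`` (default: whole run)."""
    t0, t1 = _check_interval(record, interval)
    p0 = record._interp(record.product_conc, t0)
    p1 = record._interp(record.product_conc, t1)
    titer = p1
    productivity = (p1 - p0) / (t1 - t0)
    consumed = substrate_consumed(record, (t0, t1))
    v1 = record._interp(record.working_volume, t1)
    v0 = record._interp(record.working_volume, t0)
    product_formed = (p1 * v1 - p0 * v0) / v1  # g per L final volume
    yield_ = product_formed / consumed if consumed > 0 else 0.0
    return PerformanceMetrics(titer, yield_, productivity)


def percent_theoretical(yield_: float, ceiling: float) -> float:
    """Yield expressed as % of the theoretical maximum yield."""
    if ceiling <= 0:
        raise ValueError("theoretical ceiling must be positive")
    return 100.0 * yield_ / ceiling


def _check_interval(record: FermentationRecord,
                    interval: tuple[float, float] | None) -> tuple[float, float]:
    if interval is None:
        return float(record.times[0]), float(record.times[-1])
    t0, t1 = interval
    if t1 <= t0:
        raise ValueError("interval must have t_end > t_start")
    if t0 < record.times[0] - 1e-12 or t1 > record.times[-1] + 1e-12:
        raise ValueError("interval outside record time range")
    return float(t0), float(t1)
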