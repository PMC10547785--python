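"""Latin hypercube Monte Carlo propagation and Spearman rank sensitivity.

Uncertain parameters carry triangular or uniform distributions. Latin
hypercube sampling partitions [0, 1) into N equal-probability strata per
parameter, draws one uniform point inside each stratum, permutes the
strata independently per parameter, and maps the points through the
inverse CDF — so every marginal is perfectly stratified while columns
are mutually shuffled. Outputs are summarized by interpolated
percentiles (5/25/50/75/95) and ranked against each parameter with
Spearman's rho.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ParameterDistribution", "SampleMatrix", "MonteCarloResult",
    "SensitivityResult", "lhs_sample", "run_monte_carlo", "spearman_rho",
    "read_parameter_csv", "write_parameter_csv",
]

PERCENTILES = (5, 25, 50, 75, 95)


@dataclass(frozen=True)
class ParameterDistribution:
    """One uncertain parameter: uniform(lower, upper) or
    triangular(lower, mode, upper), with a baseline inside the bounds."""

    name: str
    kind: str
    baseline: float
    lower: float
    upper: float
    mode: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "triangular"):
            raise ValueError(f"{self.name}: unknown distribution kind "
                             f"{self.kind!r}")
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower must be < upper")
        if not self.lower <= self.baseline <= self.upper:
            raise ValueError(f"{self.name}: baseline outside bounds")
        if self.kind == "triangular":
            if self.mode is None:
                raise ValueError(f"{self.name}: triangular needs a mode")
            if not self.lower <= self.mode <= self.upper:
                raise ValueError(f"{self.name}: mode outside bounds")

    def ppf(self, q: np.ndarray) -> np.ndarray:
        """Inverse CDF at probabilities q."""
        if self.kind == "uniform":
            return stats.uniform.ppf(q, loc=self.lower,
                                     scale=self.upper - self.lower)
        c = (self.mode - self.lower) / (self.upper - self.lower)
        return stats.triang.ppf(q, c, loc=self.lower,
                                scale=self.upper - self.lower)


@dataclass
class SampleMatrix:
    """N x k Latin hypercube sample with its generating metadata."""

    values: np.ndarray  # (N, k)
    names: tuple[str, ...]
    seed: int
    unit_strata: np.ndarray  # (N, k) points in [0, 1) before the ppf map

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.names))

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]


def lhs_sample(distributions: Sequence[ParameterDistribution], n: int,
               seed: int) -> SampleMatrix:
    """Latin hypercube sample: one random point per equal-probability
    stratum per parameter, strata independently permuted per parameter."""
    if n < 1:
        raise ValueError("sample count must be >= 1")
    if not distributions:
        raise ValueError("at least one distribution required")
    rng = np.random.default_rng(seed)
    k = len(distributions)
    unit = np.empty((n, k))
    for j in range(k):
        strata = (np.arange(n) + rng.random(n)) / n  # one point per stratum
        unit[:, j] = rng.permutation(strata)
    values = np.column_stack([d.ppf(unit[:, j])
                              for j, d in enumerate(distributions)])
    return SampleMatrix(values, tuple(d.name for d in distributions),
                        seed, unit)


@dataclass
class MonteCarloResult:
    outputs: pd.DataFrame  # one row per sample, one column per output
    percentiles: pd.DataFrame  # index = percentile, columns = outputs
    failed_indices: tuple[int, ...] = ()

    def to_dict(self) -> dict:
        return {
            "percentiles": {
                str(p): {c: float(self.percentiles.loc[p, c])
                         for c in self.percentiles.columns}
                for p in self.percentiles.index
            },
            "n": int(len(self.outputs)),
            "n_failed": len(self.failed_indices),
        }


def run_monte_carlo(model: Callable[[Mapping[str, float]], Mapping[str, float]],
                    samples: SampleMatrix,
                    max_failure_fraction: float = 0.01) -> MonteCarloResult:
    """Evaluate ``model`` on every sampled parameter vector.

    The model maps a {name: value} dict to a {output: value} dict.
    Failures (exceptions or non-finite outputs) are recorded with their
    sample indices; more than ``max_failure_fraction`` of them aborts.
    """
    rows, failed = [], []
    for i in range(samples.n):
        point = dict(zip(samples.names, samples.values[i]))
        try:
            out = model(point)
            if not all(np.isfinite(v) for v in out.values()):
                raise ValueError("non-finite model output")
            rows.append(out)
        except Exception:
            failed.append(i)
            rows.append(None)
    if len(failed) > max_failure_fraction * samples.n:
        raise RuntimeError(
            f"{len(failed)}/{samples.n} model evaluations failed "
            f"(indices {failed[:10]}...)")
    ok = [r for r in rows if r is not None]
    outputs = pd.DataFrame(ok)
    pct = pd.DataFrame(
        {c: np.percentile(outputs[c], PERCENTILES) for c in outputs.columns},
        index=list(PERCENTILES))
    return MonteCarloResult(outputs, pct, tuple(failed))


@dataclass
class SensitivityResult:
    """Spearman's rho per (parameter, output); NaN where undefined
    (zero rank variance)."""

    rho: pd.DataFrame  # index = parameter, columns = outputs

    def ranked(self, output: str) -> pd.Series:
        return self.rho[output].reindex(
            self.rho[output].abs().sort_values(ascending=False).index)


def spearman_rho(samples: SampleMatrix,
                 outputs: pd.DataFrame | Mapping[str, Sequence[float]]
                 ) -> SensitivityResult:
    """Rank-order correlation of every parameter against every output.

    Average ranks are used for ties; a constant vector has undefined
    rho, reported as NaN.
    """
    out_df = pd.DataFrame(outputs)
    if len(out_df) != samples.n:
        raise ValueError("outputs length does not match sample count")
    if samples.n < 3:
        raise ValueError("need at least 3 samples for rank correlation")
    table = {}
    for col in out_df.columns:
        y = out_df[col].to_numpy(dtype=float)
        rhos = []
        for j in range(len(samples.names)):
            x = samples.values[:, j]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                rhos.append(np.nan)
            else:
                rhos.append(stats.spearmanr(x, y).statistic)
        table[col] = rhos
    return SensitivityResult(pd.DataFrame(table, index=list(samples.names)))


# ---------------------------------------------------------------------------
# distribution file round-trip (CSV layout: name, kind, lower, mode, upper,
# baseline — mode blank for uniform)

def read_parameter_csv(path: str | Path) -> list[ParameterDistribution]:
    df = pd.read_csv(path)
    dists = []
    for _, row in df.iterrows():
        mode = row.get("mode")
        mode = None if pd.isna(mode) else float(mode)
        dists.append(ParameterDistribution(
            name=str(row["name"]), kind=str(row["kind"]),
            baseline=float(row["baseline"]), lower=float(row["lower"]),
            upper=float(row["upper"]), mode=mode))
    return dists


def write_parameter_csv(dists: Sequence[ParameterDistribution],
                        path: str | Path) -> None:
    pd.DataFrame([
        {"name": d.name, "kind": d.kind, "lower": d.lower,
         "mode": "" if d.mode is None else d.mode, "upper": d.upper,
         "baseline": d.baseline}
        for d in dists
    ]).to_csv(path, index=False)
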