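"""Deterministic (tornado) and probabilistic sensitivity analysis.

One-way DSA re-evaluates the model at each parameter's low and high bound
with everything else at base; the tornado ranks parameters by ICER spread.
PSA draws all parameters jointly from their tagged distributions (Gamma for
costs and quantities, Beta for utilities, degenerate for Fixed), re-runs the
cohort model per draw, and summarises decision uncertainty as a
cost-effectiveness acceptability curve: the probability each strategy has
maximal net monetary benefit at each willingness-to-pay value.

Published ranges are treated as 95% intervals, so the bridging standard
deviation is s = (max − min)/3.92; that single assumption lives in
``_range_sd`` only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic_data import ParameterTable

log = logging.getLogger(__name__)

#: default relative variation when a parameter has no published range
DEFAULT_VARIATION = 0.20


@dataclass(frozen=True)
class PsaSettings:
    n_iterations: int = 1000
    seed: int = 0
    wtp_grid: tuple[float, ...] = tuple(float(x) for x in
                                        np.arange(0, 300_001, 10_000))

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if any(b < a for a, b in zip(self.wtp_grid, self.wtp_grid[1:])):
            raise ValueError("wtp_grid must be sorted ascending")


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_value: float
    high_value: float
    icer_at_low: float
    icer_at_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_at_high - self.icer_at_low)


# ---------------------------------------------------------------------------
# deterministic sensitivity

def default_range(base: float, variation: float = DEFAULT_VARIATION
                  ) -> tuple[float, float]:
    """±20% band around the base value, used when no explicit range exists."""
    if not np.isfinite(base):
        raise ValueError("base value must be finite")
    lo, hi = base * (1 - variation), base * (1 + variation)
    return (min(lo, hi), max(lo, hi))


def one_way(parameter: str, table: ParameterTable,
            model_closure: Callable[[Mapping[str, float]], float]
            ) -> TornadoEntry:
    """Re-evaluate the model at the parameter's bounds, all else at base.

    ``model_closure`` maps a complete parameter dict to the quantity of
    interest (typically an ICER).
    """
    if parameter not in table.data.index:
        raise KeyError(f"unknown parameter {parameter!r}")
    base_values = table.base_values()
    lo, hi = table.range(parameter)
    try:
        at_low = model_closure({**base_values, parameter: lo})
        at_high = model_closure({**base_values, parameter: hi})
    except Exception as exc:
        raise RuntimeError(
            f"model evaluation failed while varying {parameter!r}") from exc
    return TornadoEntry(parameter, lo, hi, at_low, at_high)


def tornado(table: ParameterTable,
            model_closure: Callable[[Mapping[str, float]], float],
            parameters: Sequence[str] | None = None) -> list[TornadoEntry]:
    """One-way DSA over every parameter, sorted by ICER spread descending."""
    names = list(parameters) if parameters is not None else table.names()
    entries = [one_way(p, table, model_closure) for p in names]
    return sorted(entries, key=lambda e: -e.spread)


def tornado_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame({
        "parameter": [e.parameter for e in entries],
        "low_value": [e.low_value for e in entries],
        "high_value": [e.high_value for e in entries],
        "icer_at_low": [e.icer_at_low for e in entries],
        "icer_at_high": [e.icer_at_high for e in entries],
        "spread": [e.spread for e in entries],
    })


# ---------------------------------------------------------------------------
# probabilistic sensitivity

def _range_sd(lo: float, hi: float) -> float:
    """Bridge a (min, max) range to a standard deviation, reading the range
    as a 95% interval."""
    return (hi - lo) / 3.92


def draw_parameters(table: ParameterTable, rng: np.random.Generator
                    ) -> dict[str, float]:
    """One joint PSA draw: Gamma rows moment-matched to (base, range-SD),
    Beta rows likewise, Fixed rows at base.  Draws respect support."""
    out: dict[str, float] = {}
    for name, row in table.data.iterrows():
        m = float(row["base"])
        dist = row["distribution"]
        s = _range_sd(float(row["min"]), float(row["max"]))
        if dist == "Fixed" or s <= 0.0 or m == 0.0:
            out[name] = m
        elif dist == "Gamma":
            shape = m * m / (s * s)
            scale = s * s / m
            out[name] = float(rng.gamma(shape, scale))
        elif dist == "Beta":
            s_max = np.sqrt(m * (1.0 - m))
            if s >= s_max:
                log.warning("%s: range SD %.4g infeasible for Beta; shrunk",
                            name, s)
                s = 0.99 * s_max
            nu = m * (1.0 - m) / (s * s) - 1.0
            alpha, beta = m * nu, (1.0 - m) * nu
            out[name] = float(rng.beta(alpha, beta))
        else:
            raise ValueError(f"{name}: unknown distribution tag {dist!r}")
    return out


@dataclass
class PsaResult:
    """Per-iteration discounted (cost, QALY) per strategy."""

    strategies: tuple[str, ...]
    costs: np.ndarray   # (n_iterations, n_strategies)
    qalys: np.ndarray
    seed: int = 0
    draws: list = field(default_factory=list, repr=False)

    def to_frame(self) -> pd.DataFrame:
        frames = {}
        for j, s in enumerate(self.strategies):
            frames[f"cost_{s}"] = self.costs[:, j]
            frames[f"qaly_{s}"] = self.qalys[:, j]
        df = pd.DataFrame(frames)
        df.index.name = "iteration"
        return df


def run_psa(evaluator: Callable[[Mapping[str, float]], Mapping[str, tuple]],
            table: ParameterTable, settings: PsaSettings,
            keep_draws: bool = False) -> PsaResult:
    """Monte-Carlo PSA: each iteration re-runs the full cohort model on one
    joint parameter draw.

    ``evaluator`` maps a parameter dict to {strategy: (cost, qalys)}.  Any
    iteration failure aborts with the iteration index and drawn values in
    the exception chain.
    """
    rng = np.random.default_rng(settings.seed)
    strategies: tuple[str, ...] | None = None
    costs, qalys, draws = [], [], []
    for i in range(settings.n_iterations):
        params = draw_parameters(table, rng)
        try:
            res = evaluator(params)
        except Exception as exc:
            log.error("PSA iteration %d failed; draw: %s", i, params)
            raise RuntimeError(f"PSA iteration {i} failed") from exc
        if strategies is None:
            strategies = tuple(res.keys())
        costs.append([res[s][0] for s in strategies])
        qalys.append([res[s][1] for s in strategies])
        if keep_draws:
            draws.append(params)
    return PsaResult(strategies, np.asarray(costs), np.asarray(qalys),
                     seed=settings.seed, draws=draws)


def ceac(result: PsaResult, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves.

    For each λ, the fraction of iterations in which each strategy attains
    the maximal net monetary benefit λ·QALY − cost; rows sum to 1 (ties go
    to the first strategy in column order).
    """
    grid = np.asarray(list(wtp_grid), dtype=float)
    n_iter, n_strat = result.costs.shape
    probs = np.zeros((len(grid), n_strat))
    for gi, lam in enumerate(grid):
        nmb = lam * result.qalys - result.costs
        winners = np.argmax(nmb, axis=1)
        probs[gi] = np.bincount(winners, minlength=n_strat) / n_iter
    df = pd.DataFrame(probs, columns=list(result.strategies))
    df.insert(0, "wtp", grid)
    return df
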