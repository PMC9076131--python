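"""Pairwise incremental cost-effectiveness analysis.

Given discounted totals per strategy: incremental cost, incremental QALYs,
the ICER (Δcost/ΔQALY) when the pair trades money for health, a dominance
label otherwise, and net monetary benefit at a willingness-to-pay threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .cohort_model import EconOutcome

QALY_EPS = 1e-12  # below this, ΔQALY is treated as exactly zero

LABEL_ICER = "icer"
LABEL_DOMINANT = "dominant"
LABEL_DOMINATED = "dominated"
LABEL_COST_ONLY = "cost-difference-only"
LABEL_EQUIVALENT = "equivalent"


@dataclass(frozen=True)
class IncrementalResult:
    """Incremental comparison of an intervention against a comparator."""

    intervention: str
    comparator: str
    delta_cost: float
    delta_qalys: float
    icer: Optional[float]
    label: str

    def __str__(self):
        pair = f"{self.intervention} vs {self.comparator}"
        if self.label == LABEL_ICER:
            return f"{pair}: ICER ${self.icer:,.2f}/QALY"
        return f"{pair}: {self.label}"


def compare(intervention: EconOutcome, comparator: EconOutcome
            ) -> IncrementalResult:
    """Incremental analysis of two strategies evaluated under one setting.

    The ICER Δcost/ΔQALY is reported when both differences share a sign
    (a genuine trade-off).  Cheaper-and-better is ``dominant``, dearer-and-
    worse is ``dominated``; a pure cost difference at equal QALYs gets no
    ratio.
    """
    dc = intervention.total_cost - comparator.total_cost
    dq = intervention.total_qalys - comparator.total_qalys

    if abs(dq) < QALY_EPS:
        label = LABEL_EQUIVALENT if abs(dc) < 1e-9 else LABEL_COST_ONLY
        return IncrementalResult(intervention.strategy, comparator.strategy,
                                 dc, dq, None, label)
    if dc < 0 and dq > 0:
        label, icer = LABEL_DOMINANT, None
    elif dc > 0 and dq < 0:
        label, icer = LABEL_DOMINATED, None
    elif dc <= 0 and dq < 0:
        # cheaper but worse: still a trade-off ratio (savings per QALY lost)
        label, icer = LABEL_ICER, dc / dq
    else:
        label, icer = LABEL_ICER, dc / dq
    return IncrementalResult(intervention.strategy, comparator.strategy,
                             dc, dq, icer, label)


def nmb(outcome: EconOutcome, wtp: float) -> float:
    """Net monetary benefit λ·QALYs − cost."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * outcome.total_qalys - outcome.total_cost


def incremental_table(outcomes: Sequence[EconOutcome]
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Totals plus all pairwise comparisons, one row per ordered pair with
    higher-cost strategy as intervention (the usual table layout)."""
    totals = pd.DataFrame({
        "strategy": [o.strategy for o in outcomes],
        "total_cost": [o.total_cost for o in outcomes],
        "total_qalys": [o.total_qalys for o in outcomes],
    })
    rows = []
    for i, a in enumerate(outcomes):
        for b in outcomes[i + 1:]:
            hi, lo = (a, b) if a.total_cost >= b.total_cost else (b, a)
            r = compare(hi, lo)
            rows.append({
                "comparison": f"{r.intervention} vs {r.comparator}",
                "delta_cost": r.delta_cost,
                "delta_qalys": r.delta_qalys,
                "icer": r.icer,
                "label": r.label,
            })
    pairs = pd.DataFrame(rows)
    return totals, pairs


def dominance_frontier(outcomes: Sequence[EconOutcome]
                       ) -> list[EconOutcome]:
    """Cost-effectiveness frontier (strict and extended dominance removed).

    Optional output; the base tables report pairwise ICERs only.
    """
    ranked = sorted(outcomes, key=lambda o: (o.total_cost, -o.total_qalys))
    # strict dominance
    frontier: list[EconOutcome] = []
    best_q = -float("inf")
    for o in ranked:
        if o.total_qalys > best_q + QALY_EPS:
            frontier.append(o)
            best_q = o.total_qalys
    # extended dominance: ICERs along the frontier must increase
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for j in range(1, len(frontier) - 1):
            icer_lo = compare(frontier[j], frontier[j - 1]).icer
            icer_hi = compare(frontier[j + 1], frontier[j]).icer
            if icer_lo is not None and icer_hi is not None and icer_lo > icer_hi:
                del frontier[j]
                changed = True
                break
    return frontier
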