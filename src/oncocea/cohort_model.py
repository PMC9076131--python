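"""Three-state partitioned-survival cohort model with cost/QALY accrual.

States are progression-free (PFS), progressed disease (PD) and death.
Occupancy is read directly off the fitted survival curves at each 3-week
cycle: pfs = min(S_PFS, S_OS), dead = 1 − S_OS, pd = the remainder.  Costs
(first-line drugs, adverse-event management, routine disease management,
second-line therapy, best supportive care, end-of-life care) and utilities
accrue per cycle and are discounted annually.

Conventions: months of 365.25/12 days; discounting by (1+r)^(−t/365.25 yr);
state membership evaluated at cycle start (optional half-cycle correction
averages adjacent boundaries).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .survfit import ParametricFit

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = DAYS_PER_YEAR / 12.0


@dataclass(frozen=True)
class ModelSettings:
    """Global cohort-model settings."""

    cycle_length_days: float = 21.0
    discount_rate: float = 0.03          # per year
    wtp: float = 200_000.0               # $ per QALY
    horizon_years: float = 20.0          # operationalises "lifetime"
    half_cycle_correction: bool = False

    def __post_init__(self):
        if self.cycle_length_days <= 0:
            raise ValueError("cycle_length_days must be positive")
        if not 0.0 <= self.discount_rate <= 0.08:
            raise ValueError("discount_rate outside the supported 0–8%/yr range")
        if self.horizon_years * DAYS_PER_YEAR < self.cycle_length_days:
            raise ValueError("horizon shorter than one cycle")

    @property
    def cycle_months(self) -> float:
        return self.cycle_length_days / DAYS_PER_MONTH

    @property
    def cycle_years(self) -> float:
        return self.cycle_length_days / DAYS_PER_YEAR

    @property
    def n_cycles(self) -> int:
        return int(math.ceil(self.horizon_years / self.cycle_years))


@dataclass(frozen=True)
class PatientProfile:
    """Reference patient used for dose calculations."""

    bsa: float = 1.82                     # m^2
    weight: float = 70.0                  # kg
    carboplatin_auc: float = 6.0          # mg·min/mL
    creatinine_clearance: float = 70.0    # mL/min (Calvert formula input)

    def __post_init__(self):
        for name in ("bsa", "weight", "carboplatin_auc",
                     "creatinine_clearance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class DrugDose:
    """One scheduled drug: dosing rule, unit price and billing-unit size."""

    drug: str
    rule: str                 # flat | per_m2 | per_kg | auc
    dose: float               # mg, mg/m^2, mg/kg, or AUC target
    unit_price: float         # $ per billing unit
    unit_size_mg: float       # mg per billing unit

    RULES = ("flat", "per_m2", "per_kg", "auc")

    def __post_init__(self):
        if self.rule not in self.RULES:
            raise ValueError(f"unknown dose rule {self.rule!r}")
        if self.dose <= 0 or self.unit_size_mg <= 0 or self.unit_price < 0:
            raise ValueError(f"invalid dose spec for {self.drug}")

    def dose_mg(self, profile: PatientProfile) -> float:
        if self.rule == "flat":
            return self.dose
        if self.rule == "per_m2":
            return self.dose * profile.bsa
        if self.rule == "per_kg":
            return self.dose * profile.weight
        # Calvert: dose = AUC × (creatinine clearance + 25)
        return self.dose * (profile.creatinine_clearance + 25.0)

    def cost(self, profile: PatientProfile) -> float:
        units = math.ceil(self.dose_mg(profile) / self.unit_size_mg - 1e-9)
        return units * self.unit_price


@dataclass(frozen=True)
class StrategySpec:
    """Everything cost- and utility-related about one treatment strategy."""

    name: str
    drugs: tuple[DrugDose, ...]
    u_pfs: float
    u_pd: float
    management_cost_pfs: float           # $/cycle while progression-free
    management_cost_pd: float            # $/cycle after progression
    sae_expected_cost: float = 0.0       # $ once at model entry
    second_line_cost_per_cycle: float = 0.0
    second_line_duration_cycles: int = 4
    bsc_cost_per_cycle: float = 0.0
    end_of_life_cost: float = 0.0        # $ once at death
    max_treatment_cycles: Optional[int] = None   # e.g. 35 for a 2-year cap
    chemo_cycle_cap: Optional[int] = None        # 4 or 6, chemo only

    def __post_init__(self):
        if not (0.0 <= self.u_pfs <= 1.0 and 0.0 <= self.u_pd <= 1.0):
            raise ValueError(f"{self.name}: utilities must lie in [0, 1]")
        for attr in ("management_cost_pfs", "management_cost_pd",
                     "sae_expected_cost", "second_line_cost_per_cycle",
                     "bsc_cost_per_cycle", "end_of_life_cost"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{self.name}: {attr} must be >= 0")
        for attr in ("second_line_duration_cycles", "max_treatment_cycles",
                     "chemo_cycle_cap"):
            v = getattr(self, attr)
            if v is not None and v < 0:
                raise ValueError(f"{self.name}: {attr} must be >= 0")

    @property
    def drug_cap_cycles(self) -> Optional[int]:
        caps = [c for c in (self.max_treatment_cycles, self.chemo_cycle_cap)
                if c is not None]
        return min(caps) if caps else None


@dataclass
class CohortTrace:
    """Per-cycle state occupancy of the cohort."""

    times_months: np.ndarray
    pfs: np.ndarray
    pd: np.ndarray
    dead: np.ndarray

    def __post_init__(self):
        self.validate()

    @property
    def newly_dead(self) -> np.ndarray:
        return np.diff(self.dead, prepend=0.0)

    @property
    def n_cycles(self) -> int:
        return len(self.times_months)

    def validate(self) -> None:
        total = self.pfs + self.pd + self.dead
        if np.any(np.abs(total - 1.0) > 1e-12):
            raise ValueError("state occupancy does not sum to 1")
        if np.any((self.pfs < -1e-12) | (self.pd < -1e-12)
                  | (self.dead < -1e-12)):
            raise ValueError("negative occupancy")
        if np.any(np.diff(self.dead) < -1e-12):
            raise ValueError("dead fraction decreased")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cycle": np.arange(self.n_cycles),
            "time_months": self.times_months,
            "pfs": self.pfs, "pd": self.pd, "dead": self.dead,
            "newly_dead": self.newly_dead,
        })


@dataclass
class EconOutcome:
    """Discounted totals per strategy plus the undiscounted annual cost
    profile that feeds the budget-impact projection."""

    strategy: str
    total_cost: float
    total_qalys: float
    undiscounted_cost_by_year: np.ndarray
    undiscounted_total_cost: float = 0.0
    undiscounted_total_qalys: float = 0.0
    cost_breakdown: dict = field(default_factory=dict)


def build_trace(pfs_fit: ParametricFit, os_fit: ParametricFit,
                settings: ModelSettings) -> CohortTrace:
    """Partitioned-survival occupancy at each cycle start.

    pfs_k = min(S_PFS(t_k), S_OS(t_k)) (clamped so progression-free never
    exceeds alive), dead_k = 1 − S_OS(t_k), pd_k the remainder.
    """
    k = np.arange(settings.n_cycles)  # cycle-start evaluation
    t = k * settings.cycle_months
    s_os = np.asarray(os_fit.survival(t), dtype=float)
    s_pfs = np.minimum(np.asarray(pfs_fit.survival(t), dtype=float), s_os)
    dead = 1.0 - s_os
    pd_ = 1.0 - s_pfs - dead  # = s_os − s_pfs ≥ 0 after the clamp above
    return CohortTrace(t, s_pfs, pd_, dead)


def drug_cost_per_cycle(strategy: StrategySpec,
                        profile: PatientProfile) -> float:
    """Per-cycle first-line drug acquisition cost for the reference patient.

    Doses resolve per rule (AUC dosing via the Calvert formula), are divided
    by the billing-unit size and rounded UP to whole units (partial vials
    are billed whole), then priced and summed.
    """
    return float(sum(d.cost(profile) for d in strategy.drugs))


def _second_line_occupancy(trace: CohortTrace, duration_cycles: int
                           ) -> np.ndarray:
    """Fraction of the cohort on second-line therapy at each cycle.

    Progression inflow at cycle j is the drop in progression-free occupancy;
    subjects stay on second line for ``duration_cycles`` cycles of PD
    exposure, capped by the actual PD occupancy (death thins the pool).
    """
    inflow = np.maximum(-np.diff(trace.pfs, prepend=trace.pfs[0]), 0.0)
    if duration_cycles <= 0:
        return np.zeros_like(inflow)
    window = np.ones(duration_cycles)
    recent = np.convolve(inflow, window)[: len(inflow)]
    return np.minimum(recent, trace.pd)


def accrue(trace: CohortTrace, strategy: StrategySpec,
           settings: ModelSettings,
           profile: PatientProfile | None = None) -> EconOutcome:
    """Accrue discounted costs and QALYs over the trace for one strategy."""
    profile = profile or PatientProfile()
    n = trace.n_cycles
    k = np.arange(n)
    years = k * settings.cycle_years
    disc = (1.0 + settings.discount_rate) ** (-years)

    pfs, pd_, newly_dead = trace.pfs, trace.pd, trace.newly_dead
    if settings.half_cycle_correction:
        # state membership counted mid-cycle: average adjacent boundaries
        pfs = np.append((pfs[:-1] + pfs[1:]) / 2.0, pfs[-1])
        pd_ = np.append((pd_[:-1] + pd_[1:]) / 2.0, pd_[-1])

    drug_cycle = drug_cost_per_cycle(strategy, profile)
    cap = strategy.drug_cap_cycles
    on_drug = np.ones(n) if cap is None else (k < cap).astype(float)

    sl = _second_line_occupancy(trace, strategy.second_line_duration_cycles)
    bsc = np.maximum(pd_ - sl, 0.0)

    cost_first_line = pfs * (drug_cycle * on_drug + strategy.management_cost_pfs)
    cost_pd = (sl * strategy.second_line_cost_per_cycle
               + bsc * strategy.bsc_cost_per_cycle
               + pd_ * strategy.management_cost_pd)
    cost_death = newly_dead * strategy.end_of_life_cost
    cost_k = cost_first_line + cost_pd + cost_death
    cost_k[0] += strategy.sae_expected_cost

    qaly_k = (pfs * strategy.u_pfs + pd_ * strategy.u_pd) * settings.cycle_years

    total_cost = float(np.sum(disc * cost_k))
    total_qalys = float(np.sum(disc * qaly_k))

    year_idx = np.floor(years).astype(int)
    by_year = np.bincount(year_idx, weights=cost_k)

    return EconOutcome(
        strategy=strategy.name,
        total_cost=total_cost,
        total_qalys=total_qalys,
        undiscounted_cost_by_year=by_year,
        undiscounted_total_cost=float(cost_k.sum()),
        undiscounted_total_qalys=float(qaly_k.sum()),
        cost_breakdown={
            "first_line_drug": float(np.sum(disc * pfs * drug_cycle * on_drug)),
            "management": float(np.sum(disc * (pfs * strategy.management_cost_pfs
                                               + pd_ * strategy.management_cost_pd))),
            "second_line": float(np.sum(disc * sl
                                        * strategy.second_line_cost_per_cycle)),
            "bsc": float(np.sum(disc * bsc * strategy.bsc_cost_per_cycle)),
            "end_of_life": float(np.sum(disc * cost_death)),
            "sae": strategy.sae_expected_cost,
        },
    )


def run_strategy(pfs_fit: ParametricFit, os_fit: ParametricFit,
                 strategy: StrategySpec, settings: ModelSettings,
                 profile: PatientProfile | None = None) -> EconOutcome:
    """Convenience: trace + accrual in one call."""
    trace = build_trace(pfs_fit, os_fit, settings)
    if trace.pfs[-1] + trace.pd[-1] > 0.01:
        import logging
        logging.getLogger(__name__).warning(
            "%.1f%% of the cohort still alive at the %s-year horizon; "
            "consider a longer horizon",
            100 * (trace.pfs[-1] + trace.pd[-1]), settings.horizon_years)
    return accrue(trace, strategy, settings, profile)
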