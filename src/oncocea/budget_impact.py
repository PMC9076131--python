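"""Budget-impact projection over incident cohorts.

Each calendar year a new cohort of eligible patients (incident stage-IV
NSCLC cases × biomarker proportion) starts treatment; every active cohort
contributes its per-patient undiscounted cost difference for its current
year since diagnosis.  The projection matrix is upper-triangular in
(cohort year × calendar year); the net row is the column sum over active
cohorts — the cumulative incremental impact in that calendar year.

Incidence declines geometrically.  The incident count is truncated to whole
patients once, in the first model year; later cohorts decay by the exact
geometric factor so adjacent cohorts' first-year entries scale by
(1 − decline) without re-rounding artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_model import EconOutcome


@dataclass(frozen=True)
class PopulationProjection:
    """Eligible-population model for the projection window."""

    base_count: int = 1312            # incident cases in the base year
    base_year: int = 2015
    annual_decline: float = 0.02      # fraction per year
    biomarker_proportion: float = 0.22
    first_model_year: int = 2020
    n_years: int = 5

    def __post_init__(self):
        if not 0.0 <= self.annual_decline < 1.0:
            raise ValueError("annual_decline must be in [0, 1)")
        if not 0.0 <= self.biomarker_proportion <= 1.0:
            raise ValueError("biomarker_proportion must be in [0, 1]")
        if self.base_count < 0 or self.n_years < 1:
            raise ValueError("counts must be non-negative, n_years >= 1")
        if self.first_model_year < self.base_year:
            raise ValueError("first model year precedes the base year")


def incident_cases(proj: PopulationProjection, year: int) -> int:
    """Projected incident cases in ``year``: geometric decline from the
    base-year count, truncated to whole patients."""
    if year < proj.base_year:
        raise ValueError(f"year {year} precedes base year {proj.base_year}")
    return int(proj.base_count
               * (1.0 - proj.annual_decline) ** (year - proj.base_year))


def eligible_patients(proj: PopulationProjection, year: int) -> float:
    """Biomarker-eligible patients in ``year``; fractional after applying
    the biomarker proportion to the truncated incident count."""
    return incident_cases(proj, year) * proj.biomarker_proportion


def per_patient_cost_diff_profile(ici_outcome: EconOutcome,
                                  chemo_outcome: EconOutcome,
                                  n_years: int) -> np.ndarray:
    """Per-patient undiscounted annual cost difference (ICI − chemo) for
    years 1..n_years since treatment start."""
    a = ici_outcome.undiscounted_cost_by_year
    b = chemo_outcome.undiscounted_cost_by_year
    if len(a) < n_years or len(b) < n_years:
        raise ValueError(f"outcome horizons shorter than {n_years} years")
    return a[:n_years] - b[:n_years]


@dataclass
class BIAMatrix:
    """Cohort-year × calendar-year incremental expenditure."""

    years: np.ndarray        # calendar years, length n
    entries: np.ndarray      # (n, n) with entries[c, y] = 0 for y < c

    @property
    def net(self) -> np.ndarray:
        """Net incremental budget per calendar year = column sums."""
        return self.entries.sum(axis=0)

    @property
    def cumulative(self) -> np.ndarray:
        """Running total of the net row across calendar years."""
        return np.cumsum(self.net)

    def to_frame(self) -> pd.DataFrame:
        cols = [str(int(y)) for y in self.years]
        df = pd.DataFrame(self.entries, columns=cols,
                          index=[str(int(y)) for y in self.years])
        df.index.name = "cohort_year"
        df.loc["net"] = self.net
        df.loc["cumulative"] = self.cumulative
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, float_format="%.2f")


def project(proj: PopulationProjection, profile: np.ndarray) -> BIAMatrix:
    """Project cohort expenditures across calendar years.

    entries[c, y] = eligible(first year) · (1 − decline)^(c) · profile[y − c]
    for calendar year index y ≥ cohort index c.
    """
    profile = np.asarray(profile, dtype=float)
    if len(profile) != proj.n_years:
        raise ValueError(f"profile length {len(profile)} != n_years "
                         f"{proj.n_years}")
    years = proj.first_model_year + np.arange(proj.n_years)
    first_cohort = eligible_patients(proj, proj.first_model_year)
    entries = np.zeros((proj.n_years, proj.n_years))
    for c in range(proj.n_years):
        cohort_size = first_cohort * (1.0 - proj.annual_decline) ** c
        for y in range(c, proj.n_years):
            entries[c, y] = cohort_size * profile[y - c]
    return BIAMatrix(years, entries)
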