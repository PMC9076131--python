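"""Scenario configuration: validation, (de)serialisation, defaults.

A :class:`Scenario` bundles everything one analysis run needs — model
settings, the reference patient, strategy definitions (dosing schedules and
which parameter-table rows feed their costs and utilities), the synthetic
trial design or digitized-curve file paths, PSA settings and the population
projection.  Validation is collected by pydantic, so a broken file reports
every violation at once, each named with its config path.

Strategy costs and utilities are *references* into the parameter table
rather than literal numbers; that single indirection is what lets the
tornado and the PSA re-price a strategy by overriding one table row.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Mapping, Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .budget_impact import PopulationProjection
from .cohort_model import (DrugDose, ModelSettings, PatientProfile,
                           StrategySpec)
from .sensitivity import PsaSettings
from .synthetic_data import (ParameterTable, TrialScenario,
                             default_trial_scenario, make_parameter_set)

# parameter-table rows with special roles
ROW_BSA = "BSA (m2)"
ROW_WEIGHT = "Body weight (kg)"
ROW_AUC = "AUC"
ROW_DISCOUNT = "Discount rate (%)"


class DrugConfig(BaseModel):
    """One scheduled drug; its unit price comes from the parameter table."""

    drug: str
    rule: Literal["flat", "per_m2", "per_kg", "auc"]
    dose: float = Field(gt=0)          # mg, mg/m2, mg/kg or AUC target
    price_param: str                   # parameter-table row with the price
    unit_size_mg: float = Field(gt=0)
    share: float = Field(default=1.0, ge=0, le=1)  # mix weight (2nd line)


class StrategyConfig(BaseModel):
    name: str
    drugs: list[DrugConfig]
    utility_pfs_param: str
    utility_pd_param: str
    management_pfs_param: str = "Disease management in PFS"
    management_pd_param: str = "Disease management in PD"
    bsc_param: str = "BSC"
    end_of_life_param: str = "End of life"
    sae_incidences: dict[str, float] = Field(default_factory=dict)
    second_line_drugs: list[DrugConfig] = Field(default_factory=list)
    second_line_duration_cycles: int = Field(default=4, ge=0)
    max_treatment_cycles: Optional[int] = Field(default=None, ge=0)
    chemo_cycle_cap: Optional[int] = Field(default=None, ge=0)

    @field_validator("sae_incidences")
    @classmethod
    def _incidences_are_fractions(cls, v):
        bad = {k: x for k, x in v.items() if not 0.0 <= x <= 1.0}
        if bad:
            raise ValueError(f"SAE incidences outside [0, 1]: {bad}")
        return v


class ModelConfig(BaseModel):
    cycle_length_days: float = Field(default=21.0, gt=0)
    wtp: float = Field(default=200_000.0, ge=0)
    horizon_years: float = Field(default=20.0, gt=0)
    half_cycle_correction: bool = False


class PsaConfig(BaseModel):
    n_iterations: int = Field(default=1000, ge=1)
    seed: int = 0
    wtp_max: float = Field(default=300_000.0, gt=0)
    wtp_step: float = Field(default=10_000.0, gt=0)

    def settings(self) -> PsaSettings:
        import numpy as np
        grid = tuple(float(x) for x in
                     np.arange(0.0, self.wtp_max + 1e-9, self.wtp_step))
        return PsaSettings(self.n_iterations, self.seed, grid)


class PopulationConfig(BaseModel):
    base_count: int = Field(default=1312, ge=0)
    base_year: int = 2015
    annual_decline: float = Field(default=0.02, ge=0, lt=1)
    biomarker_proportion: float = Field(default=0.22, ge=0, le=1)
    first_model_year: int = 2020
    n_years: int = Field(default=5, ge=1)

    def projection(self) -> PopulationProjection:
        return PopulationProjection(self.base_count, self.base_year,
                                    self.annual_decline,
                                    self.biomarker_proportion,
                                    self.first_model_year, self.n_years)


class CurveFiles(BaseModel):
    """Digitized-curve inputs for one arm/endpoint (alternative to synth)."""

    arm: str
    endpoint: Literal["PFS", "OS"]
    curve_csv: str
    risk_csv: Optional[str] = None
    total_events: Optional[int] = Field(default=None, ge=0)


class Scenario(BaseModel):
    """Complete, validated configuration of one analysis run."""

    name: str = "default"
    model: ModelConfig = Field(default_factory=ModelConfig)
    creatinine_clearance: float = Field(default=70.0, gt=0)
    strategies: list[StrategyConfig]
    trial: Optional[dict] = None          # TrialScenario JSON dict
    curves: list[CurveFiles] = Field(default_factory=list)
    parameter_table_path: Optional[str] = None
    psa: PsaConfig = Field(default_factory=PsaConfig)
    population: PopulationConfig = Field(default_factory=PopulationConfig)
    dsa_intervention: str = "atezolizumab"
    dsa_comparator: str = "chemotherapy"
    bia_intervention: str = "atezolizumab"
    bia_comparator: str = "chemotherapy"

    @model_validator(mode="after")
    def _check_cross_references(self):
        names = [s.name for s in self.strategies]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate strategy names: {names}")
        for role in ("dsa_intervention", "dsa_comparator",
                     "bia_intervention", "bia_comparator"):
            if getattr(self, role) not in names:
                raise ValueError(f"{role}={getattr(self, role)!r} is not a "
                                 f"configured strategy ({names})")
        if self.trial is None and not self.curves:
            raise ValueError("either a synthetic trial or digitized curve "
                             "files must be configured")
        table = self.load_parameter_table()
        known = set(table.names())
        errs = []
        for s in self.strategies:
            refs = ([d.price_param for d in s.drugs]
                    + [d.price_param for d in s.second_line_drugs]
                    + [s.utility_pfs_param, s.utility_pd_param,
                       s.management_pfs_param, s.management_pd_param,
                       s.bsc_param, s.end_of_life_param]
                    + list(s.sae_incidences))
            for r in refs:
                if r not in known:
                    errs.append(f"strategies[{s.name}]: unknown parameter "
                                f"reference {r!r}")
            for up in (s.utility_pfs_param, s.utility_pd_param):
                if up in known and table.distribution(up) != "Beta":
                    errs.append(f"strategies[{s.name}]: utility reference "
                                f"{up!r} is not a Beta row")
        if errs:
            raise ValueError("; ".join(errs))
        return self

    def load_parameter_table(self) -> ParameterTable:
        if self.parameter_table_path:
            return ParameterTable.from_csv(self.parameter_table_path)
        return make_parameter_set()

    def trial_scenario(self, seed: int | None = None) -> TrialScenario:
        if self.trial is None:
            raise ValueError("scenario has no synthetic trial configured")
        ts = TrialScenario.from_json_dict(self.trial)
        if seed is not None:
            ts.seed = seed
        return ts

    # -- serialisation ------------------------------------------------------

    def save(self, path) -> None:
        path = Path(path)
        data = self.model_dump(mode="json")
        with open(path, "w") as fh:
            if path.suffix in (".yaml", ".yml"):
                yaml.safe_dump(data, fh, sort_keys=False)
            else:
                json.dump(data, fh, indent=2)


def load_and_validate(path) -> Scenario:
    """Load a scenario from JSON or YAML; pydantic reports *all* violations,
    each with its config path."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"scenario file not found: {path}")
    with open(path) as fh:
        data = (yaml.safe_load(fh) if path.suffix in (".yaml", ".yml")
                else json.load(fh))
    scenario = Scenario.model_validate(data)
    for cf in scenario.curves:
        if not Path(cf.curve_csv).exists():
            raise FileNotFoundError(
                f"curves[{cf.arm}/{cf.endpoint}].curve_csv: missing file "
                f"{cf.curve_csv}")
        if cf.risk_csv and not Path(cf.risk_csv).exists():
            raise FileNotFoundError(
                f"curves[{cf.arm}/{cf.endpoint}].risk_csv: missing file "
                f"{cf.risk_csv}")
    return scenario


# ---------------------------------------------------------------------------
# building runtime objects from a parameter draw

def build_profile(scenario: Scenario, params: Mapping[str, float]
                  ) -> PatientProfile:
    return PatientProfile(bsa=params[ROW_BSA], weight=params[ROW_WEIGHT],
                          carboplatin_auc=params[ROW_AUC],
                          creatinine_clearance=scenario.creatinine_clearance)


def build_settings(scenario: Scenario, params: Mapping[str, float]
                   ) -> ModelSettings:
    return ModelSettings(
        cycle_length_days=scenario.model.cycle_length_days,
        discount_rate=params[ROW_DISCOUNT] / 100.0,
        wtp=scenario.model.wtp,
        horizon_years=scenario.model.horizon_years,
        half_cycle_correction=scenario.model.half_cycle_correction,
    )


def _dose_value(d: DrugConfig, params: Mapping[str, float]) -> float:
    # AUC-based dosing reads the (possibly varied) AUC parameter
    return params[ROW_AUC] if d.rule == "auc" else d.dose


def build_strategy(cfg: StrategyConfig, params: Mapping[str, float],
                   profile: PatientProfile) -> StrategySpec:
    """Resolve a strategy config against one parameter draw."""
    drugs = tuple(
        DrugDose(d.drug, d.rule, _dose_value(d, params),
                 unit_price=params[d.price_param],
                 unit_size_mg=d.unit_size_mg)
        for d in cfg.drugs)
    second_line_cost = sum(
        d.share * DrugDose(d.drug, d.rule, _dose_value(d, params),
                           unit_price=params[d.price_param],
                           unit_size_mg=d.unit_size_mg).cost(profile)
        for d in cfg.second_line_drugs)
    sae = sum(inc * params[row] for row, inc in cfg.sae_incidences.items())
    clip01 = lambda u: min(max(u, 0.0), 1.0)
    return StrategySpec(
        name=cfg.name,
        drugs=drugs,
        u_pfs=clip01(params[cfg.utility_pfs_param]),
        u_pd=clip01(params[cfg.utility_pd_param]),
        management_cost_pfs=params[cfg.management_pfs_param],
        management_cost_pd=params[cfg.management_pd_param],
        sae_expected_cost=sae,
        second_line_cost_per_cycle=second_line_cost,
        second_line_duration_cycles=cfg.second_line_duration_cycles,
        bsc_cost_per_cycle=params[cfg.bsc_param],
        end_of_life_cost=params[cfg.end_of_life_param],
        max_treatment_cycles=cfg.max_treatment_cycles,
        chemo_cycle_cap=cfg.chemo_cycle_cap,
    )


# ---------------------------------------------------------------------------
# packaged default scenario

def default_scenario(seed: int = 0, n_per_arm: int = 300,
                     psa_iterations: int = 1000) -> Scenario:
    """The packaged synthetic scenario: a high-PD-L1-like three-arm trial
    with the default parameter table and trial-protocol dosing."""
    chemo = StrategyConfig(
        name="chemotherapy",
        drugs=[
            DrugConfig(drug="carboplatin", rule="auc", dose=6.0,
                       price_param="Carboplatin (50 mg)", unit_size_mg=50.0),
            DrugConfig(drug="pemetrexed", rule="per_m2", dose=500.0,
                       price_param="Pemetrexed (10 mg)", unit_size_mg=10.0),
        ],
        utility_pfs_param="PFS of Chemotherapy",
        utility_pd_param="PD of Chemotherapy",
        sae_incidences={"Anemia": 0.15, "Neutropenia": 0.20,
                        "Thrombocytopenia": 0.08, "Nausea": 0.08},
        second_line_drugs=[
            DrugConfig(drug="nivolumab", rule="per_kg", dose=3.0,
                       price_param="Nivolumab (1 mg)", unit_size_mg=1.0,
                       share=0.5),
            DrugConfig(drug="docetaxel", rule="per_m2", dose=75.0,
                       price_param="Docetaxel (50 mg)", unit_size_mg=50.0,
                       share=0.5),
        ],
        chemo_cycle_cap=4,
    )
    pembro = StrategyConfig(
        name="pembrolizumab",
        drugs=[DrugConfig(drug="pembrolizumab", rule="flat", dose=200.0,
                          price_param="Pembrolizumab (1 mg)",
                          unit_size_mg=1.0)],
        utility_pfs_param="PFS of Pembrolizumab in high PD-L1 expression",
        utility_pd_param="PD of Pembrolizumab in high PD-L1 expression",
        sae_incidences={"Pneumonia": 0.03, "Asthenia": 0.02},
        second_line_drugs=[
            DrugConfig(drug="docetaxel", rule="per_m2", dose=75.0,
                       price_param="Docetaxel (50 mg)", unit_size_mg=50.0),
        ],
        max_treatment_cycles=35,   # 2-year protocol cap
    )
    atezo = StrategyConfig(
        name="atezolizumab",
        drugs=[DrugConfig(drug="atezolizumab", rule="flat", dose=1200.0,
                          price_param="Atezolizumab (10 mg)",
                          unit_size_mg=10.0)],
        utility_pfs_param="PFS of Atezolizumab",
        utility_pd_param="PD of Atezolizumab",
        sae_incidences={"Pneumonia": 0.03, "Asthenia": 0.02},
        second_line_drugs=[
            DrugConfig(drug="docetaxel", rule="per_m2", dose=75.0,
                       price_param="Docetaxel (50 mg)", unit_size_mg=50.0),
        ],
        max_treatment_cycles=None,  # until progression
    )
    return Scenario(
        name="synthetic-high-pdl1",
        strategies=[chemo, pembro, atezo],
        trial=default_trial_scenario(seed=seed,
                                     n_per_arm=n_per_arm).to_json_dict(),
        psa=PsaConfig(n_iterations=psa_iterations, seed=seed),
    )
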