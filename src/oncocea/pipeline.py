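"""Stage pipeline: synth → reconstruct → fit → trace → evaluate → dsa/psa/bia.

Each stage reads its inputs from, and writes its artifacts to, a run
directory, so stages can be re-run independently; a missing upstream
artifact raises an error naming the stage to run first.  A run-metadata
JSON beside the outputs records the seed, package version and stage
timings.

Monetary values are printed with 2 decimals and probabilities with 4;
internal computation is full precision.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .budget_impact import (BIAMatrix, eligible_patients,
                            per_patient_cost_diff_profile, project)
from .cohort_model import CohortTrace, EconOutcome, accrue, build_trace
from .config import (Scenario, build_profile, build_settings, build_strategy)
from .econ_eval import compare, incremental_table
from .km_reconstruct import (DigitizedCurve, IPDSet, reconstruct_ipd,
                             reconstruction_error)
from .sensitivity import ceac, run_psa, tornado, tornado_frame
from .survfit import ParametricFit, fit_all_and_select
from .synthetic_data import (default_grids, digitize, digitize_steps,
                             generate_arm_ipd)

log = logging.getLogger(__name__)

ENDPOINTS = ("PFS", "OS")
STAGES = ("synth", "reconstruct", "fit", "trace", "evaluate",
          "dsa", "psa", "bia")


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run the '{stage}' stage first")
    return path


def _slug(name: str) -> str:
    return name.replace(" ", "_").replace("/", "-")


# ---------------------------------------------------------------------------
# stages

def stage_synth(scenario: Scenario, outdir: Path, seed: int | None = None
                ) -> None:
    """Generate trial-like IPD and the derived digitized artefacts."""
    d = outdir / "synth"
    d.mkdir(parents=True, exist_ok=True)
    ts = scenario.trial_scenario(seed)
    ts.save(d / "trial_scenario.json")
    _, risk_times = default_grids(ts.max_followup)
    for arm in ts.arm_names:
        pfs, os_ = generate_arm_ipd(ts, arm)
        for ipd in (pfs, os_):
            tag = f"{_slug(arm)}_{ipd.endpoint}"
            ipd.to_csv(d / f"ipd_{tag}.csv")
            # step-accurate coordinates: what a digitizer actually traces
            curve = digitize_steps(ipd, risk_times)
            curve.to_csv(d / f"curve_{tag}.csv", d / f"risk_{tag}.csv")


def stage_reconstruct(scenario: Scenario, outdir: Path) -> None:
    """Reconstruct pseudo-IPD from every digitized curve and report
    fidelity."""
    d = outdir / "recon"
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for arm, endpoint, curve, total_events in _iter_curves(scenario, outdir):
        ipd = reconstruct_ipd(curve, total_events)
        tag = f"{_slug(arm)}_{endpoint}"
        ipd.to_csv(d / f"ipd_{tag}.csv")
        max_dev, mean_dev = reconstruction_error(curve, ipd)
        rows.append({"arm": arm, "endpoint": endpoint, "n": ipd.n,
                     "events": ipd.n_events, "max_abs_dev": max_dev,
                     "mean_abs_dev": mean_dev})
    pd.DataFrame(rows).to_csv(d / "fidelity.csv", index=False,
                              float_format="%.4f")


def _iter_curves(scenario: Scenario, outdir: Path):
    """Yield (arm, endpoint, DigitizedCurve, total_events) from configured
    files or the synth stage."""
    if scenario.curves:
        for cf in scenario.curves:
            curve = DigitizedCurve.from_csv(cf.curve_csv, cf.risk_csv,
                                            arm=cf.arm, endpoint=cf.endpoint)
            yield cf.arm, cf.endpoint, curve, cf.total_events
        return
    ts = scenario.trial_scenario()
    for arm in ts.arm_names:
        for endpoint in ENDPOINTS:
            tag = f"{_slug(arm)}_{endpoint}"
            cpath = _require(outdir / "synth" / f"curve_{tag}.csv", "synth")
            rpath = _require(outdir / "synth" / f"risk_{tag}.csv", "synth")
            curve = DigitizedCurve.from_csv(cpath, rpath, arm=arm,
                                            endpoint=endpoint)
            yield arm, endpoint, curve, None


def _arms(scenario: Scenario) -> list[str]:
    if scenario.curves:
        return list(dict.fromkeys(cf.arm for cf in scenario.curves))
    return list(scenario.trial_scenario().arm_names)


def stage_fit(scenario: Scenario, outdir: Path) -> None:
    """Fit the five parametric families per arm/endpoint; select by AIC."""
    d = outdir / "fits"
    d.mkdir(parents=True, exist_ok=True)
    for arm in _arms(scenario):
        for endpoint in ENDPOINTS:
            tag = f"{_slug(arm)}_{endpoint}"
            ipd = IPDSet.from_csv(
                _require(outdir / "recon" / f"ipd_{tag}.csv", "reconstruct"),
                arm=arm, endpoint=endpoint)
            fits, best = fit_all_and_select(ipd.times, ipd.events)
            with open(d / f"fits_{tag}.json", "w") as fh:
                json.dump({"all": [f.to_json_dict() for f in fits],
                           "best": best.to_json_dict()}, fh, indent=2)


def load_fits(outdir: Path, arm: str, endpoint: str) -> ParametricFit:
    tag = f"{_slug(arm)}_{endpoint}"
    path = _require(outdir / "fits" / f"fits_{tag}.json", "fit")
    with open(path) as fh:
        return ParametricFit.from_json_dict(json.load(fh)["best"])


def _traces(scenario: Scenario, outdir: Path,
            params: Mapping[str, float]) -> dict[str, CohortTrace]:
    settings = build_settings(scenario, params)
    out = {}
    for s in scenario.strategies:
        pfs_fit = load_fits(outdir, s.name, "PFS")
        os_fit = load_fits(outdir, s.name, "OS")
        out[s.name] = build_trace(pfs_fit, os_fit, settings)
    return out


def stage_trace(scenario: Scenario, outdir: Path) -> None:
    """Write the per-strategy three-state occupancy traces."""
    d = outdir / "trace"
    d.mkdir(parents=True, exist_ok=True)
    params = scenario.load_parameter_table().base_values()
    for name, trace in _traces(scenario, outdir, params).items():
        trace.to_frame().to_csv(d / f"trace_{_slug(name)}.csv", index=False,
                                float_format="%.6f")


def base_outcomes(scenario: Scenario, outdir: Path
                  ) -> dict[str, EconOutcome]:
    """Outcomes of every strategy at base-case parameters."""
    params = scenario.load_parameter_table().base_values()
    profile = build_profile(scenario, params)
    settings = build_settings(scenario, params)
    traces = _traces(scenario, outdir, params)
    out = {}
    for cfg in scenario.strategies:
        spec = build_strategy(cfg, params, profile)
        out[cfg.name] = accrue(traces[cfg.name], spec, settings, profile)
    return out


def stage_evaluate(scenario: Scenario, outdir: Path) -> None:
    """Base-case totals and pairwise incremental results."""
    d = outdir / "evaluate"
    d.mkdir(parents=True, exist_ok=True)
    outcomes = base_outcomes(scenario, outdir)
    ordered = [outcomes[s.name] for s in scenario.strategies]
    totals, pairs = incremental_table(ordered)
    totals.to_csv(d / "totals.csv", index=False, float_format="%.2f")
    pairs.to_csv(d / "incremental.csv", index=False, float_format="%.2f")
    with open(d / "outcomes.json", "w") as fh:
        json.dump({name: {
            "total_cost": o.total_cost,
            "total_qalys": o.total_qalys,
            "undiscounted_cost_by_year": o.undiscounted_cost_by_year.tolist(),
            "cost_breakdown": o.cost_breakdown,
        } for name, o in outcomes.items()}, fh, indent=2)


def make_evaluator(scenario: Scenario, outdir: Path
                   ) -> Callable[[Mapping[str, float]],
                                 dict[str, tuple[float, float]]]:
    """Closure re-running the accrual for every strategy on one parameter
    set.  Survival fits stay at their base estimates (the parameter table
    carries no survival rows); traces are rebuilt only if the discount rate
    moves, which does not affect occupancy, so they are cached."""
    params0 = scenario.load_parameter_table().base_values()
    traces = _traces(scenario, outdir, params0)

    def evaluate(params: Mapping[str, float]
                 ) -> dict[str, tuple[float, float]]:
        profile = build_profile(scenario, params)
        settings = build_settings(scenario, params)
        res = {}
        for cfg in scenario.strategies:
            spec = build_strategy(cfg, params, profile)
            o = accrue(traces[cfg.name], spec, settings, profile)
            res[cfg.name] = (o.total_cost, o.total_qalys)
        return res

    return evaluate


def make_icer_closure(scenario: Scenario, outdir: Path,
                      intervention: str, comparator: str
                      ) -> Callable[[Mapping[str, float]], float]:
    evaluate = make_evaluator(scenario, outdir)

    def icer(params: Mapping[str, float]) -> float:
        res = evaluate(params)
        ci, qi = res[intervention]
        cc, qc = res[comparator]
        a = EconOutcome(intervention, ci, qi, np.array([]))
        b = EconOutcome(comparator, cc, qc, np.array([]))
        r = compare(a, b)
        return r.icer if r.icer is not None else float("nan")

    return icer


def stage_dsa(scenario: Scenario, outdir: Path) -> None:
    """One-way tornado on the configured intervention/comparator ICER."""
    d = outdir / "dsa"
    d.mkdir(parents=True, exist_ok=True)
    table = scenario.load_parameter_table()
    closure = make_icer_closure(scenario, outdir, scenario.dsa_intervention,
                                scenario.dsa_comparator)
    entries = tornado(table, closure)
    tornado_frame(entries).to_csv(d / "tornado.csv", index=False,
                                  float_format="%.2f")


def stage_psa(scenario: Scenario, outdir: Path, seed: int | None = None
              ) -> None:
    """Probabilistic sensitivity analysis and acceptability curves."""
    d = outdir / "psa"
    d.mkdir(parents=True, exist_ok=True)
    settings = scenario.psa.settings()
    if seed is not None:
        from dataclasses import replace
        settings = replace(settings, seed=seed)
    table = scenario.load_parameter_table()
    evaluate = make_evaluator(scenario, outdir)
    result = run_psa(evaluate, table, settings)
    result.to_frame().to_csv(d / "psa_draws.csv", float_format="%.2f")
    curves = ceac(result, settings.wtp_grid)
    curves.to_csv(d / "ceac.csv", index=False, float_format="%.4f")
    with open(d / "psa_metadata.json", "w") as fh:
        json.dump({"seed": settings.seed,
                   "n_iterations": settings.n_iterations}, fh)


def stage_bia(scenario: Scenario, outdir: Path) -> BIAMatrix:
    """Budget-impact projection for the configured ICI vs chemo pair."""
    d = outdir / "bia"
    d.mkdir(parents=True, exist_ok=True)
    path = _require(outdir / "evaluate" / "outcomes.json", "evaluate")
    with open(path) as fh:
        data = json.load(fh)
    proj = scenario.population.projection()

    def as_outcome(name: str) -> EconOutcome:
        o = data[name]
        return EconOutcome(name, o["total_cost"], o["total_qalys"],
                           np.asarray(o["undiscounted_cost_by_year"]))

    profile = per_patient_cost_diff_profile(
        as_outcome(scenario.bia_intervention),
        as_outcome(scenario.bia_comparator), proj.n_years)
    matrix = project(proj, profile)
    matrix.to_csv(d / "bia.csv")
    pd.DataFrame({
        "year": matrix.years,
        "eligible_patients": [eligible_patients(proj, int(y))
                              for y in matrix.years],
        "per_patient_diff_year1": profile[0],
    }).to_csv(d / "population.csv", index=False, float_format="%.2f")
    return matrix


# ---------------------------------------------------------------------------
# orchestration

_STAGE_FUNCS = {
    "synth": stage_synth,
    "reconstruct": stage_reconstruct,
    "fit": stage_fit,
    "trace": stage_trace,
    "evaluate": stage_evaluate,
    "dsa": stage_dsa,
    "psa": stage_psa,
    "bia": stage_bia,
}

_SEEDED = {"synth", "psa"}


def run(stage: str, scenario: Scenario, outdir, seed: int | None = None
        ) -> None:
    """Run one stage (or ``all``) and append run metadata."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(STAGES) if stage == "all" else [stage]
    if any(s not in _STAGE_FUNCS for s in stages):
        raise ValueError(f"unknown stage {stage!r}; choose from "
                         f"{STAGES + ('all',)}")
    timings = {}
    for s in stages:
        t0 = time.perf_counter()
        if s in _SEEDED:
            _STAGE_FUNCS[s](scenario, outdir, seed)
        else:
            _STAGE_FUNCS[s](scenario, outdir)
        timings[s] = round(time.perf_counter() - t0, 3)
        log.info("stage %s finished in %.2fs", s, timings[s])
    meta_path = outdir / "run_metadata.json"
    meta = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
    meta.setdefault("package_version", __version__)
    meta.setdefault("scenario", scenario.name)
    meta["seed"] = seed
    meta.setdefault("stage_timings", {}).update(timings)
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2)
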