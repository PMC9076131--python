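"""Parametric survival fitting for right-censored individual patient data.

Five candidate families — exponential, Weibull, log-normal, log-logistic and
gamma — are fitted by maximum likelihood and compared by AIC.  The selected
curve is what the cohort engine extrapolates beyond trial follow-up, so the
fitting surface is deliberately small: a censored log-likelihood, one ``fit``
per family, and an AIC-based selector.

All times are in months.  Parameterisations follow ``scipy.stats``:

========== ==================== =========================================
family     parameters           survival function
========== ==================== =========================================
exponential rate θ              S(t) = exp(−θ t)
weibull     shape k, scale λ    S(t) = exp(−(t/λ)^k)
lognormal   mu, sigma           S(t) = 1 − Φ((ln t − mu)/sigma)
loglogistic shape a, scale b    S(t) = 1 / (1 + (t/b)^a)
gamma       shape a, scale b    S(t) = 1 − Γ-cdf(t; a, b)
========== ==================== =========================================
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize, stats

log = logging.getLogger(__name__)

#: smallest event time used in density evaluations; avoids f(0)=0 blow-ups
EPS_TIME = 1e-8

#: AIC differences below this are treated as ties (float equality is noise)
AIC_TIE_TOL = 1e-6

#: fixed family order used for tie-breaking after the parameter-count rule
FAMILY_ORDER = ("exponential", "weibull", "lognormal", "loglogistic", "gamma")


class _Family:
    """One parametric family: scipy frozen-dist factory plus start values."""

    def __init__(self, name, param_names, freeze, start):
        self.name = name
        self.param_names = tuple(param_names)
        self.n_params = len(param_names)
        self._freeze = freeze
        self._start = start

    def dist(self, params: Sequence[float]):
        return self._freeze(*params)

    def start_values(self, times, events):
        return np.asarray(self._start(times, events), dtype=float)


def _weibull_plot_start(times, events):
    """Least-squares line on ln(−ln S_KM) vs ln t (the Weibull plot)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    # crude KM at event times; enough for a starting point
    order = np.argsort(t)
    t, e = t[order], e[order]
    n = len(t)
    at_risk = n - np.arange(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.cumprod(1.0 - e / at_risk)
    mask = e.astype(bool) & (s > 1e-10) & (s < 1 - 1e-10) & (t > 0)
    if mask.sum() >= 2:
        x = np.log(t[mask])
        y = np.log(-np.log(s[mask]))
        k, c = np.polyfit(x, y, 1)
        k = float(np.clip(k, 0.05, 20.0))
        lam = float(np.exp(-c / k))
        if np.isfinite(lam) and lam > 0:
            return k, lam
    # fall back to exponential-like start
    total = max(t.sum(), EPS_TIME)
    rate = max(e.sum(), 1) / total
    return 1.0, 1.0 / rate


def _lognormal_start(times, events):
    t = np.asarray(times, dtype=float)
    lt = np.log(np.maximum(t[np.asarray(events, bool)] if np.any(events) else t,
                           EPS_TIME))
    mu = float(np.mean(lt))
    sigma = float(np.std(lt) or 1.0)
    return mu, max(sigma, 0.05)


def _loglogistic_start(times, events):
    mu, sigma = _lognormal_start(times, events)
    # logistic scale ≈ normal sigma·√3/π; shape is its reciprocal
    a = np.pi / (max(sigma, 0.05) * np.sqrt(3.0))
    return max(a, 0.1), float(np.exp(mu))


def _gamma_start(times, events):
    t = np.asarray(times, dtype=float)
    te = t[np.asarray(events, bool)] if np.any(events) else t
    m = float(np.mean(te))
    v = float(np.var(te)) or m**2
    shape = max(m**2 / v, 0.05)
    return shape, m / shape


FAMILIES: Mapping[str, _Family] = {
    "exponential": _Family(
        "exponential", ("rate",),
        lambda rate: stats.expon(scale=1.0 / rate),
        lambda t, e: (max(np.sum(e), 1) / max(np.sum(t), EPS_TIME),),
    ),
    "weibull": _Family(
        "weibull", ("shape", "scale"),
        lambda k, lam: stats.weibull_min(c=k, scale=lam),
        _weibull_plot_start,
    ),
    "lognormal": _Family(
        "lognormal", ("mu", "sigma"),
        lambda mu, sigma: stats.lognorm(s=sigma, scale=np.exp(mu)),
        _lognormal_start,
    ),
    "loglogistic": _Family(
        "loglogistic", ("shape", "scale"),
        lambda a, b: stats.fisk(c=a, scale=b),
        _loglogistic_start,
    ),
    "gamma": _Family(
        "gamma", ("shape", "scale"),
        lambda a, b: stats.gamma(a=a, scale=b),
        _gamma_start,
    ),
}


@dataclass(frozen=True)
class ParametricFit:
    """A fitted survival distribution with its likelihood and AIC."""

    family: str
    params: tuple[float, ...]
    log_likelihood: float
    aic: float
    n_records: int
    converged: bool
    param_names: tuple[str, ...] = field(default=(), compare=False)

    def survival(self, t):
        return survival(self, t)

    def params_dict(self) -> dict[str, float]:
        return dict(zip(self.param_names, self.params))

    def to_json_dict(self) -> dict:
        return {
            "family": self.family,
            "params": self.params_dict(),
            "log_likelihood": self.log_likelihood,
            "aic": self.aic,
            "n_records": self.n_records,
            "converged": self.converged,
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "ParametricFit":
        fam = FAMILIES[d["family"]]
        params = tuple(float(d["params"][p]) for p in fam.param_names)
        return cls(d["family"], params, float(d["log_likelihood"]),
                   float(d["aic"]), int(d["n_records"]), bool(d["converged"]),
                   fam.param_names)


def _validate_params(family: str, params) -> np.ndarray:
    if family not in FAMILIES:
        raise ValueError(f"unknown survival family: {family!r}")
    p = np.asarray(params, dtype=float)
    if p.shape != (FAMILIES[family].n_params,):
        raise ValueError(
            f"{family} expects {FAMILIES[family].n_params} parameters, got {p.shape}")
    if not np.all(np.isfinite(p)) or np.any(p <= 0 if family != "lognormal"
                                            else np.array([False, p[1] <= 0])):
        raise ValueError(f"{family} parameters out of support: {p}")
    return p


def neg_log_likelihood(family: str, params, times, events,
                       eps_time: float = EPS_TIME) -> float:
    """Censored negative log-likelihood −[Σ_event ln f(t) + Σ_cens ln S(t)].

    Event times at 0 are floored at ``eps_time`` so families with f(0)=0
    stay finite.  NaN anywhere is raised, never propagated.
    """
    p = _validate_params(family, params)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if np.any(t < 0):
        raise ValueError("negative times")
    dist = FAMILIES[family].dist(p)
    te = np.maximum(t[e], eps_time)
    ll = float(np.sum(dist.logpdf(te)) + np.sum(dist.logsf(t[~e])))
    if np.isnan(ll):
        raise FloatingPointError(
            f"NaN log-likelihood for {family} at params {p}")
    return -ll


def fit(family: str, times, events, eps_time: float = EPS_TIME) -> ParametricFit:
    """Maximum-likelihood fit of one family to right-censored data.

    Optimisation runs on log-transformed parameters (Nelder–Mead, then a
    BFGS polish) from Weibull-plot or method-of-moments start values; the
    ``converged`` flag reports the optimiser's verdict honestly.
    """
    fam = FAMILIES.get(family)
    if fam is None:
        raise ValueError(f"unknown survival family: {family!r}")
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(t) < 2:
        raise ValueError("need at least 2 records")
    if e.sum() < 1:
        raise ValueError("need at least 1 event to fit a parametric model")

    start = fam.start_values(t, e)
    # mu of the log-normal may be negative; optimise it untransformed
    free_log = np.ones(fam.n_params, dtype=bool)
    if family == "lognormal":
        free_log[0] = False

    def pack(p):
        x = np.array(p, dtype=float)
        x[free_log] = np.log(x[free_log])
        return x

    def unpack(x):
        p = np.array(x, dtype=float)
        p[free_log] = np.exp(p[free_log])
        return p

    def objective(x):
        try:
            return neg_log_likelihood(family, unpack(x), t, e, eps_time)
        except (ValueError, FloatingPointError, OverflowError):
            return 1e12

    x0 = pack(start)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10,
                                         "maxiter": 4000})
        polish = optimize.minimize(objective, res.x, method="BFGS",
                                   options={"gtol": 1e-8})
    best = polish if polish.fun <= res.fun else res
    converged = bool(best.success or res.success) and best.fun < 1e11
    params = tuple(float(v) for v in unpack(best.x))
    ll = -float(best.fun)
    aic = 2.0 * fam.n_params - 2.0 * ll
    return ParametricFit(family, params, ll, aic, len(t), converged,
                         fam.param_names)


def fit_all_and_select(times, events) -> tuple[list[ParametricFit], ParametricFit]:
    """Fit all five families and select the minimum-AIC fit.

    Non-convergent families are excluded with a warning; ties within
    ``AIC_TIE_TOL`` go to the fewer-parameter family, then fixed family
    order.  Raises only if every family fails.
    """
    fits: list[ParametricFit] = []
    for fam in FAMILY_ORDER:
        try:
            f = fit(fam, times, events)
        except Exception as exc:  # numerical failure of one family only
            log.warning("fit of %s failed: %s", fam, exc)
            continue
        if not f.converged:
            log.warning("fit of %s did not converge; excluded from selection", fam)
            continue
        fits.append(f)
    if not fits:
        raise RuntimeError("all five survival families failed to converge")
    order = {name: i for i, name in enumerate(FAMILY_ORDER)}
    best = min(fits, key=lambda f: (round_to_tie(f.aic, fits),
                                    FAMILIES[f.family].n_params,
                                    order[f.family]))
    return fits, best


def round_to_tie(aic: float, fits: Sequence[ParametricFit]) -> float:
    """Collapse AICs within the tie tolerance of the minimum onto it."""
    lo = min(f.aic for f in fits)
    return lo if aic - lo <= AIC_TIE_TOL else aic


def survival(fit_: ParametricFit, t) -> np.ndarray | float:
    """Evaluate S(t) of a fitted distribution; S(0)=1, non-increasing."""
    tt = np.asarray(t, dtype=float)
    if np.any(tt < 0):
        raise ValueError("negative time")
    out = FAMILIES[fit_.family].dist(np.asarray(fit_.params)).sf(tt)
    return float(out) if np.isscalar(t) or tt.ndim == 0 else out
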