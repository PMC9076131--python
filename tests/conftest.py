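import numpy as np
import pytest

from oncocea.survfit import FAMILIES, ParametricFit
from oncocea.synthetic_data import make_parameter_set


def make_fit(family: str, *params) -> ParametricFit:
    """Construct a ParametricFit with given parameters (no fitting)."""
    fam = FAMILIES[family]
    return ParametricFit(family, tuple(float(p) for p in params),
                         log_likelihood=0.0, aic=0.0, n_records=0,
                         converged=True, param_names=fam.param_names)


def brute_force_km(times, events, at):
    """Textbook product-limit estimate evaluated at `at`; kept independent of
    the packaged estimator so it can serve as an oracle."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    out = []
    uniq = np.unique(times[events == 1])
    for t in np.atleast_1d(at):
        s = 1.0
        for u in uniq[uniq <= t]:
            n_risk = np.sum(times >= u)
            d = np.sum((times == u) & (events == 1))
            s *= 1.0 - d / n_risk
        out.append(s)
    return np.array(out)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def parameter_table():
    return make_parameter_set()
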