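"""Censored maximum likelihood for the five survival families: hand-checked
likelihood values, closed-form MLEs, nesting identities, AIC bookkeeping,
parameter recovery against a grid-search oracle, and cross-validation
against lifelines."""

import numpy as np
import pytest
from scipy import stats

from oncocea.survfit import (FAMILIES, FAMILY_ORDER, ParametricFit, fit,
                             fit_all_and_select, neg_log_likelihood, survival)

from conftest import make_fit


def weibull_sample(rng, k, lam, n, cens_upper=None):
    t = lam * rng.weibull(k, n)
    if cens_upper is None:
        return t, np.ones(n, dtype=int)
    c = rng.uniform(0, cens_upper, n)
    return np.minimum(t, c), (t <= c).astype(int)


class TestNegLogLikelihood:
    def test_exponential_hand_value(self):
        # −lnL = −(5·ln 0.25 − 0.25·20) with Σt = 20, all events
        v = neg_log_likelihood("exponential", (0.25,), [1, 2, 3, 4, 10],
                               [1] * 5)
        assert v == pytest.approx(-(5 * np.log(0.25) - 0.25 * 20), abs=1e-12)

    def test_all_censored_near_zero_tends_to_zero(self):
        for fam, params in [("exponential", (0.5,)), ("weibull", (1.2, 10.0)),
                            ("lognormal", (2.0, 0.5)),
                            ("loglogistic", (2.0, 10.0)),
                            ("gamma", (2.0, 5.0))]:
            v = neg_log_likelihood(fam, params, [1e-9] * 4, [0] * 4)
            assert v == pytest.approx(0.0, abs=1e-6)

    def test_weibull_shape_one_equals_exponential(self, rng):
        t, e = weibull_sample(rng, 1.4, 9.0, 50, cens_upper=30.0)
        lam = 8.0
        vw = neg_log_likelihood("weibull", (1.0, lam), t, e)
        ve = neg_log_likelihood("exponential", (1.0 / lam,), t, e)
        assert abs(vw - ve) < 1e-10

    def test_unknown_family_and_bad_params(self):
        with pytest.raises(ValueError):
            neg_log_likelihood("cauchy", (1.0,), [1.0], [1])
        with pytest.raises(ValueError):
            neg_log_likelihood("weibull", (-1.0, 5.0), [1.0], [1])
        with pytest.raises(ValueError):
            neg_log_likelihood("weibull", (1.0, 5.0), [-1.0], [1])


class TestFit:
    def test_exponential_closed_form_mle(self):
        f = fit("exponential", [1, 2, 3, 4, 10], [1] * 5)
        assert f.params[0] == pytest.approx(5 / 20, rel=1e-5)
        assert f.converged

    def test_aic_identity_all_families(self, rng):
        t, e = weibull_sample(rng, 1.4, 11.0, 150, cens_upper=40.0)
        for fam in FAMILY_ORDER:
            f = fit(fam, t, e)
            k = FAMILIES[fam].n_params
            assert f.aic == pytest.approx(2 * k - 2 * f.log_likelihood,
                                          abs=1e-9)
            assert f.n_records == 150

    def test_weibull_recovery_vs_grid_oracle(self, rng):
        """MLE within 10% of truth at n=400 and at least as good (in
        likelihood) as an independent coarse grid search."""
        k_true, lam_true = 1.4, 11.0
        t, e = weibull_sample(rng, k_true, lam_true, 400, cens_upper=45.0)
        f = fit("weibull", t, e)
        k_hat, lam_hat = f.params
        assert k_hat == pytest.approx(k_true, rel=0.10)
        assert lam_hat == pytest.approx(lam_true, rel=0.10)
        # independent oracle: brute-force likelihood over a parameter grid
        ks = np.linspace(0.5, 3.0, 60)
        lams = np.linspace(5.0, 20.0, 60)
        best = min(
            (neg_log_likelihood("weibull", (kk, ll), t, e), kk, ll)
            for kk in ks for ll in lams)
        assert -f.log_likelihood <= best[0] + 1e-6
        assert k_hat == pytest.approx(best[1], abs=np.diff(ks)[0])
        assert lam_hat == pytest.approx(best[2], abs=np.diff(lams)[0])

    def test_matches_lifelines_weibull(self, rng):
        from lifelines import WeibullFitter
        t, e = weibull_sample(rng, 1.6, 12.0, 300, cens_upper=40.0)
        ours = fit("weibull", t, e)
        ll = WeibullFitter().fit(t, e)
        assert ours.params[0] == pytest.approx(ll.rho_, rel=1e-3)
        assert ours.params[1] == pytest.approx(ll.lambda_, rel=1e-3)
        assert ours.log_likelihood == pytest.approx(
            ll.log_likelihood_, rel=1e-6)

    def test_requires_events_and_records(self):
        with pytest.raises(ValueError):
            fit("weibull", [5.0], [1])
        with pytest.raises(ValueError):
            fit("weibull", [5.0, 6.0], [0, 0])


class TestSelection:
    def test_aic_value_from_loglik(self):
        f = ParametricFit("weibull", (1.0, 1.0), -100.0,
                          2 * 2 - 2 * (-100.0), 10, True)
        assert f.aic == 204.0

    def test_nested_weibull_close_to_exponential(self, rng):
        t = rng.exponential(8.0, 500)
        e = np.ones(500, dtype=int)
        fe = fit("exponential", t, e)
        fw = fit("weibull", t, e)
        assert fw.params[0] == pytest.approx(1.0, abs=0.15)
        assert abs(fw.aic - fe.aic) < 2.5

    def test_tie_break_prefers_fewer_parameters(self, monkeypatch):
        fits_by_family = {
            "exponential": ParametricFit("exponential", (0.1,), -50.0,
                                         2 - 2 * -50.0, 20, True),
            "weibull": ParametricFit("weibull", (1.0, 10.0), -49.0,
                                     4 - 2 * -49.0, 20, True),
        }
        # equal AIC = 102: the one-parameter family must win
        import oncocea.survfit as sf
        monkeypatch.setattr(sf, "fit",
                            lambda fam, t, ev: fits_by_family[fam])
        monkeypatch.setattr(sf, "FAMILY_ORDER", ("exponential", "weibull"))
        fits, best = sf.fit_all_and_select([1.0, 2.0], [1, 1])
        assert best.family == "exponential"

    def test_selection_consistency_weibull(self):
        """With strongly non-exponential Weibull data (k=1.6, n=1000) the
        AIC choice is Weibull in ≥90% of seeded replicates."""
        wins = 0
        n_rep = 20
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            t, e = weibull_sample(rng, 1.6, 12.0, 1000, cens_upper=40.0)
            _, best = fit_all_and_select(t, e)
            wins += best.family == "weibull"
        assert wins / n_rep >= 0.9


class TestSurvival:
    def test_s_zero_is_one(self):
        for fam, params in [("exponential", (0.2,)), ("weibull", (1.5, 8.0)),
                            ("lognormal", (2.0, 0.7)),
                            ("loglogistic", (1.8, 9.0)),
                            ("gamma", (2.0, 4.0))]:
            assert survival(make_fit(fam, *params), 0.0) == 1.0

    def test_weibull_closed_form_values(self):
        f = make_fit("weibull", 1.0, 10.0)
        assert survival(f, 10.0) == pytest.approx(np.exp(-1.0), abs=1e-12)
        f2 = make_fit("weibull", 2.0, 12.0)
        assert survival(f2, 6.0) == pytest.approx(np.exp(-0.25), abs=1e-12)

    def test_agrees_with_closed_forms_at_random_points(self, rng):
        ts = rng.uniform(0.01, 50.0, 20)
        cases = {
            "exponential": ((0.13,), lambda t: np.exp(-0.13 * t)),
            "weibull": ((1.7, 9.0), lambda t: np.exp(-((t / 9.0) ** 1.7))),
            "lognormal": ((2.1, 0.6),
                          lambda t: stats.norm.sf((np.log(t) - 2.1) / 0.6)),
            "loglogistic": ((2.2, 8.0),
                            lambda t: 1.0 / (1.0 + (t / 8.0) ** 2.2)),
            "gamma": ((2.5, 4.0), lambda t: stats.gamma.sf(t, 2.5, scale=4.0)),
        }
        for fam, (params, closed) in cases.items():
            got = survival(make_fit(fam, *params), ts)
            np.testing.assert_allclose(got, closed(ts), atol=1e-12)

    def test_monotone_non_increasing(self, rng):
        ts = np.sort(rng.uniform(0, 60, 50))
        for fam, params in [("weibull", (0.8, 14.0)), ("gamma", (1.3, 7.0))]:
            s = survival(make_fit(fam, *params), ts)
            assert np.all(np.diff(s) <= 1e-15)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            survival(make_fit("weibull", 1.0, 10.0), -0.5)


def test_parameter_recovery_bias_shrinks_with_n():
    """Median relative error of (k, λ) decreases from n=100 to n=1600."""
    k_true, lam_true = 1.4, 11.0

    def med_err(n, seeds=8):
        errs = []
        for seed in range(seeds):
            rng = np.random.default_rng(1000 + seed)
            t, e = weibull_sample(rng, k_true, lam_true, n, cens_upper=45.0)
            f = fit("weibull", t, e)
            errs.append(max(abs(f.params[0] / k_true - 1),
                            abs(f.params[1] / lam_true - 1)))
        return float(np.median(errs))

    assert med_err(1600) < med_err(100)


def test_json_round_trip(rng):
    t, e = weibull_sample(rng, 1.3, 10.0, 80, cens_upper=30.0)
    f = fit("weibull", t, e)
    back = ParametricFit.from_json_dict(f.to_json_dict())
    assert back == f
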