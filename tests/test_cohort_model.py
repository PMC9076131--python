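"""Partitioned-survival engine: occupancy identities, restricted-mean
oracle, dose arithmetic, accrual linearity and discounting properties."""

import dataclasses

import numpy as np
import pytest

from oncocea.cohort_model import (DrugDose, ModelSettings, PatientProfile,
                                  StrategySpec, accrue, build_trace,
                                  drug_cost_per_cycle)

from conftest import make_fit


def simple_strategy(**overrides):
    base = dict(
        name="test",
        drugs=(DrugDose("drugA", "flat", 100.0, 10.0, 10.0),),
        u_pfs=0.8, u_pd=0.6,
        management_cost_pfs=500.0, management_cost_pd=400.0,
        sae_expected_cost=1000.0,
        second_line_cost_per_cycle=2000.0, second_line_duration_cycles=4,
        bsc_cost_per_cycle=665.33, end_of_life_cost=2491.08,
    )
    base.update(overrides)
    return StrategySpec(**base)


@pytest.fixture
def settings():
    return ModelSettings(horizon_years=20.0)


@pytest.fixture
def fits():
    return (make_fit("weibull", 1.3, 8.0),   # PFS
            make_fit("weibull", 1.2, 16.0))  # OS


class TestBuildTrace:
    def test_identical_curves_mean_nobody_progresses(self, settings):
        f = make_fit("weibull", 1.3, 10.0)
        trace = build_trace(f, f, settings)
        assert np.all(trace.pd == 0.0)

    def test_occupancy_partition_every_cycle(self, fits, settings):
        trace = build_trace(*fits, settings)
        np.testing.assert_allclose(trace.pfs + trace.pd + trace.dead, 1.0,
                                   atol=1e-12)
        assert np.all(np.diff(trace.dead) >= -1e-12)
        assert np.all(trace.newly_dead >= -1e-12)

    def test_pfs_clamped_below_os(self, settings):
        # PFS curve above OS: the clamp must force pfs <= alive
        pfs_fit = make_fit("weibull", 1.0, 30.0)
        os_fit = make_fit("weibull", 1.0, 10.0)
        trace = build_trace(pfs_fit, os_fit, settings)
        assert np.all(trace.pd >= 0.0)
        np.testing.assert_allclose(trace.pfs, 1.0 - trace.dead, atol=1e-12)

    def test_restricted_mean_survival_oracle(self):
        """Cycle-sum of S_OS approximates the closed-form RMST of an
        exponential within one cycle's width."""
        mu = 0.05  # per month
        settings = ModelSettings(horizon_years=20.0)
        lam = 1.0 / mu
        os_fit = make_fit("weibull", 1.0, lam)
        trace = build_trace(os_fit, os_fit, settings)
        cycle_years = settings.cycle_years
        approx_years = np.sum(1.0 - trace.dead) * cycle_years
        horizon_months = trace.times_months[-1]
        exact_years = (1.0 - np.exp(-mu * horizon_months)) / mu / 12.0
        assert abs(approx_years - exact_years) <= cycle_years


class TestDrugCost:
    profile = PatientProfile()

    def test_flat_dose_atezolizumab_price(self):
        s = simple_strategy(drugs=(
            DrugDose("atezolizumab", "flat", 1200.0, 78.28, 10.0),))
        assert drug_cost_per_cycle(s, self.profile) == pytest.approx(9393.60)

    def test_flat_dose_pembrolizumab_price(self):
        s = simple_strategy(drugs=(
            DrugDose("pembrolizumab", "flat", 200.0, 50.84, 1.0),))
        assert drug_cost_per_cycle(s, self.profile) == pytest.approx(10168.00)

    def test_per_m2_dose_rounds_up_units(self):
        # 500 mg/m2 × 1.82 m2 = 910 mg -> 91 ten-mg units
        s = simple_strategy(drugs=(
            DrugDose("pemetrexed", "per_m2", 500.0, 71.95, 10.0),))
        assert drug_cost_per_cycle(s, self.profile) == pytest.approx(6547.45)

    def test_auc_dose_uses_calvert_formula(self):
        # AUC 6 × (70 + 25) = 570 mg -> 12 fifty-mg units
        s = simple_strategy(drugs=(
            DrugDose("carboplatin", "auc", 6.0, 2.76, 50.0),))
        assert drug_cost_per_cycle(s, self.profile) == pytest.approx(12 * 2.76)

    def test_per_kg_dose(self):
        # 3 mg/kg × 70 kg = 210 one-mg units
        s = simple_strategy(drugs=(
            DrugDose("nivolumab", "per_kg", 3.0, 28.56, 1.0),))
        assert drug_cost_per_cycle(s, self.profile) == pytest.approx(210 * 28.56)

    def test_whole_unit_no_spurious_rounding(self):
        # exactly 120 units must not become 121
        s = simple_strategy(drugs=(DrugDose("x", "flat", 1200.0, 1.0, 10.0),))
        assert drug_cost_per_cycle(s, self.profile) == 120.0

    def test_invalid_rule_rejected(self):
        with pytest.raises(ValueError):
            DrugDose("x", "per_mole", 1.0, 1.0, 1.0)


class TestAccrue:
    def test_full_health_year_without_death(self):
        """rate=0, utilities 1, nobody dies in year one -> 1.0 QALY/yr."""
        os_fit = make_fit("weibull", 1.0, 1e9)  # essentially immortal
        settings = ModelSettings(discount_rate=0.0, horizon_years=1.0)
        trace = build_trace(os_fit, os_fit, settings)
        s = simple_strategy(u_pfs=1.0, u_pd=1.0)
        out = accrue(trace, s, settings)
        expected_years = trace.n_cycles * settings.cycle_years
        assert out.total_qalys == pytest.approx(expected_years, rel=1e-6)
        assert expected_years == pytest.approx(1.0, abs=settings.cycle_years)

    def test_discount_factor_is_one_at_entry(self, fits, settings):
        trace = build_trace(*fits, settings)
        s = simple_strategy()
        zero = dataclasses.replace(settings, discount_rate=0.0)
        # cycle-0 accrual identical discounted vs not: factor at k=0 is 1
        only_sae = simple_strategy(
            drugs=(), management_cost_pfs=0.0, management_cost_pd=0.0,
            second_line_cost_per_cycle=0.0, bsc_cost_per_cycle=0.0,
            end_of_life_cost=0.0, sae_expected_cost=777.0)
        a = accrue(trace, only_sae, settings)
        b = accrue(trace, only_sae, zero)
        assert a.total_cost == pytest.approx(777.0)
        assert b.total_cost == pytest.approx(777.0)

    def test_cost_linearity(self, fits, settings):
        trace = build_trace(*fits, settings)
        s = simple_strategy()
        doubled = simple_strategy(
            drugs=(DrugDose("drugA", "flat", 100.0, 20.0, 10.0),),
            management_cost_pfs=1000.0, management_cost_pd=800.0,
            sae_expected_cost=2000.0, second_line_cost_per_cycle=4000.0,
            bsc_cost_per_cycle=2 * 665.33, end_of_life_cost=2 * 2491.08)
        a = accrue(trace, s, settings)
        b = accrue(trace, doubled, settings)
        assert b.total_cost == pytest.approx(2 * a.total_cost, rel=1e-12)
        assert b.total_qalys == pytest.approx(a.total_qalys, rel=1e-12)

    @pytest.mark.parametrize("rates", [(0.0, 0.03), (0.03, 0.08)])
    def test_totals_non_increasing_in_discount_rate(self, fits, rates):
        lo, hi = rates
        trace = build_trace(*fits, ModelSettings(horizon_years=20.0))
        s = simple_strategy()
        a = accrue(trace, s, ModelSettings(discount_rate=lo))
        b = accrue(trace, s, ModelSettings(discount_rate=hi))
        assert b.total_cost <= a.total_cost
        assert b.total_qalys <= a.total_qalys

    def test_longer_horizon_never_decreases_totals(self, fits):
        s = simple_strategy()
        outs = []
        for horizon in (5.0, 10.0, 20.0):
            st = ModelSettings(horizon_years=horizon)
            outs.append(accrue(build_trace(*fits, st), s, st))
        costs = [o.total_cost for o in outs]
        qalys = [o.total_qalys for o in outs]
        assert costs == sorted(costs)
        assert qalys == sorted(qalys)

    def test_end_of_life_cost_limit(self, fits):
        """With only an end-of-life cost, the undiscounted total tends to
        that one-time cost as everyone eventually dies."""
        s = simple_strategy(drugs=(), management_cost_pfs=0.0,
                            management_cost_pd=0.0, sae_expected_cost=0.0,
                            second_line_cost_per_cycle=0.0,
                            bsc_cost_per_cycle=0.0,
                            end_of_life_cost=2491.08)
        st = ModelSettings(discount_rate=0.0, horizon_years=60.0)
        out = accrue(build_trace(*fits, st), s, st)
        assert out.undiscounted_total_cost == pytest.approx(2491.08, rel=1e-4)

    def test_drug_cap_limits_first_line_cost(self, fits, settings):
        trace = build_trace(*fits, settings)
        uncapped = accrue(trace, simple_strategy(), settings)
        capped = accrue(trace, simple_strategy(chemo_cycle_cap=4), settings)
        assert capped.total_cost < uncapped.total_cost
        assert capped.cost_breakdown["first_line_drug"] < \
            uncapped.cost_breakdown["first_line_drug"]
        assert capped.total_qalys == uncapped.total_qalys

    def test_undiscounted_yearly_costs_sum_to_total(self, fits, settings):
        trace = build_trace(*fits, settings)
        out = accrue(trace, simple_strategy(), settings)
        assert out.undiscounted_cost_by_year.sum() == pytest.approx(
            out.undiscounted_total_cost, rel=1e-12)

    def test_half_cycle_correction_changes_totals_modestly(self, fits,
                                                           settings):
        trace = build_trace(*fits, settings)
        s = simple_strategy()
        plain = accrue(trace, s, settings)
        hcc = accrue(trace, s,
                     dataclasses.replace(settings, half_cycle_correction=True))
        assert hcc.total_qalys != plain.total_qalys
        assert abs(hcc.total_qalys / plain.total_qalys - 1) < 0.05


class TestValidation:
    def test_negative_utility_rejected(self):
        with pytest.raises(ValueError):
            simple_strategy(u_pfs=-0.1)

    def test_utility_above_one_rejected(self):
        with pytest.raises(ValueError):
            simple_strategy(u_pd=1.2)

    def test_negative_cost_rejected(self):
        with pytest.raises(ValueError):
            simple_strategy(bsc_cost_per_cycle=-5.0)

    def test_discount_rate_range_enforced(self):
        with pytest.raises(ValueError):
            ModelSettings(discount_rate=0.10)

    def test_profile_positive(self):
        with pytest.raises(ValueError):
            PatientProfile(bsa=-1.0)
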