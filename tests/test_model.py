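"""Cohort model oracles: hazard conversion, traces, HLY, DALY/month."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surgdelay import (ConfigurationError, DelayScenario, daly_per_month,
                       effective_post_params, healthy_life_years,
                       per_cycle_death_probability, run_cohort)
from surgdelay.model import (DELAY_GRID_WEEKS, MONTHS_PER_WEEK, _hly_closed,
                             horizon_cycles)
from conftest import make_params


class TestHazardConversion:
    def test_no_mortality(self):
        assert per_cycle_death_probability(1.0) == 0.0

    def test_one_year_cycle_identity(self):
        assert per_cycle_death_probability(0.9, 52) == pytest.approx(0.1)

    def test_weekly_closed_form(self):
        assert per_cycle_death_probability(0.9, 1) == pytest.approx(
            1 - 0.9 ** (1 / 52), abs=1e-15)

    def test_zero_survival_rejected(self):
        with pytest.raises(ConfigurationError):
            per_cycle_death_probability(0.0)


class TestEffectivePostParams:
    def test_benefit_intact_below_both_windows(self):
        p = make_params()
        assert effective_post_params(p, DelayScenario(2)) == (0.97, 0.9)

    def test_benefit_lost_at_both_windows(self):
        p = make_params(t_no_surv_benefit=30, t_no_hrqol_benefit=30)
        assert effective_post_params(p, DelayScenario(52)) == (0.9, 0.5)

    def test_mixed_case_hrqol_window_only(self):
        p = make_params(t_no_surv_benefit=200, t_no_hrqol_benefit=30)
        assert effective_post_params(p, DelayScenario(42)) == (0.97, 0.5)

    def test_cancellation_exceeds_both_windows(self):
        p = make_params()
        assert effective_post_params(p, DelayScenario.cancellation()) == (0.9, 0.5)


class TestCohortTrace:
    def test_immortal_cohort(self):
        p = make_params(surv_pre=1.0, surv_post=1.0)
        trace = run_cohort(p, DelayScenario(2))
        assert trace.deceased.max() == 0.0
        assert (trace.post[2:] == 1.0).all()
        assert (trace.pre[:2] == 1.0).all()

    def test_cancelled_geometric_closed_form(self):
        p = make_params(surv_pre=0.9)
        trace = run_cohort(p, DelayScenario.cancellation())
        q = 0.9 ** (1 / 52)
        t = np.arange(len(trace.pre))
        np.testing.assert_allclose(trace.pre, q ** t, atol=1e-12)
        assert trace.post.max() == 0.0

    @pytest.mark.parametrize("delay", [DelayScenario(2), DelayScenario(32),
                                       DelayScenario.cancellation()])
    def test_conservation_and_absorbing_death(self, delay):
        p = make_params(surv_pre=0.8, surv_post=0.92)
        trace = run_cohort(p, delay)
        total = trace.pre + trace.post + trace.deceased
        np.testing.assert_allclose(total, 1.0, atol=1e-12)
        assert (np.diff(trace.deceased) >= -1e-15).all()
        for occ in (trace.pre, trace.post, trace.deceased):
            assert ((occ >= 0) & (occ <= 1)).all()

    def test_horizon_runs_to_age_100(self):
        p = make_params(mean_age=98.0)
        trace = run_cohort(p, DelayScenario(2))
        assert len(trace.pre) == horizon_cycles(98.0) == 104

    def test_age_at_horizon_rejected(self):
        with pytest.raises(ConfigurationError):
            make_params(mean_age=100.0)


class TestHealthyLifeYears:
    def test_perfect_health_bound(self):
        p = make_params(surv_pre=1.0, surv_post=1.0, hrqol_pre=1.0,
                        hrqol_post=1.0, mean_age=90.0)
        trace = run_cohort(p, DelayScenario(2))
        hly = healthy_life_years(trace, p, DelayScenario(2))
        assert hly == pytest.approx(10.0, abs=1e-9)

    def test_all_deceased_contributes_zero(self):
        p = make_params()
        trace = run_cohort(p, DelayScenario(2))
        dead = type(trace)(pre=np.zeros_like(trace.pre),
                           post=np.zeros_like(trace.post),
                           deceased=np.ones_like(trace.deceased))
        assert healthy_life_years(dead, p, DelayScenario(2)) == 0.0

    def test_immortal_piecewise_closed_form(self):
        p = make_params(surv_pre=1.0, surv_post=1.0, mean_age=80.0)
        for d in (2, 22, 52):
            scenario = DelayScenario(d)
            trace = run_cohort(p, scenario)
            hly = healthy_life_years(trace, p, scenario)
            horizon_years = horizon_cycles(80.0) / 52
            expected = 0.5 * d / 52 + 0.9 * (horizon_years - d / 52)
            assert hly == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_trace_sum_matches_geometric_closed_form(self, seed):
        rng = np.random.default_rng(seed)
        p = make_params(surv_pre=rng.uniform(0.5, 0.99),
                        surv_post=rng.uniform(0.5, 0.99),
                        hrqol_pre=0.4, hrqol_post=0.8,
                        mean_age=rng.uniform(30, 95),
                        t_no_surv_benefit=rng.uniform(0, 100),
                        t_no_hrqol_benefit=rng.uniform(0, 100))
        for scenario in (DelayScenario(12), DelayScenario.cancellation()):
            trace = run_cohort(p, scenario)
            via_trace = healthy_life_years(trace, p, scenario)
            via_sum = _hly_closed(p, scenario, 0.4, 0.8)
            assert via_trace == pytest.approx(via_sum, abs=1e-10)


class TestDalyPerMonth:
    def test_harmless_delay_gives_zero(self):
        p = make_params(surv_pre=0.9, surv_post=0.9, hrqol_pre=0.7,
                        hrqol_post=0.7)
        assert daly_per_month(p).daly_per_month == 0.0

    def test_immortal_cohort_slope_is_utility_gap_per_month(self):
        p = make_params(surv_pre=1.0, surv_post=1.0)
        out = daly_per_month(p)
        assert out.daly_per_month == pytest.approx(0.4 / 12, abs=1e-12)

    def test_unit_coherence_months_vs_weeks(self):
        """Fitting loss against weeks changes the slope by exactly 12/52."""
        p = make_params(surv_pre=0.85, surv_post=0.95)
        out = daly_per_month(p)
        weeks = np.array(sorted(out.loss_by_delay))
        losses = np.array([out.loss_by_delay[w] for w in weeks])
        slope_weeks = np.polyfit(weeks, losses, 1)[0]
        assert out.daly_per_month == pytest.approx(
            slope_weeks / MONTHS_PER_WEEK, rel=1e-9)

    @settings(max_examples=60, deadline=None)
    @given(surv_pre=st.floats(0.3, 0.99), surv_gain=st.floats(0.0, 0.2),
           u_pre=st.floats(0.05, 0.7), u_gain=st.floats(0.0, 0.3),
           age=st.floats(25, 95), w_surv=st.floats(0, 250),
           w_hrqol=st.floats(0, 250))
    def test_loss_monotone_and_slope_nonnegative(self, surv_pre, surv_gain,
                                                 u_pre, u_gain, age, w_surv,
                                                 w_hrqol):
        p = make_params(surv_pre=surv_pre,
                        surv_post=min(surv_pre + surv_gain, 1.0),
                        hrqol_pre=u_pre, hrqol_post=min(u_pre + u_gain, 1.0),
                        mean_age=age, t_no_surv_benefit=w_surv,
                        t_no_hrqol_benefit=w_hrqol)
        out = daly_per_month(p)
        losses = [out.loss_by_delay[d] for d in sorted(out.loss_by_delay)]
        assert all(b - a >= -1e-12 for a, b in zip(losses, losses[1:]))
        assert out.daly_per_month >= -1e-12
        assert out.cancellation_daly >= losses[-1] - 1e-12

    def test_dominance_in_post_utility(self):
        low = daly_per_month(make_params(hrqol_post=0.7)).daly_per_month
        high = daly_per_month(make_params(hrqol_post=0.95)).daly_per_month
        assert high > low

    def test_cancellation_excluded_from_slope(self):
        p = make_params()
        out = daly_per_month(p, include_cancellation=False)
        assert out.cancellation_daly is None
        assert set(out.loss_by_delay) == set(DELAY_GRID_WEEKS)
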