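"""Weibull curves, calibration, transition probabilities, DP mortality."""

import math
from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from markovcea.cohort import build_trace, summarize_occupancy
from markovcea.params import ModelStructure
from markovcea.survival import (
    CalibrationError,
    TransitionSchedule,
    WeibullParams,
    apply_hazard_ratio,
    calibrate_dp_mortality,
    cycle_transition_prob,
    fit_weibull_to_km,
    schedule_from_weibull,
    transition_probs,
    weibull_from_median,
    weibull_survival,
)

LN2 = math.log(2.0)
STRUCTURE = ModelStructure()
CYCLE_MONTHS = STRUCTURE.cycle_length_months

positive = st.floats(min_value=0.2, max_value=50.0, allow_nan=False)
shapes = st.floats(min_value=0.3, max_value=4.0, allow_nan=False)


class TestWeibullSurvival:
    @pytest.mark.parametrize(
        "shape,scale,t,expected",
        [
            (1.0, 10.0, 0.0, 1.0),
            (1.0, 13.1 / LN2, 13.1, 0.5),
            (2.0, 5.0, 5.0, math.exp(-1.0)),
        ],
    )
    def test_closed_form_points(self, shape, scale, t, expected):
        assert weibull_survival(WeibullParams(shape, scale), t) == pytest.approx(
            expected, abs=1e-3)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            weibull_survival(WeibullParams(1.0, 10.0), -0.1)

    @given(shape=shapes, scale=positive)
    def test_non_increasing_in_unit_interval(self, shape, scale):
        grid = np.linspace(0.0, 5 * scale, 200)
        s = weibull_survival(WeibullParams(shape, scale), grid)
        assert s[0] == 1.0
        assert np.all((s >= 0) & (s <= 1))
        assert np.all(np.diff(s) <= 1e-15)


class TestMedianCalibration:
    @pytest.mark.parametrize(
        "median,expected_scale", [(13.1, 13.1 / LN2), (4.6, 4.6 / LN2)])
    def test_exponential_scale(self, median, expected_scale):
        wp = weibull_from_median(median, shape=1.0)
        assert wp.scale == pytest.approx(expected_scale, rel=1e-12)

    @given(median=positive, shape=shapes)
    def test_survival_at_median_is_half(self, median, shape):
        wp = weibull_from_median(median, shape)
        assert weibull_survival(wp, median) == pytest.approx(0.5, abs=1e-12)
        assert wp.median() == pytest.approx(median, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            weibull_from_median(-1.0)
        with pytest.raises(ValueError):
            weibull_from_median(5.0, shape=0.0)


class TestHazardRatio:
    def test_identity(self):
        wp = WeibullParams(1.3, 7.0)
        assert apply_hazard_ratio(wp, 1.0) == wp

    def test_exponential_scale_division(self):
        wp = apply_hazard_ratio(WeibullParams(1.0, 4.6 / LN2), 0.16)
        assert wp.scale == pytest.approx(4.6 / LN2 / 0.16, rel=1e-12)

    @given(shape=shapes, scale=positive,
           hr=st.floats(min_value=0.05, max_value=5.0))
    def test_inverse_composition(self, shape, scale, hr):
        wp = WeibullParams(shape, scale)
        back = apply_hazard_ratio(apply_hazard_ratio(wp, hr), 1.0 / hr)
        assert back.scale == pytest.approx(scale, abs=1e-9, rel=1e-9)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            apply_hazard_ratio(WeibullParams(1.0, 1.0), 0.0)


class TestKMFit:
    def test_noiseless_self_consistency(self):
        truth = WeibullParams(1.5, 10.0)
        t = np.arange(2.0, 21.0, 2.0)
        km = SimpleNamespace(times=t, survival=weibull_survival(truth, t))
        fitted = fit_weibull_to_km(km)
        assert fitted.shape == pytest.approx(1.5, abs=1e-6)
        assert fitted.scale == pytest.approx(10.0, abs=1e-6)

    def test_degenerate_curve_rejected(self):
        km = SimpleNamespace(times=np.array([1.0, 2.0]),
                             survival=np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            fit_weibull_to_km(km)


class TestCycleTransitionProb:
    def test_exponential_closed_form(self):
        wp = weibull_from_median(4.6)
        expected = 1.0 - math.exp(-(LN2 / 4.6) * CYCLE_MONTHS)
        for k in (1, 5, 50):
            assert cycle_transition_prob(wp, k, CYCLE_MONTHS) == pytest.approx(
                expected, abs=1e-12)
        assert expected == pytest.approx(0.0988, abs=1e-3)

    def test_increasing_hazard_when_shape_above_one(self):
        wp = WeibullParams(2.0, 10.0)
        assert cycle_transition_prob(wp, 10, 1.0) > cycle_transition_prob(wp, 1, 1.0)

    def test_absorbing_tail_returns_one(self):
        wp = WeibullParams(4.0, 0.5)  # survival underflows quickly
        assert cycle_transition_prob(wp, 10_000, 10.0) == 1.0

    @given(shape=shapes, scale=positive)
    def test_product_reproduces_survival(self, shape, scale):
        """Prod over cycles of (1 - p_k) telescopes back to S(k u)."""
        wp = WeibullParams(shape, scale)
        probs = transition_probs(wp, 40, CYCLE_MONTHS)
        prod = np.cumprod(1.0 - probs)
        s = weibull_survival(wp, np.arange(1, 41) * CYCLE_MONTHS)
        np.testing.assert_allclose(prod, s, atol=1e-12)


class TestDPMortalityCalibration:
    @staticmethod
    def _schedule():
        return schedule_from_weibull(weibull_from_median(4.6), STRUCTURE)

    @staticmethod
    def _dp_ly(p):
        sched = TestDPMortalityCalibration._schedule().with_dp_death(p)
        trace = build_trace(sched, STRUCTURE)
        return summarize_occupancy(trace, STRUCTURE).ly_dp

    def test_round_trip_recovers_known_probability(self):
        target = self._dp_ly(0.05)
        p = calibrate_dp_mortality(target, self._schedule(), STRUCTURE)
        assert p == pytest.approx(0.05, abs=1e-6)
        assert self._dp_ly(p) == pytest.approx(target, abs=1e-6)

    def test_monotone_in_p(self):
        ly = [self._dp_ly(p) for p in (0.01, 0.05, 0.2, 1.0)]
        assert all(a > b for a, b in zip(ly, ly[1:]))

    def test_p_one_counts_each_entrant_once(self):
        """At p=1 everyone dies after one DP cycle, so the discounted DP
        person-time equals the discounted sum of per-cycle entrants."""
        sched = self._schedule()
        trace = build_trace(sched.with_dp_death(1.0), STRUCTURE)
        inflow = trace.pfs[:-1] * sched.p_pfs_exit[: STRUCTURE.n_cycles]
        oracle = float(
            np.sum(inflow * trace.discount[1:]) * STRUCTURE.cycle_length_years)
        assert summarize_occupancy(trace, STRUCTURE).ly_dp == pytest.approx(
            oracle, abs=1e-12)

    def test_unreachable_target_reports_maximum(self):
        with pytest.raises(CalibrationError, match="maximum achievable"):
            calibrate_dp_mortality(50.0, self._schedule(), STRUCTURE)
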