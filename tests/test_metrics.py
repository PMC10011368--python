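"""Detection scoring, exact binomial intervals, glycemic outcome metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import interpolate, stats
from scipy.integrate import quad

from rap import metrics as mx
from rap.errors import UndefinedMetricError, ValidationError
from rap.policy import DetectionEvent
from rap.simulator import CgmTrace, MealEvent


def meal(t, grams=50.0, announced=False):
    return MealEvent(time=t, grams=grams, announced=announced)


def event(t):
    return DetectionEvent(alert_time=t, p_meal=0.9, carb_class=2,
                          estimated_grams=50.0, presumed_meal_time=t - 25.0)


def trace(values, start=0.0):
    return CgmTrace(start_time=start, values=np.asarray(values, dtype=float))


class TestMatching:
    def test_single_pair_matches_with_delay(self):
        res = mx.match_detections([meal(0.0)], [event(26.0)])
        assert len(res.true_positives) == 1
        assert res.true_positives[0][2] == 26.0
        assert res.missed_meals == [] and res.false_events == []

    def test_event_outside_window_is_false_and_meal_missed(self):
        res = mx.match_detections([meal(0.0)], [event(130.0)], window=120.0)
        assert len(res.missed_meals) == 1 and len(res.false_events) == 1

    def test_event_without_meal_is_false(self):
        res = mx.match_detections([], [event(50.0)])
        assert len(res.false_events) == 1

    def test_announced_and_rescue_meals_are_not_targets(self):
        meals = [meal(0.0, announced=True),
                 MealEvent(time=10.0, grams=15.0, announced=False, is_rescue=True)]
        res = mx.match_detections(meals, [event(30.0)])
        assert res.n_meals == 0 and len(res.false_events) == 1

    def test_most_recent_meal_wins(self):
        res = mx.match_detections([meal(0.0), meal(60.0)], [event(80.0)])
        assert res.true_positives[0][0].time == 60.0

    @given(st.lists(st.floats(min_value=0, max_value=5000), max_size=12),
           st.lists(st.floats(min_value=0, max_value=5000), max_size=12))
    @settings(deadline=None)
    def test_matching_conservation_laws(self, meal_times, event_times):
        meals = [meal(t) for t in sorted(set(meal_times))]
        events = [event(t) for t in sorted(set(event_times))]
        res = mx.match_detections(meals, events)
        assert len(res.true_positives) + len(res.missed_meals) == len(meals)
        assert len(res.true_positives) + len(res.false_events) == len(events)
        for _, _, delay in res.true_positives:
            assert 0 <= delay <= res.matching_window


class TestRates:
    @staticmethod
    def result(tp, missed, false):
        return mx.MatchResult(
            true_positives=[(meal(i * 300.0), event(i * 300.0 + 26), 26.0)
                            for i in range(tp)],
            missed_meals=[meal(1e5 + i) for i in range(missed)],
            false_events=[event(2e5 + i * 300) for i in range(false)])

    def test_headline_sensitivity(self):
        assert mx.sensitivity(self.result(20, 4, 4)) == pytest.approx(83.3, abs=0.05)

    def test_headline_false_discovery_rate(self):
        # 4 false of 24 alerts; the study reports this rounded down to 16.6%
        assert mx.false_discovery_rate(self.result(20, 4, 4)) == pytest.approx(16.6, abs=0.1)

    def test_detection_time_mean_sd(self):
        res = mx.MatchResult(true_positives=[
            (meal(0.0), event(20.0), 20.0), (meal(500.0), event(530.0), 30.0)])
        mean, sd = mx.mean_detection_time(res)
        assert mean == 25.0 and sd == 5.0

    def test_empty_denominators_raise(self):
        with pytest.raises(UndefinedMetricError):
            mx.sensitivity(mx.MatchResult())
        with pytest.raises(UndefinedMetricError):
            mx.false_discovery_rate(mx.MatchResult())
        assert mx.sensitivity(self.result(0, 5, 0)) == 0.0

    def test_grams_restriction(self):
        res = mx.MatchResult(
            true_positives=[(meal(0.0, grams=50), event(26.0), 26.0),
                            (meal(400.0, grams=95), event(430.0), 30.0)],
            missed_meals=[meal(900.0, grams=45), meal(1500.0, grams=20)],
            false_events=[event(3000.0)])
        sub = res.restricted(40.0, 80.0)
        assert sub.n_meals == 2
        assert len(sub.true_positives) == 1
        assert len(sub.false_events) == 1


class TestClopperPearson:
    def test_reported_sensitivity_interval(self):
        # exact bounds 62.616 / 95.265; reported figures truncate the upper one
        lo, hi = mx.clopper_pearson(20, 24)
        assert lo == pytest.approx(62.6, abs=0.1)
        assert hi == pytest.approx(95.2, abs=0.1)

    def test_reported_fdr_interval(self):
        lo, hi = mx.clopper_pearson(4, 24)
        assert lo == pytest.approx(4.7, abs=0.1)
        assert hi == pytest.approx(37.4, abs=0.1)

    def test_degenerate_bounds(self):
        assert mx.clopper_pearson(0, 10)[0] == 0.0
        assert mx.clopper_pearson(10, 10)[1] == 100.0

    def test_invalid_counts(self):
        for s, n in ((-1, 5), (6, 5), (0, 0)):
            with pytest.raises(ValidationError):
                mx.clopper_pearson(s, n)

    def test_matches_tail_inversion_oracle_up_to_n30(self):
        # independent oracle: bisect the binomial tail probabilities directly
        def oracle(s, n, alpha=0.05):
            def lower():
                if s == 0:
                    return 0.0
                f = lambda p: stats.binom.sf(s - 1, n, p) - alpha / 2
                return _bisect(f, 0.0, 1.0)
            def upper():
                if s == n:
                    return 1.0
                f = lambda p: alpha / 2 - stats.binom.cdf(s, n, p)
                return _bisect(f, 0.0, 1.0)
            return 100.0 * lower(), 100.0 * upper()

        def _bisect(f, lo, hi, tol=1e-10):
            for _ in range(60):
                mid = (lo + hi) / 2
                if f(mid) > 0:
                    hi = mid
                else:
                    lo = mid
            return (lo + hi) / 2

        for n in range(1, 31):
            for s in range(0, n + 1):
                got = mx.clopper_pearson(s, n)
                want = oracle(s, n)
                assert got[0] == pytest.approx(want[0], abs=1e-4)
                assert got[1] == pytest.approx(want[1], abs=1e-4)


class TestIauc:
    def test_constant_trace_zero(self):
        assert mx.iauc(trace([100.0] * 49), 0.0) == 0.0

    def test_triangular_excursion(self):
        # baseline 100, linear to 160 mg/dL at 60 min, back at 120 min, flat after:
        # a triangle of base 2 h and height 60 -> 60 mg.h/dL
        up = np.linspace(100, 160, 13)
        down = np.linspace(160, 100, 13)[1:]
        flat = np.full(24, 100.0)
        t = trace(np.concatenate([up, down, flat]))
        assert mx.iauc(t, 0.0, horizon=240.0) == pytest.approx(60.0, abs=1e-9)

    def test_below_baseline_contributes_nothing(self):
        values = np.concatenate([[120.0], np.full(48, 90.0)])
        assert mx.iauc(trace(values), 0.0) == 0.0

    def test_insufficient_coverage_rejected(self):
        with pytest.raises(ValidationError):
            mx.iauc(trace([100.0] * 10), 0.0, horizon=240.0)

    def test_matches_analytic_integral_on_piecewise_linear_traces(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            values = 100.0 + np.abs(rng.normal(0, 40, 49))
            values[0] = 100.0
            t = trace(values)
            grid = t.times
            f = interpolate.interp1d(grid, np.maximum(values - values[0], 0.0))
            oracle = quad(f, 0.0, 240.0, limit=400,
                          points=grid, epsabs=1e-10)[0] / 60.0
            assert mx.iauc(t, 0.0) == pytest.approx(oracle, abs=1e-7)


class TestRangesAndRisk:
    def test_all_in_range(self):
        assert mx.time_in_ranges(trace([100.0] * 24)) == (100.0, 0.0, 0.0, 0.0)

    def test_half_above_range(self):
        values = [200.0] * 12 + [100.0] * 12
        assert mx.time_in_ranges(trace(values)) == (50.0, 50.0, 0.0, 0.0)

    def test_boundaries_count_in_range(self):
        tir, tar, tbr70, _ = mx.time_in_ranges(trace([70.0, 180.0]))
        assert tir == 100.0 and tar == 0.0 and tbr70 == 0.0

    @given(st.lists(st.floats(min_value=40, max_value=400), min_size=1, max_size=60))
    @settings(deadline=None)
    def test_band_percentages_conserve(self, values):
        tir, tar, tbr70, tbr54 = mx.time_in_ranges(trace(values))
        assert tir + tar + tbr70 == pytest.approx(100.0)
        assert tbr54 <= tbr70

    def test_lbgi_zero_above_risk_root(self):
        # f(g) = 1.509((ln g)^1.084 - 5.381) crosses zero at ~112.7 mg/dL
        assert mx.lbgi(trace([113.0, 150.0, 300.0])) == 0.0

    def test_lbgi_monotone_below_root(self):
        assert mx.lbgi(trace([60.0] * 10)) > mx.lbgi(trace([65.0] * 10))

    def test_lbgi_flags_deep_hypoglycemia(self):
        assert mx.lbgi(trace([50.0] * 10)) >= mx.LBGI_RISK_THRESHOLD

    def test_lbgi_rejects_nonpositive_glucose(self):
        with pytest.raises(ValidationError):
            mx.lbgi(np.array([100.0, 0.0]))

    def test_postprandial_summary_consistency(self):
        values = np.concatenate([np.full(10, 120.0), np.linspace(120, 220, 20),
                                 np.linspace(220, 120, 20), np.full(30, 120.0)])
        t = trace(values)
        summary = mx.summarize_postprandial(t, meal_time=50.0)
        assert summary.iauc > 0
        assert summary.tir_pct + summary.tar_pct + summary.tbr70_pct == pytest.approx(100.0)
        assert summary.lbgi == 0.0
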