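"""Detection-performance and postprandial glycemic metrics.

Detection metrics (sensitivity, false discovery rate, detection time) are
computed from a greedy chronological matching of alerts to unannounced
meals within a matching window, with exact Clopper-Pearson binomial
confidence intervals.  Glycemic metrics are the standard CGM consensus
quantities: incremental area under the curve above the meal-start baseline
(trapezoidal rule), time in/above/below range, and the low blood glucose
index (LBGI), a nonlinear risk transform emphasising hypoglycemia.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import UndefinedMetricError, ValidationError
from .policy import DetectionEvent
from .simulator import CgmTrace, MealEvent

LBGI_RISK_THRESHOLD = 5.0   # LBGI at or above this flags elevated hypoglycemia risk


@dataclass
class MatchResult:
    """Outcome of matching detection alerts to unannounced meals.

    ``true_positives`` holds (meal, event, delay-in-minutes) triples; every
    meal and every event appears in exactly one bucket.
    """

    true_positives: list[tuple[MealEvent, DetectionEvent, float]] = field(default_factory=list)
    missed_meals: list[MealEvent] = field(default_factory=list)
    false_events: list[DetectionEvent] = field(default_factory=list)
    matching_window: float = 120.0

    @property
    def n_meals(self) -> int:
        return len(self.true_positives) + len(self.missed_meals)

    @property
    def n_events(self) -> int:
        return len(self.true_positives) + len(self.false_events)

    def restricted(self, min_grams: float, max_grams: float) -> "MatchResult":
        """The same match restricted to meals within [min_grams, max_grams]."""
        keep = lambda m: min_grams <= m.grams <= max_grams
        return MatchResult(
            true_positives=[tp for tp in self.true_positives if keep(tp[0])],
            missed_meals=[m for m in self.missed_meals if keep(m)],
            false_events=list(self.false_events),
            matching_window=self.matching_window,
        )

    def merge(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(
            true_positives=self.true_positives + other.true_positives,
            missed_meals=self.missed_meals + other.missed_meals,
            false_events=self.false_events + other.false_events,
            matching_window=self.matching_window,
        )


def match_detections(meals: list[MealEvent], events: list[DetectionEvent],
                     window: float = 120.0) -> MatchResult:
    """Greedy chronological matching of alerts to unannounced meals.

    Each alert matches the most recent still-unmatched unannounced meal
    that started within ``window`` minutes before it; unmatched alerts are
    false, unmatched meals missed.
    """
    meals = sorted((m for m in meals if not m.announced and not m.is_rescue),
                   key=lambda m: m.time)
    events = sorted(events, key=lambda e: e.alert_time)
    matched = [False] * len(meals)
    result = MatchResult(matching_window=window)
    for event in events:
        candidate = None
        for j, meal in enumerate(meals):
            if matched[j]:
                continue
            delay = event.alert_time - meal.time
            if 0 <= delay <= window:
                candidate = j
        if candidate is None:
            result.false_events.append(event)
        else:
            matched[candidate] = True
            result.true_positives.append(
                (meals[candidate], event, event.alert_time - meals[candidate].time))
    result.missed_meals = [m for m, used in zip(meals, matched) if not used]
    return result


def sensitivity(match: MatchResult) -> float:
    """Detected fraction of unannounced meals, in percent."""
    if match.n_meals == 0:
        raise UndefinedMetricError("sensitivity undefined: no meals")
    return 100.0 * len(match.true_positives) / match.n_meals


def false_discovery_rate(match: MatchResult) -> float:
    """Fraction of alerts not attributable to a meal, in percent."""
    if match.n_events == 0:
        raise UndefinedMetricError("false discovery rate undefined: no alerts")
    return 100.0 * len(match.false_events) / match.n_events


def mean_detection_time(match: MatchResult) -> tuple[float, float]:
    """Mean and SD (minutes) of meal-start-to-alert delays over true positives."""
    if not match.true_positives:
        raise UndefinedMetricError("detection time undefined: no true positives")
    delays = np.array([d for _, _, d in match.true_positives])
    return float(delays.mean()), float(delays.std())


def clopper_pearson(successes: int, trials: int, alpha: float = 0.05,
                    ) -> tuple[float, float]:
    """Exact binomial confidence interval, in percent.

    Beta-quantile formulation of the tail-probability inversion; the lower
    bound is 0 when successes = 0 and the upper bound 100 when
    successes = trials.
    """
    if trials < 1 or not 0 <= successes <= trials:
        raise ValidationError("clopper_pearson: need 0 <= successes <= trials, trials >= 1")
    if successes == 0:
        lower = 0.0
    else:
        lower = float(stats.beta.ppf(alpha / 2, successes, trials - successes + 1))
    if successes == trials:
        upper = 1.0
    else:
        upper = float(stats.beta.ppf(1 - alpha / 2, successes + 1, trials - successes))
    return 100.0 * lower, 100.0 * upper


# ---------------------------------------------------------------------------
# glycemic outcomes
# ---------------------------------------------------------------------------

def iauc(trace: CgmTrace, meal_time: float, horizon: float = 240.0) -> float:
    """Incremental area under the glucose curve, in mg.h/dL.

    Trapezoidal integral of max(G - baseline, 0) over [meal_time,
    meal_time + horizon], with baseline the sensor glucose at meal start;
    below-baseline excursions contribute zero.
    """
    times = trace.times
    lo, hi = meal_time, meal_time + horizon
    if lo < times[0] - trace.cadence / 2 or hi > times[-1] + 1e-9:
        raise ValidationError("iauc: trace does not cover the post-meal horizon")
    start = int(np.searchsorted(times, lo - 1e-9))
    stop = int(np.searchsorted(times, hi + 1e-9))
    seg = trace.values[start:stop]
    baseline = seg[0]
    incremental = np.maximum(seg - baseline, 0.0)
    return float(np.trapezoid(incremental, dx=trace.cadence / 60.0))


def time_in_ranges(trace: CgmTrace | np.ndarray) -> tuple[float, float, float, float]:
    """(TIR 70-180, TAR >180, TBR <70, TBR <54) as percentages of samples.

    Boundary values 70 and 180 mg/dL count as in range.
    """
    values = trace.values if isinstance(trace, CgmTrace) else np.asarray(trace, dtype=float)
    if values.size == 0:
        raise ValidationError("time_in_ranges: empty trace")
    tir = 100.0 * np.mean((values >= 70.0) & (values <= 180.0))
    tar = 100.0 * np.mean(values > 180.0)
    tbr70 = 100.0 * np.mean(values < 70.0)
    tbr54 = 100.0 * np.mean(values < 54.0)
    return float(tir), float(tar), float(tbr70), float(tbr54)


def lbgi(trace: CgmTrace | np.ndarray) -> float:
    """Low blood glucose index of a CGM trace.

    With f(g) = 1.509 ((ln g)^1.084 - 5.381), each sample contributes
    rl(g) = 10 f(g)^2 when f(g) < 0 and 0 otherwise; the LBGI is the mean
    contribution.  Zero for traces uniformly above ~112.7 mg/dL; values at
    or above 5.0 flag elevated hypoglycemia risk.
    """
    values = trace.values if isinstance(trace, CgmTrace) else np.asarray(trace, dtype=float)
    if values.size == 0 or np.any(values <= 0):
        raise ValidationError("lbgi: glucose samples must be positive")
    f = 1.509 * (np.log(values) ** 1.084 - 5.381)
    rl = np.where(f < 0, 10.0 * f ** 2, 0.0)
    return float(rl.mean())


@dataclass(frozen=True)
class GlycemicSummary:
    """Postprandial outcomes for one meal or one trace segment."""

    iauc: float
    tir_pct: float
    tar_pct: float
    tbr70_pct: float
    tbr54_pct: float
    lbgi: float


def summarize_postprandial(trace: CgmTrace, meal_time: float,
                           horizon: float = 240.0) -> GlycemicSummary:
    """All glycemic outcomes over the post-meal horizon of one meal."""
    times = trace.times
    start = int(np.searchsorted(times, meal_time - 1e-9))
    stop = int(np.searchsorted(times, meal_time + horizon + 1e-9))
    seg = trace.values[start:stop]
    tir, tar, tbr70, tbr54 = time_in_ranges(seg)
    return GlycemicSummary(
        iauc=iauc(trace, meal_time, horizon),
        tir_pct=tir, tar_pct=tar, tbr70_pct=tbr70, tbr54_pct=tbr54,
        lbgi=lbgi(seg),
    )
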