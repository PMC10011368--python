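"""Alerting and dosing policy on top of per-step network outputs.

A detection alert fires at the first up-crossing of the probability
threshold (default 0.86); further alerts are suppressed for a refractory
period and around reported rescue-carbohydrate intakes.  The recommended
meal insulin is the class-representative grams divided by the person's
carbohydrate ratio, discounted by 1% for every minute elapsed since the
presumed meal time (alert time minus 25 min, the mean in-silico detection
delay) — so an immediately acknowledged alert doses 75% of the nominal
meal insulin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .features import N_CARB_CLASSES

logger = logging.getLogger(__name__)

#: representative grams per carbohydrate class (bin midpoints; 80+ -> 90 g)
CLASS_GRAMS = (10.0, 30.0, 50.0, 70.0, 90.0)


@dataclass(frozen=True)
class PolicyConfig:
    p_threshold: float = 0.86
    refractory: float = 90.0          # min between alerts
    presumed_meal_offset: float = 25.0  # min before alert the meal is presumed
    rescue_mask: float = 60.0         # min of suppression after rescue carbs
    max_bolus: float = 10.0           # units, safety cap

    def __post_init__(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ValidationError("PolicyConfig.p_threshold must lie in (0, 1)")
        if self.refractory < 0 or self.presumed_meal_offset < 0 or self.rescue_mask < 0:
            raise ValidationError("PolicyConfig time fields must be >= 0")
        if self.max_bolus <= 0:
            raise ValidationError("PolicyConfig.max_bolus must be > 0")


@dataclass(frozen=True)
class DetectionEvent:
    alert_time: float
    p_meal: float
    carb_class: int
    estimated_grams: float
    presumed_meal_time: float


@dataclass(frozen=True)
class DoseRecommendation:
    units: float
    fraction_applied: float
    ack_time: float


def class_to_grams(carb_class: int) -> float:
    """Representative grams for a carbohydrate class (bin midpoint)."""
    if carb_class not in range(N_CARB_CLASSES):
        raise ValidationError(f"carb_class must be in 0..{N_CARB_CLASSES - 1}")
    return CLASS_GRAMS[carb_class]


def dose_fraction(minutes_since_presumed_meal: float) -> float:
    """Fraction of nominal meal insulin to dose: 1 - 0.01 per elapsed minute,
    clamped to [0, 1]."""
    if minutes_since_presumed_meal < 0:
        raise ValidationError("dose_fraction: minutes must be >= 0")
    return float(np.clip(1.0 - 0.01 * minutes_since_presumed_meal, 0.0, 1.0))


def _argmax_prefer_larger(probs: np.ndarray) -> int:
    """Argmax with ties resolved toward the larger class index."""
    probs = np.asarray(probs)
    best = len(probs) - 1 - int(np.argmax(probs[::-1]))
    if np.sum(probs == probs[best]) > 1:
        logger.info("class-probability tie resolved toward class %d", best)
    return best


def detect_stream(times: np.ndarray, p_meal: np.ndarray, class_probs: np.ndarray,
                  config: PolicyConfig = PolicyConfig(),
                  rescue_times: tuple[float, ...] = (),
                  ) -> list[DetectionEvent]:
    """Turn a per-5-min probability series into discrete detection alerts.

    An alert fires at each first up-crossing of ``p_threshold``; alerts
    within ``refractory`` minutes of the previous alert, or within
    ``rescue_mask`` minutes after a reported rescue-carb time, are
    suppressed.
    """
    times = np.asarray(times, dtype=float)
    p_meal = np.asarray(p_meal, dtype=float)
    class_probs = np.asarray(class_probs, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValidationError("detect_stream: times must be strictly increasing")
    events: list[DetectionEvent] = []
    last_alert = -np.inf
    above = False
    for i, t in enumerate(times):
        p = p_meal[i]
        if p < config.p_threshold:
            above = False
            continue
        crossing = not above
        above = True
        if not crossing:
            continue
        if t - last_alert < config.refractory:
            continue
        if any(0 <= t - rt <= config.rescue_mask for rt in rescue_times):
            continue
        cls = _argmax_prefer_larger(class_probs[i])
        events.append(DetectionEvent(
            alert_time=float(t),
            p_meal=float(p),
            carb_class=cls,
            estimated_grams=class_to_grams(cls),
            presumed_meal_time=float(t) - config.presumed_meal_offset,
        ))
        last_alert = t
    return events


def recommend_dose(event: DetectionEvent, ack_time: float, carb_ratio: float,
                   config: PolicyConfig = PolicyConfig(),
                   grams_override: float | None = None) -> DoseRecommendation:
    """Delay-discounted meal insulin for an acknowledged detection alert.

    units = dose_fraction(ack_time - presumed_meal_time)
            * estimated grams / carb_ratio, capped at ``max_bolus``.
    ``grams_override`` models the user editing the estimated meal size in
    the confirmation step.
    """
    if carb_ratio <= 0:
        raise ValidationError("recommend_dose: carb_ratio must be > 0")
    if ack_time < event.alert_time:
        raise ValidationError("recommend_dose: ack_time must be >= alert_time")
    grams = event.estimated_grams if grams_override is None else float(grams_override)
    fraction = dose_fraction(ack_time - event.presumed_meal_time)
    units = min(fraction * grams / carb_ratio, config.max_bolus)
    return DoseRecommendation(units=units, fraction_applied=fraction, ack_time=ack_time)
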