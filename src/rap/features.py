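"""Feature extraction: a two-hour CGM + insulin history -> 32 predictors.

The predictor schema is frozen and versioned (``SCHEMA_VERSION``): glucose
level/trend/shape statistics over the trailing 120 minutes, insulin-on-board
features from a bilinear-decay kernel, dosing-history features, and a cyclic
(cosine, sine) encoding of the hour of day.  Labels pair a binary missed-meal
flag with a 5-way carbohydrate-content class over the bins
[0,20), [20,40), [40,60), [60,80), 80+ grams.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .simulator import CGM_CADENCE_MIN, CgmTrace, InsulinRecord, MealEvent

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "1"
WINDOW_SAMPLES = 24          # 2 h of 5-min CGM
DEFAULT_DIA_MIN = 240.0      # duration of insulin action
DEFAULT_LABEL_HORIZON_MIN = 60.0
CARB_BIN_EDGES = (20.0, 40.0, 60.0, 80.0)
N_CARB_CLASSES = 5
NO_MEAL_CLASS = -1           # sentinel carb class for meal_flag == 0

FEATURE_NAMES: tuple[str, ...] = (
    "cgm_mean_30", "cgm_mean_60", "cgm_mean_90", "cgm_mean_120",
    "cgm_roc_10", "cgm_roc_20", "cgm_roc_30", "cgm_roc_60",
    "cgm_last", "cgm_range", "cgm_area_above_baseline",
    "diff1_mean", "diff1_sd", "diff1_max",
    "diff2_mean", "diff2_max",
    "consecutive_rises",
    "iob_now", "iob_30", "iob_60", "iob_delta_60",
    "bolus_units_window", "basal_units_window",
    "minutes_since_bolus",
    "hour_cos", "hour_sin",
    "cgm_sd", "last_minus_mean60", "max_roc_position",
    "frac_above_140", "cgm_t60", "cgm_baseline",
)
N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 32


@dataclass(frozen=True)
class HistoryWindow:
    """Exactly 24 consecutive 5-min CGM samples ending at ``prediction_time``
    plus the insulin record covering the trailing two hours."""

    cgm: np.ndarray
    insulin: InsulinRecord
    prediction_time: float      # minutes from scenario start

    def __post_init__(self) -> None:
        values = np.asarray(self.cgm, dtype=float)
        if values.shape != (WINDOW_SAMPLES,):
            raise ValidationError(
                f"HistoryWindow.cgm must hold exactly {WINDOW_SAMPLES} samples")
        if not np.all(np.isfinite(values)):
            raise ValidationError("HistoryWindow.cgm contains non-finite samples")
        object.__setattr__(self, "cgm", values)


@dataclass(frozen=True)
class LabelPair:
    meal_flag: int
    carb_class: int = NO_MEAL_CLASS

    def __post_init__(self) -> None:
        if self.meal_flag not in (0, 1):
            raise ValidationError("LabelPair.meal_flag must be 0 or 1")
        if self.meal_flag == 1 and not 0 <= self.carb_class < N_CARB_CLASSES:
            raise ValidationError("LabelPair.carb_class must be in 0..4 when meal_flag=1")
        if self.meal_flag == 0 and self.carb_class != NO_MEAL_CLASS:
            raise ValidationError("LabelPair.carb_class is a sentinel when meal_flag=0")


def carb_class_of(grams: float) -> int:
    """Map grams of carbohydrate to the 5-way class index."""
    return int(np.digitize(grams, CARB_BIN_EDGES))


def encode_hour(hour: float) -> tuple[float, float]:
    """Cyclic (cos, sin) encoding of the hour of day on the unit circle."""
    if not 0.0 <= hour < 24.0:
        raise ValidationError("encode_hour: hour must lie in [0, 24)")
    angle = 2.0 * math.pi * hour / 24.0
    return math.cos(angle), math.sin(angle)


def _bilinear_residual(age: float, dia: float) -> float:
    """Residual fraction of insulin activity ``age`` minutes after delivery:
    1 - age/dia on [0, dia], 0 beyond."""
    if age < 0 or age >= dia:
        return 0.0
    return 1.0 - age / dia


def insulin_on_board(record: InsulinRecord, t: float, dia: float = DEFAULT_DIA_MIN) -> float:
    """Residual insulin activity (units) at time ``t``.

    Each bolus contributes units * R(age/dia) with the bilinear kernel
    R(x) = 1 - x on [0, 1]; basal delivery contributes the same kernel
    integrated over the trailing ``dia`` minutes of infusion.
    """
    if dia <= 0:
        raise ValidationError("insulin_on_board: dia must be positive")
    iob = sum(units * _bilinear_residual(t - bt, dia)
              for bt, units in record.boluses)
    for start, end, rate in record.basal_segments:
        a = max(start, t - dia)
        b = min(end, t)
        if b <= a:
            continue
        # integral of (rate/60) * (1 - (t - s)/dia) ds over s in [a, b]
        iob += rate / 60.0 * ((b - a) - ((t - a) ** 2 - (t - b) ** 2) / (2.0 * dia))
    return iob


def _window_insulin_sums(record: InsulinRecord, t: float) -> tuple[float, float, float]:
    """(bolus units, basal units, minutes since last bolus) over [t-120, t]."""
    lo = t - 120.0
    bolus_units = sum(u for bt, u in record.boluses if lo < bt <= t)
    basal_units = 0.0
    for start, end, rate in record.basal_segments:
        a, b = max(start, lo), min(end, t)
        if b > a:
            basal_units += rate * (b - a) / 60.0
    past = [t - bt for bt, _ in record.boluses if bt <= t]
    since_bolus = min(min(past), 240.0) if past else 240.0
    return bolus_units, basal_units, since_bolus


def extract_features(window: HistoryWindow, dia: float = DEFAULT_DIA_MIN) -> np.ndarray:
    """Compute the frozen 32-feature vector for one history window."""
    g = window.cgm
    t = window.prediction_time
    step = CGM_CADENCE_MIN

    means = [float(g[-k:].mean()) for k in (6, 12, 18, 24)]
    # rate of change over 10/20/30/60 min from endpoint differences
    rocs = [float((g[-1] - g[-1 - k]) / (k * step)) for k in (2, 4, 6, 12)]

    d1 = np.diff(g)
    d2 = np.diff(g, n=2)
    baseline = float(g[0])
    area = float(np.trapezoid(g - baseline, dx=step))

    rises = 0
    for delta in d1[::-1]:
        if delta > 0:
            rises += 1
        else:
            break

    iob_now = insulin_on_board(window.insulin, t, dia)
    iob_30 = insulin_on_board(window.insulin, t - 30.0, dia)
    iob_60 = insulin_on_board(window.insulin, t - 60.0, dia)
    bolus_units, basal_units, since_bolus = _window_insulin_sums(window.insulin, t)
    hour_cos, hour_sin = encode_hour((t / 60.0) % 24.0)

    max_roc_idx = int(np.argmax(d1))
    max_roc_position = (len(d1) - 1 - max_roc_idx) * step  # minutes back from t

    values = np.array([
        *means,
        *rocs,
        float(g[-1]),
        float(g.max() - g.min()),
        area,
        float(d1.mean()), float(d1.std()), float(d1.max()),
        float(d2.mean()), float(d2.max()),
        float(rises),
        iob_now, iob_30, iob_60, iob_now - iob_60,
        bolus_units, basal_units,
        since_bolus,
        hour_cos, hour_sin,
        float(g.std()),
        float(g[-1] - g[-12:].mean()),
        float(max_roc_position),
        float((g > 140.0).mean()),
        float(g[-13]),
        baseline,
    ])
    if not np.all(np.isfinite(values)):
        raise ValidationError("extract_features produced non-finite values")
    return values


def make_labels(meals: list[MealEvent], t: float,
                horizon: float = DEFAULT_LABEL_HORIZON_MIN) -> LabelPair:
    """Label a prediction time: positive iff an unannounced, non-rescue meal
    started in (t - horizon, t]; the class is that meal's carbohydrate bin.

    If two unannounced meals fall inside one horizon the most recent wins
    (a warning is logged).
    """
    if horizon <= 0:
        raise ValidationError("make_labels: horizon must be positive")
    hits = [m for m in meals
            if not m.announced and not m.is_rescue and t - horizon < m.time <= t]
    if not hits:
        return LabelPair(0)
    if len(hits) > 1:
        logger.warning("two unannounced meals within one labeling horizon at t=%s; "
                       "using the most recent", t)
    meal = max(hits, key=lambda m: m.time)
    return LabelPair(1, carb_class_of(meal.grams))


def featurize_trace(cgm: CgmTrace, insulin: InsulinRecord, meals: list[MealEvent],
                    label_horizon: float = DEFAULT_LABEL_HORIZON_MIN,
                    dia: float = DEFAULT_DIA_MIN,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Slide a two-hour window over a subject's record.

    Returns ``(times, X, meal_flag, carb_class)`` with one row per 5-min
    prediction step from the first complete window onward.
    """
    values = cgm.values
    n = len(values)
    if n < WINDOW_SAMPLES:
        raise ValidationError("trace shorter than one history window")
    times = []
    rows = []
    flags = []
    classes = []
    for i in range(WINDOW_SAMPLES - 1, n):
        t = cgm.start_time + i * cgm.cadence
        window = HistoryWindow(values[i - WINDOW_SAMPLES + 1: i + 1], insulin, t)
        label = make_labels(meals, t, label_horizon)
        times.append(t)
        rows.append(extract_features(window, dia))
        flags.append(label.meal_flag)
        classes.append(label.carb_class)
    return (np.array(times), np.vstack(rows),
            np.array(flags, dtype=int), np.array(classes, dtype=int))
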