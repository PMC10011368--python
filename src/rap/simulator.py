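"""Virtual-patient simulator for type 1 diabetes meal-detection studies.

Generates synthetic cohorts of virtual subjects, realistic meal schedules
(low-carb / high-carb diets, a configurable fraction of meals eaten without
an insulin bolus), and glucose/insulin time series from a minimal-model
glucose ODE driven by two-compartment gut-absorption and subcutaneous
insulin kinetics.  The continuous glucose monitor (CGM) is modelled as a
pure transport delay plus i.i.d. Gaussian noise, sampled every 5 minutes
and clamped to the sensor dynamic range [39, 401] mg/dL.

The dynamical model is deliberately minimal: it is calibrated so that a
typical unannounced meal produces a detectable CGM rise (+10 mg/dL over
baseline) roughly 15-30 minutes after eating, which is the feature of real
postprandial physiology that meal detection hinges on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .errors import SimulationError, ValidationError

CGM_CADENCE_MIN = 5.0
CGM_FLOOR = 39.0
CGM_CEIL = 401.0

#: glucose effectiveness: fractional pull of plasma glucose back to the
#: fasting level, per minute.  0.02/min puts the postprandial CGM peak at
#: ~90 min and largely resolves excursions within 3-4 h, as real CGM does.
GLUCOSE_EFFECTIVENESS = 0.02

#: hard floor for plasma glucose (mg/dL); the minimal model has no
#: counter-regulatory response, so a floor stands in for it.
PLASMA_FLOOR = 20.0


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientParams:
    """Physiology and therapy settings of one virtual subject.

    Parameters
    ----------
    body_mass : float
        kg.
    carb_ratio : float
        Grams of carbohydrate covered by one unit of insulin (g/U).
    correction_factor : float
        Glucose drop per unit of insulin (mg/dL per U).
    basal_rate : float
        Continuous background insulin infusion (U/h).
    insulin_sensitivity : float
        Total glucose-lowering effect of one unit of absorbed insulin
        (mg/dL per U); the gain applied to the insulin-appearance signal.
    glucose_fasting : float
        Fasting equilibrium glucose (mg/dL).
    meal_absorption_tau : float
        Time constant of each gut compartment (min).
    insulin_absorption_tau : float
        Time constant of each subcutaneous insulin compartment (min).
    cgm_noise_sd : float
        Standard deviation of additive sensor noise (mg/dL).
    sensor_delay : float
        Pure transport delay between plasma and sensor glucose (min).
    """

    body_mass: float
    carb_ratio: float
    correction_factor: float
    basal_rate: float
    insulin_sensitivity: float
    glucose_fasting: float
    meal_absorption_tau: float
    insulin_absorption_tau: float
    cgm_noise_sd: float = 5.0
    sensor_delay: float = 10.0

    def __post_init__(self) -> None:
        positive = (
            "body_mass", "carb_ratio", "correction_factor", "basal_rate",
            "insulin_sensitivity", "glucose_fasting", "meal_absorption_tau",
            "insulin_absorption_tau",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValidationError(f"PatientParams.{name} must be positive")
        if self.cgm_noise_sd < 0:
            raise ValidationError("PatientParams.cgm_noise_sd must be >= 0")
        if not 3.0 <= self.carb_ratio <= 30.0:
            raise ValidationError("PatientParams.carb_ratio must lie in [3, 30] g/U")
        if not 90.0 <= self.glucose_fasting <= 160.0:
            raise ValidationError("PatientParams.glucose_fasting must lie in [90, 160] mg/dL")
        if not 5.0 <= self.sensor_delay <= 15.0:
            raise ValidationError("PatientParams.sensor_delay must lie in [5, 15] min")


@dataclass(frozen=True)
class MealEvent:
    """One carbohydrate intake.

    ``announced`` meals received a user bolus at mealtime; unannounced,
    non-rescue meals are the detection target.  ``absorption_multiplier``
    scales the gut time constant for that meal only (high-fat meals absorb
    slower; default 1.0 = off).
    """

    time: float            # minutes from scenario start
    grams: float
    announced: bool
    is_rescue: bool = False
    absorption_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if self.grams < 0:
            raise ValidationError("MealEvent.grams must be >= 0")
        if self.absorption_multiplier <= 0:
            raise ValidationError("MealEvent.absorption_multiplier must be > 0")


@dataclass(frozen=True)
class CgmTrace:
    """A 5-min cadence CGM record; values are mg/dL within [39, 401]."""

    start_time: float           # minutes; 0 = scenario start
    values: np.ndarray
    cadence: float = CGM_CADENCE_MIN

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.cadence != CGM_CADENCE_MIN:
            raise ValidationError("CgmTrace.cadence is fixed at 5 min")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + self.cadence * np.arange(len(self.values))


@dataclass(frozen=True)
class InsulinRecord:
    """Basal segments (start, end, U/h) and boluses (time, units)."""

    basal_segments: tuple[tuple[float, float, float], ...]
    boluses: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        segs = tuple(tuple(map(float, s)) for s in self.basal_segments)
        bols = tuple((float(t), float(u)) for t, u in self.boluses)
        object.__setattr__(self, "basal_segments", segs)
        object.__setattr__(self, "boluses", bols)
        for start, end, rate in segs:
            if rate < 0 or end <= start:
                raise ValidationError("InsulinRecord basal segment invalid")
        prev_end = None
        for start, end, _ in sorted(segs):
            if prev_end is not None and start < prev_end:
                raise ValidationError("InsulinRecord basal segments overlap")
            prev_end = end
        if any(u < 0 for _, u in bols):
            raise ValidationError("InsulinRecord bolus units must be >= 0")

    def total_units(self) -> float:
        """Total delivered insulin: integral of basal plus sum of boluses."""
        basal = sum((end - start) / 60.0 * rate for start, end, rate in self.basal_segments)
        return basal + sum(u for _, u in self.boluses)


_DIETS = ("low_carb", "high_carb", "mixed")


@dataclass(frozen=True)
class ScenarioConfig:
    """Cohort-level description of an in-silico study.

    Defaults reproduce the reference protocol: 199 virtual subjects
    followed for 14 days, meal sizes 46.6 +/- 27.1 g (low-carb diet) or
    72.5 +/- 29.3 g (high-carb), and 33% of meals eaten without a bolus.
    """

    n_subjects: int = 199
    n_days: int = 14
    diet: str = "mixed"
    meal_mean_sd: dict = field(default_factory=lambda: {
        "low_carb": (46.6, 27.1),
        "high_carb": (72.5, 29.3),
    })
    unannounced_fraction: float = 0.33
    meals_per_day: int = 3
    meal_hours: tuple[float, ...] = (8.0, 12.5, 18.5)
    meal_time_jitter_sd: float = 30.0
    min_grams: float = 10.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValidationError("ScenarioConfig.n_subjects must be >= 0")
        if self.n_days < 1:
            raise ValidationError("ScenarioConfig.n_days must be >= 1")
        if self.diet not in _DIETS:
            raise ValidationError(f"ScenarioConfig.diet must be one of {_DIETS}")
        if not 0.0 <= self.unannounced_fraction <= 1.0:
            raise ValidationError("ScenarioConfig.unannounced_fraction must lie in [0, 1]")
        if self.meals_per_day < 1:
            raise ValidationError("ScenarioConfig.meals_per_day must be >= 1")
        if len(self.meal_hours) < self.meals_per_day:
            raise ValidationError("ScenarioConfig.meal_hours must provide meals_per_day entries")
        if self.meal_time_jitter_sd < 0:
            raise ValidationError("ScenarioConfig.meal_time_jitter_sd must be >= 0")

    @property
    def horizon_min(self) -> float:
        return self.n_days * 1440.0


# ---------------------------------------------------------------------------
# population and meal schedules
# ---------------------------------------------------------------------------

def generate_population(config: ScenarioConfig) -> list[PatientParams]:
    """Draw a reproducible cohort of virtual-subject parameter sets.

    Each subject is drawn from its own stream seeded by
    ``(config.rng_seed, subject_index)``, so any subject can be regenerated
    independently of cohort size.
    """
    subjects = []
    for i in range(config.n_subjects):
        rng = np.random.default_rng([config.rng_seed, i])
        correction = rng.uniform(30.0, 60.0)
        subjects.append(PatientParams(
            body_mass=float(np.clip(rng.lognormal(math.log(75.0), 0.15), 45.0, 120.0)),
            carb_ratio=rng.uniform(6.0, 15.0),
            correction_factor=correction,
            basal_rate=rng.uniform(0.6, 1.4),
            insulin_sensitivity=correction * rng.uniform(0.9, 1.1),
            glucose_fasting=rng.uniform(100.0, 150.0),
            meal_absorption_tau=float(np.clip(rng.normal(28.0, 5.0), 20.0, 45.0)),
            insulin_absorption_tau=float(np.clip(rng.normal(55.0, 8.0), 40.0, 80.0)),
            cgm_noise_sd=5.0,
            sensor_delay=float(rng.integers(5, 16)),
        ))
    return subjects


def _truncnorm_loc(target_mean: float, sd: float, lower: float) -> float:
    """Location parameter of a normal truncated at ``lower`` whose truncated
    mean equals ``target_mean``.

    Truncating a normal at a lower bound shifts its mean upward, so drawing
    from N(target_mean, sd) truncated at 10 g would overshoot the intended
    average meal size; this solves for the compensating location.
    """
    def truncated_mean(loc: float) -> float:
        a = (lower - loc) / sd
        return float(stats.truncnorm.mean(a, np.inf, loc=loc, scale=sd))

    return float(optimize.brentq(
        lambda loc: truncated_mean(loc) - target_mean,
        target_mean - 6 * sd, target_mean + sd,
    ))


def generate_meal_schedule(config: ScenarioConfig, subject_seed: int,
                           diet: str | None = None) -> list[MealEvent]:
    """Draw one subject's meal log for the scenario horizon.

    Meal sizes follow the diet's normal distribution truncated at
    ``config.min_grams`` (location adjusted so the truncated mean matches the
    configured diet mean); times are jittered around the canonical meal hours;
    each meal is independently unannounced with probability
    ``config.unannounced_fraction``.
    """
    rng = np.random.default_rng([config.rng_seed, subject_seed, 0x6D65616C])
    if diet is None:
        diet = config.diet
    if diet == "mixed":
        diet = "low_carb" if rng.random() < 0.5 else "high_carb"
    mean, sd = config.meal_mean_sd[diet]
    loc = _truncnorm_loc(mean, sd, config.min_grams)
    a = (config.min_grams - loc) / sd

    meals: list[MealEvent] = []
    horizon = config.horizon_min
    for day in range(config.n_days):
        for hour in config.meal_hours[: config.meals_per_day]:
            t = (day * 24.0 + hour) * 60.0 + rng.normal(0.0, config.meal_time_jitter_sd)
            t = float(np.clip(round(t), day * 1440.0, (day + 1) * 1440.0 - 1))
            if not 0 <= t < horizon:
                continue
            grams = float(stats.truncnorm.rvs(a, np.inf, loc=loc, scale=sd, random_state=rng))
            announced = bool(rng.random() >= config.unannounced_fraction)
            meals.append(MealEvent(time=t, grams=grams, announced=announced))
    meals.sort(key=lambda m: m.time)
    # enforce strictly increasing times (jitter collisions are rare but possible)
    out: list[MealEvent] = []
    for m in meals:
        if out and m.time <= out[-1].time:
            m = replace(m, time=out[-1].time + 1.0)
        out.append(m)
    return out


# ---------------------------------------------------------------------------
# subject simulation
# ---------------------------------------------------------------------------

def _two_compartment_appearance(t: np.ndarray, event_time: float, amount: float,
                                tau: float) -> np.ndarray:
    """Appearance rate (amount/min) of a bolus input through a two-compartment
    chain with equal time constants: a(t) = D * (t/tau^2) * exp(-t/tau)."""
    dt = t - event_time
    out = np.zeros_like(t)
    mask = dt > 0
    x = dt[mask] / tau
    out[mask] = amount * x / tau * np.exp(-x)
    return out


def simulate_subject(params: PatientParams, meals: list[MealEvent], horizon: float,
                     seed: int, bolus_for_announced: bool = True,
                     ) -> tuple[CgmTrace, InsulinRecord]:
    """Integrate one subject's glucose response to a meal schedule.

    The stand-in controller delivers the subject's basal rate continuously
    and, for announced meals only, a bolus of grams/carb_ratio at mealtime.
    Plasma glucose follows

        dG/dt = -sG (G - Gf) - kI (Ri(t) - Rb) + kC Ra(t)

    where Ra and Ri are carbohydrate and insulin appearance rates from
    two-compartment chains, Rb the basal appearance at steady state,
    kI = insulin_sensitivity and kC = insulin_sensitivity / carb_ratio (so a
    correctly bolused meal is glucose-neutral in total effect).  Fixed-step
    RK4 at 1 min; CGM sampled every 5 min at ``sensor_delay`` lag with
    additive Gaussian noise, clamped to [39, 401] mg/dL.
    """
    if horizon < 240:
        raise ValidationError("simulate_subject: horizon must be >= 240 min")
    for m in meals:
        if not 0 <= m.time < horizon:
            raise ValidationError(f"meal at t={m.time} outside horizon [0, {horizon})")

    n_min = int(round(horizon))
    # forcing terms on the half-minute grid required by RK4 stages
    t_half = np.arange(2 * n_min + 1) * 0.5

    k_insulin = params.insulin_sensitivity
    k_carb = params.insulin_sensitivity / params.carb_ratio
    basal_appearance = params.basal_rate / 60.0

    carb_rate = np.zeros_like(t_half)
    boluses: list[tuple[float, float]] = []
    for m in meals:
        tau = params.meal_absorption_tau * m.absorption_multiplier
        carb_rate += _two_compartment_appearance(t_half, m.time, m.grams, tau)
        if m.announced and bolus_for_announced and m.grams > 0:
            boluses.append((m.time, m.grams / params.carb_ratio))

    insulin_rate = np.full_like(t_half, basal_appearance)
    for bt, units in boluses:
        insulin_rate += _two_compartment_appearance(
            t_half, bt, units, params.insulin_absorption_tau)

    # net forcing beyond the equilibrium balance
    forcing = k_carb * carb_rate - k_insulin * (insulin_rate - basal_appearance)

    gf = params.glucose_fasting
    sg = GLUCOSE_EFFECTIVENESS
    plasma = np.empty(n_min + 1)
    g = gf
    plasma[0] = g
    h = 1.0
    for i in range(n_min):
        f0 = forcing[2 * i]
        f1 = forcing[2 * i + 1]
        f2 = forcing[2 * i + 2]
        k1 = -sg * (g - gf) + f0
        k2 = -sg * (g + 0.5 * h * k1 - gf) + f1
        k3 = -sg * (g + 0.5 * h * k2 - gf) + f1
        k4 = -sg * (g + h * k3 - gf) + f2
        g = g + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        if not math.isfinite(g):
            raise SimulationError(f"non-finite glucose at t={i + 1} min")
        g = max(g, PLASMA_FLOOR)
        plasma[i + 1] = g

    sample_times = np.arange(0, n_min + 1, int(CGM_CADENCE_MIN))
    delay = int(round(params.sensor_delay))
    source = np.clip(sample_times - delay, 0, n_min)
    sensor = plasma[source].copy()
    sensor[sample_times < delay] = plasma[0]

    rng = np.random.default_rng(seed)
    noisy = sensor + rng.normal(0.0, params.cgm_noise_sd, size=sensor.shape)
    cgm = CgmTrace(start_time=0.0, values=np.clip(noisy, CGM_FLOOR, CGM_CEIL))
    record = InsulinRecord(
        basal_segments=((0.0, float(horizon), params.basal_rate),),
        boluses=tuple(boluses),
    )
    return cgm, record
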