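import numpy as np
import pytest

from rap import simulator as sim


@pytest.fixture(scope="session")
def quiet_params() -> sim.PatientParams:
    """A typical subject with a noiseless sensor, for deterministic checks."""
    return sim.PatientParams(
        body_mass=75.0, carb_ratio=10.0, correction_factor=45.0,
        basal_rate=1.0, insulin_sensitivity=45.0, glucose_fasting=120.0,
        meal_absorption_tau=28.0, insulin_absorption_tau=55.0,
        cgm_noise_sd=0.0, sensor_delay=10.0,
    )


@pytest.fixture(scope="session")
def small_scenario() -> sim.ScenarioConfig:
    return sim.ScenarioConfig(n_subjects=3, n_days=2, rng_seed=11)


@pytest.fixture(scope="session")
def simulated_subject(small_scenario):
    """(params, meals, cgm, insulin) of one simulated 2-day subject."""
    params = sim.generate_population(small_scenario)[0]
    meals = sim.generate_meal_schedule(small_scenario, subject_seed=0)
    cgm, insulin = sim.simulate_subject(
        params, meals, small_scenario.horizon_min, seed=42)
    return params, meals, cgm, insulin
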