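"""End-to-end in-silico validation experiment.

Simulates a virtual-patient cohort, featurizes every subject's record,
trains the multioutput detection network on a subject-level training
split, runs the alerting policy on the held-out subjects, and scores
detection (sensitivity overall and for 40-80 g meals, false discovery
rate, detection time, exact confidence intervals) and postprandial
glycemic outcomes.  All randomness derives from one global seed, so a run
is reproducible byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import features, metrics, model, policy, simulator
from .errors import RapError

REPORT_SCHEMA_VERSION = "1"


@dataclass(frozen=True)
class RunConfig:
    """Full configuration of one in-silico run.

    One ``global_seed`` deterministically derives the seeds of every stage
    (population draw, meal schedules, sensor noise, network init/shuffling,
    train/test split).
    """

    scenario: simulator.ScenarioConfig = field(default_factory=simulator.ScenarioConfig)
    net: model.MealNetConfig = field(default_factory=model.MealNetConfig)
    policy: policy.PolicyConfig = field(default_factory=policy.PolicyConfig)
    holdout_fraction: float = 0.25
    label_horizon: float = features.DEFAULT_LABEL_HORIZON_MIN
    match_window: float = 120.0
    dia: float = features.DEFAULT_DIA_MIN
    global_seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=list)


def _stage_seeds(global_seed: int) -> dict[str, int]:
    state = np.random.SeedSequence(global_seed).generate_state(4)
    names = ("scenario", "noise", "net", "split")
    return {name: int(s % (2 ** 31)) for name, s in zip(names, state)}


class StageFailure(RapError, RuntimeError):
    def __init__(self, stage: str, seed: int, cause: Exception):
        super().__init__(f"stage {stage!r} failed (seed {seed}): {cause}")
        self.stage = stage
        self.__cause__ = cause


def simulate_cohort(scenario: simulator.ScenarioConfig, noise_seed: int,
                    ) -> list[dict]:
    """Simulate every subject of a scenario; returns per-subject records."""
    population = simulator.generate_population(scenario)
    cohort = []
    for i, params in enumerate(population):
        meals = simulator.generate_meal_schedule(scenario, subject_seed=i)
        cgm, insulin = simulator.simulate_subject(
            params, meals, scenario.horizon_min,
            seed=(noise_seed + i) % (2 ** 31))
        cohort.append({"subject_id": i, "params": params, "meals": meals,
                       "cgm": cgm, "insulin": insulin})
    return cohort


def run_insilico_experiment(config: RunConfig) -> dict:
    """Run the full simulate -> featurize -> train -> detect -> evaluate
    pipeline and return the report dictionary."""
    seeds = _stage_seeds(config.global_seed)
    scenario = replace(config.scenario, rng_seed=seeds["scenario"])

    try:
        cohort = simulate_cohort(scenario, seeds["noise"])
    except Exception as exc:                         # pragma: no cover
        raise StageFailure("simulate", seeds["scenario"], exc) from exc

    try:
        for subject in cohort:
            times, X, flags, classes = features.featurize_trace(
                subject["cgm"], subject["insulin"], subject["meals"],
                label_horizon=config.label_horizon, dia=config.dia)
            subject.update(times=times, X=X, flags=flags, classes=classes)
    except Exception as exc:                         # pragma: no cover
        raise StageFailure("featurize", seeds["scenario"], exc) from exc

    # subject-level split: no subject contributes windows to both sides
    rng = np.random.default_rng(seeds["split"])
    order = rng.permutation(len(cohort))
    n_test = max(1, int(round(config.holdout_fraction * len(cohort))))
    test_ids = set(order[:n_test].tolist())
    train_subjects = [s for s in cohort if s["subject_id"] not in test_ids]
    test_subjects = [s for s in cohort if s["subject_id"] in test_ids]
    if not train_subjects:
        raise RapError("no training subjects left after hold-out split")

    try:
        X_train = np.vstack([s["X"] for s in train_subjects])
        flags_train = np.concatenate([s["flags"] for s in train_subjects])
        classes_train = np.concatenate([s["classes"] for s in train_subjects])
        net = model.build(replace(config.net, seed=seeds["net"]))
        model.train(net, X_train, flags_train, classes_train)
    except Exception as exc:
        raise StageFailure("train", seeds["net"], exc) from exc

    try:
        overall = metrics.MatchResult(matching_window=config.match_window)
        meal_summaries = []
        subject_tir = []
        subject_lbgi = []
        for subject in test_subjects:
            p, probs = model.predict(net, subject["X"])
            events = policy.detect_stream(subject["times"], p, probs, config.policy)
            match = metrics.match_detections(
                subject["meals"], events, window=config.match_window)
            overall = overall.merge(match)
            horizon = scenario.horizon_min
            for meal in subject["meals"]:
                if not meal.announced and meal.time + 240.0 <= horizon:
                    meal_summaries.append(metrics.summarize_postprandial(
                        subject["cgm"], meal.time))
            tir, tar, tbr70, tbr54 = metrics.time_in_ranges(subject["cgm"])
            subject_tir.append((tir, tar, tbr70, tbr54))
            subject_lbgi.append(metrics.lbgi(subject["cgm"]))
    except Exception as exc:
        raise StageFailure("evaluate", seeds["split"], exc) from exc

    report = _build_report(config, seeds, overall, meal_summaries,
                           subject_tir, subject_lbgi,
                           n_train=len(train_subjects), n_test=len(test_subjects))
    return report


def _build_report(config, seeds, overall, meal_summaries, subject_tir,
                  subject_lbgi, n_train, n_test) -> dict:
    restricted = overall.restricted(40.0, 80.0)
    if overall.true_positives:
        dt_mean, dt_sd = metrics.mean_detection_time(overall)
        dt_mean, dt_sd = round(dt_mean, 4), round(dt_sd, 4)
    else:
        dt_mean = dt_sd = None
    tp, n_meals = len(overall.true_positives), overall.n_meals
    tp_r, n_meals_r = len(restricted.true_positives), restricted.n_meals
    n_false, n_events = len(overall.false_events), overall.n_events

    tir_arr = np.array(subject_tir)
    report = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "global_seed": config.global_seed,
        "stage_seeds": seeds,
        "n_train_subjects": n_train,
        "n_test_subjects": n_test,
        "detection": {
            "n_unannounced_meals": n_meals,
            "n_alerts": n_events,
            "n_true_positives": tp,
            "sensitivity_pct": round(metrics.sensitivity(overall), 4)
                               if n_meals else None,
            "sensitivity_ci_pct": [round(x, 4) for x in
                                   metrics.clopper_pearson(tp, n_meals)]
                                  if n_meals else None,
            "sensitivity_40_80g_pct": round(metrics.sensitivity(restricted), 4)
                                      if n_meals_r else None,
            "sensitivity_40_80g_ci_pct": [round(x, 4) for x in
                                          metrics.clopper_pearson(tp_r, n_meals_r)]
                                         if n_meals_r else None,
            "n_meals_40_80g": n_meals_r,
            "fdr_pct": round(metrics.false_discovery_rate(overall), 4)
                       if n_events else None,
            "fdr_ci_pct": [round(x, 4) for x in
                           metrics.clopper_pearson(n_false, n_events)]
                          if n_events else None,
            "detection_time_mean_min": dt_mean,
            "detection_time_sd_min": dt_sd,
        },
        "glycemic": {
            "n_postprandial_windows": len(meal_summaries),
            "iauc_mean_mg_h_dl": round(float(np.mean([s.iauc for s in meal_summaries])), 4)
                                 if meal_summaries else None,
            "postprandial_tir_mean_pct": round(float(np.mean(
                [s.tir_pct for s in meal_summaries])), 4) if meal_summaries else None,
            "postprandial_tar_mean_pct": round(float(np.mean(
                [s.tar_pct for s in meal_summaries])), 4) if meal_summaries else None,
            "subject_tir_mean_pct": round(float(tir_arr[:, 0].mean()), 4),
            "subject_tar_mean_pct": round(float(tir_arr[:, 1].mean()), 4),
            "subject_tbr70_mean_pct": round(float(tir_arr[:, 2].mean()), 4),
            "subject_tbr54_mean_pct": round(float(tir_arr[:, 3].mean()), 4),
            "subject_lbgi_mean": round(float(np.mean(subject_lbgi)), 4),
            "subjects_lbgi_flagged": int(np.sum(
                np.array(subject_lbgi) >= metrics.LBGI_RISK_THRESHOLD)),
        },
    }
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
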