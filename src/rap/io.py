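"""CSV event-log formats and configuration serialization.

Each subject lives in its own directory holding three CSVs — ``cgm.csv``
(timestamp, glucose_mgdl), ``insulin.csv`` (timestamp, kind in
{basal, bolus}, value: U/h for basal segment starts, units for boluses)
and ``meals.csv`` (timestamp, grams, announced, is_rescue) — plus a
``scenario.json`` at the cohort root recording the full configuration and
seeds.  Timestamps are ISO-8601; internal times are minutes from the
scenario epoch.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .simulator import (CGM_CADENCE_MIN, CgmTrace, InsulinRecord, MealEvent,
                        ScenarioConfig)

EPOCH = datetime(2024, 1, 1)


def _to_timestamp(minutes: float) -> str:
    return (EPOCH + timedelta(minutes=float(minutes))).isoformat()


def _to_minutes(ts: str) -> float:
    return (datetime.fromisoformat(str(ts)) - EPOCH).total_seconds() / 60.0


def write_subject(directory: str | Path, cgm: CgmTrace, insulin: InsulinRecord,
                  meals: list[MealEvent]) -> Path:
    """Write one subject's event logs into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    pd.DataFrame({
        "timestamp": [_to_timestamp(t) for t in cgm.times],
        "glucose_mgdl": cgm.values,
    }).to_csv(directory / "cgm.csv", index=False)

    rows = [{"timestamp": _to_timestamp(start), "kind": "basal", "value": rate}
            for start, _, rate in insulin.basal_segments]
    rows += [{"timestamp": _to_timestamp(t), "kind": "bolus", "value": units}
             for t, units in insulin.boluses]
    rows.sort(key=lambda r: r["timestamp"])
    pd.DataFrame(rows, columns=["timestamp", "kind", "value"]).to_csv(
        directory / "insulin.csv", index=False)

    pd.DataFrame({
        "timestamp": [_to_timestamp(m.time) for m in meals],
        "grams": [m.grams for m in meals],
        "announced": [m.announced for m in meals],
        "is_rescue": [m.is_rescue for m in meals],
    }).to_csv(directory / "meals.csv", index=False)
    return directory


def read_event_logs(directory: str | Path,
                    ) -> tuple[CgmTrace, InsulinRecord, list[MealEvent]]:
    """Read one subject directory back into in-memory event logs.

    Rows are sorted by timestamp; the 5-min CGM cadence is validated and
    any gap reported with its interval.
    """
    directory = Path(directory)
    cgm_df = _read_csv(directory / "cgm.csv", ("timestamp", "glucose_mgdl"))
    cgm_df = cgm_df.sort_values("timestamp").reset_index(drop=True)
    times = np.array([_to_minutes(ts) for ts in cgm_df["timestamp"]])
    deltas = np.diff(times)
    bad = np.flatnonzero(np.abs(deltas - CGM_CADENCE_MIN) > 1e-6)
    if bad.size:
        i = int(bad[0])
        raise DataError(
            f"cgm.csv cadence violation: gap of {deltas[i]:g} min between "
            f"{cgm_df['timestamp'][i]} and {cgm_df['timestamp'][i + 1]} (row {i + 2})")
    cgm = CgmTrace(start_time=float(times[0]) if len(times) else 0.0,
                   values=cgm_df["glucose_mgdl"].to_numpy(dtype=float))

    ins_df = _read_csv(directory / "insulin.csv", ("timestamp", "kind", "value"))
    ins_df = ins_df.sort_values("timestamp").reset_index(drop=True)
    # the final CGM sample sits at the scenario horizon (samples 0..horizon)
    horizon = float(times[-1]) if len(times) else 0.0
    starts, rates, boluses = [], [], []
    for _, row in ins_df.iterrows():
        t = _to_minutes(row["timestamp"])
        if row["kind"] == "basal":
            starts.append(t)
            rates.append(float(row["value"]))
        elif row["kind"] == "bolus":
            boluses.append((t, float(row["value"])))
        else:
            raise DataError(f"insulin.csv: unknown kind {row['kind']!r}")
    segments = []
    for i, (start, rate) in enumerate(zip(starts, rates)):
        end = starts[i + 1] if i + 1 < len(starts) else max(horizon, start + CGM_CADENCE_MIN)
        segments.append((start, end, rate))
    insulin = InsulinRecord(basal_segments=tuple(segments), boluses=tuple(boluses))

    meals_df = _read_csv(directory / "meals.csv",
                         ("timestamp", "grams", "announced", "is_rescue"))
    meals_df = meals_df.sort_values("timestamp").reset_index(drop=True)
    meals = [MealEvent(time=_to_minutes(row["timestamp"]),
                       grams=float(row["grams"]),
                       announced=_as_bool(row["announced"]),
                       is_rescue=_as_bool(row["is_rescue"]))
             for _, row in meals_df.iterrows()]
    return cgm, insulin, meals


def _read_csv(path: Path, required: tuple[str, ...]) -> pd.DataFrame:
    if not path.exists():
        raise DataError(f"missing event log: {path}")
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DataError(f"{path.name}: missing columns {missing}")
    return df


def _as_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    return str(value).strip().lower() in ("true", "1", "yes")


def write_scenario(path: str | Path, config: ScenarioConfig, extra: dict | None = None) -> None:
    payload = {"scenario": dataclasses.asdict(config)}
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))


def read_scenario(path: str | Path) -> ScenarioConfig:
    payload = json.loads(Path(path).read_text())
    raw = payload["scenario"]
    raw["meal_hours"] = tuple(raw["meal_hours"])
    raw["meal_mean_sd"] = {k: tuple(v) for k, v in raw["meal_mean_sd"].items()}
    return ScenarioConfig(**raw)
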