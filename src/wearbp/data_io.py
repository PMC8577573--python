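"""Reading and writing the delimited-text table formats.

Three input tables describe one subject:

* wearable minutes — ``timestamp, heart_rate, steps, speed, floors``
* sleep sessions  — ``start, end, stage`` with stage in {light, rem, deep}
* blood pressure  — ``timestamp, sbp, dbp``

All files are comma-separated with dot decimals and ISO-8601 timestamps
(an explicit UTC offset is written; naive timestamps are accepted on read
and treated as UTC).  Missing numeric cells are empty strings on disk and
NaN in memory.  Internally all timestamps are timezone-naive (UTC clock).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger("wearbp")

SLEEP_STAGES = ("light", "rem", "deep")

MINUTE_COLUMNS = ["timestamp", "heart_rate", "steps", "speed", "floors"]
SLEEP_COLUMNS = ["start", "end", "stage"]
BP_COLUMNS = ["timestamp", "sbp", "dbp"]

MAX_HEART_RATE = 300.0


class ValidationError(ValueError):
    """Raised when an input table violates its column contract."""


@dataclass
class SubjectDataset:
    """One subject's raw data: minute stream, sleep sessions, BP readings.

    ``minutes`` has columns heart_rate/steps/speed/floors indexed by a unique,
    sorted DatetimeIndex; ``sleep`` has columns start/end/stage; ``bp`` has
    columns timestamp/sbp/dbp sorted by timestamp.
    """

    subject_id: str
    age: float
    minutes: pd.DataFrame
    sleep: pd.DataFrame
    bp: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def validate(self) -> "SubjectDataset":
        if not (18 <= self.age <= 120):
            raise ValidationError(f"age {self.age} outside [18, 120]")
        if len(self.bp) == 0:
            raise ValidationError("BP table is empty")
        _validate_bp(self.bp)
        _validate_sleep(self.sleep)
        _validate_minutes(self.minutes)
        return self

    def shift_time(self, delta: pd.Timedelta) -> "SubjectDataset":
        """Return a copy with every timestamp shifted by ``delta``."""
        minutes = self.minutes.copy()
        minutes.index = minutes.index + delta
        sleep = self.sleep.copy()
        sleep["start"] = sleep["start"] + delta
        sleep["end"] = sleep["end"] + delta
        bp = self.bp.copy()
        bp["timestamp"] = bp["timestamp"] + delta
        return replace(self, minutes=minutes, sleep=sleep, bp=bp)


def _parse_times(values, name: str) -> pd.DatetimeIndex:
    ts = pd.to_datetime(values, utc=True, format="ISO8601")
    if ts.isna().any():
        bad = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise ValidationError(f"{name}: unparseable timestamp at row {bad}")
    return pd.DatetimeIndex(ts).tz_convert("UTC").tz_localize(None)


def _validate_minutes(minutes: pd.DataFrame) -> None:
    if not minutes.index.is_unique:
        raise ValidationError("duplicate minute timestamps after dedup")
    if not minutes.index.is_monotonic_increasing:
        raise ValidationError("minute stream not sorted")
    hr = minutes["heart_rate"]
    if (hr >= MAX_HEART_RATE).any():
        raise ValidationError("heart_rate >= 300 beats/min")
    for col in ("heart_rate", "steps", "speed", "floors"):
        if (minutes[col] < 0).any():
            raise ValidationError(f"negative values in {col}")


def _validate_sleep(sleep: pd.DataFrame) -> None:
    if len(sleep) == 0:
        return
    if (sleep["end"] <= sleep["start"]).any():
        bad = sleep.index[(sleep["end"] <= sleep["start"])][0]
        raise ValidationError(f"sleep session {bad}: end <= start")
    unknown = set(sleep["stage"]) - set(SLEEP_STAGES)
    if unknown:
        raise ValidationError(f"unknown sleep stages {sorted(unknown)}")


def _validate_bp(bp: pd.DataFrame) -> None:
    bad = bp.index[~(bp["sbp"] > bp["dbp"])]
    if len(bad):
        raise ValidationError(f"BP row {bad[0]}: requires sbp > dbp > 0")
    if (bp["dbp"] <= 0).any():
        raise ValidationError("non-positive dbp")


def load_minutes(path) -> pd.DataFrame:
    raw = pd.read_csv(path)
    _require_columns(raw, MINUTE_COLUMNS, "wearable")
    # wearable exports are messy: malformed rows are counted, not fatal
    ts = pd.to_datetime(raw["timestamp"], utc=True, format="ISO8601", errors="coerce")
    bad = ts.isna()
    if bad.any():
        logger.warning("wearable: skipped %d rows with malformed timestamps", int(bad.sum()))
        raw = raw[~bad]
        ts = ts[~bad]
    df = raw.drop(columns=["timestamp"]).apply(pd.to_numeric, errors="coerce")
    n_coerced = int((df.notna().sum() - raw.drop(columns=["timestamp"]).notna().sum()).abs().sum())
    if n_coerced:
        logger.warning("wearable: %d non-numeric cells treated as missing", n_coerced)
    df.index = pd.DatetimeIndex(ts).tz_convert("UTC").tz_localize(None)
    df.index.name = "timestamp"
    df = df.sort_index()
    ndup = int(df.index.duplicated(keep="last").sum())
    if ndup:
        # later sync overwrites earlier partial records
        logger.info("wearable: collapsed %d duplicate timestamps (kept last)", ndup)
        df = df[~df.index.duplicated(keep="last")]
    return df


def load_sleep(path) -> pd.DataFrame:
    raw = pd.read_csv(path)
    _require_columns(raw, SLEEP_COLUMNS, "sleep")
    df = pd.DataFrame(
        {
            "start": _parse_times(raw["start"], "sleep.start"),
            "end": _parse_times(raw["end"], "sleep.end"),
            "stage": raw["stage"].astype(str).str.strip().str.lower(),
        }
    )
    return df.sort_values("start", kind="stable").reset_index(drop=True)


def load_bp(path) -> pd.DataFrame:
    raw = pd.read_csv(path)
    _require_columns(raw, BP_COLUMNS, "bp")
    if len(raw) == 0:
        raise ValidationError(f"BP file {path} is empty")
    df = pd.DataFrame(
        {
            "timestamp": _parse_times(raw["timestamp"], "bp"),
            "sbp": raw["sbp"].astype(float),
            "dbp": raw["dbp"].astype(float),
        }
    )
    return df.sort_values("timestamp", kind="stable").reset_index(drop=True)


def _require_columns(df: pd.DataFrame, cols, name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{name} table missing columns {missing}")


def load_subject_dataset(
    wearable_path, sleep_path, bp_path, age: float, subject_id: str = "subject"
) -> SubjectDataset:
    """Load one subject's three tables and validate the result.

    Rows are sorted ascending in time; duplicate wearable timestamps keep
    the last occurrence.
    """
    ds = SubjectDataset(
        subject_id=subject_id,
        age=float(age),
        minutes=load_minutes(wearable_path),
        sleep=load_sleep(sleep_path),
        bp=load_bp(bp_path),
    )
    return ds.validate()


def write_subject_dataset(ds: SubjectDataset, wearable_path, sleep_path, bp_path) -> None:
    minutes = ds.minutes.copy()
    minutes.insert(0, "timestamp", _format_times(minutes.index))
    minutes.to_csv(wearable_path, index=False)
    sleep = pd.DataFrame(
        {
            "start": _format_times(pd.DatetimeIndex(ds.sleep["start"])),
            "end": _format_times(pd.DatetimeIndex(ds.sleep["end"])),
            "stage": ds.sleep["stage"].to_numpy(),
        }
    )
    sleep.to_csv(sleep_path, index=False)
    bp = ds.bp.copy()
    bp["timestamp"] = _format_times(pd.DatetimeIndex(bp["timestamp"]))
    bp.to_csv(bp_path, index=False)


def _format_times(idx: pd.DatetimeIndex):
    return idx.tz_localize("UTC").strftime("%Y-%m-%dT%H:%M:%S%z")


# ---------------------------------------------------------------------------
# Feature-table artifact


def write_feature_table(table, path) -> None:
    """Serialize a FeatureTable; missing cells become empty strings."""
    if len(table.df) == 0:
        raise ValidationError("refusing to write an empty feature table")
    df = table.df.copy()
    df.insert(0, "timestamp", _format_times(pd.DatetimeIndex(df.pop("timestamp"))))
    df.insert(0, "subject_id", table.subject_id)
    df.to_csv(path, index=False)


def read_feature_table(path):
    from .features import FeatureTable  # local import: avoid cycle

    raw = pd.read_csv(path)
    subject_id = str(raw["subject_id"].iloc[0]) if len(raw) else "subject"
    df = raw.drop(columns=["subject_id"])
    df["timestamp"] = _parse_times(df["timestamp"], "feature table")
    feature_names = [c for c in df.columns if c not in ("timestamp", "sbp", "dbp")]
    return FeatureTable(subject_id=subject_id, df=df, feature_names=feature_names)
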