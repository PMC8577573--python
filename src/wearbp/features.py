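"""Lifestyle feature engineering from minute-level wearable streams.

For every blood-pressure reading, lifestyle activity and sleep are summarized
over the 24/48/72 hours preceding the (possibly horizon-shifted) window end,
plus a 1-hour heart-rate summary and the clock time of measurement:

* ``steps_24`` is the total step count in the previous 24 h; ``steps_48`` /
  ``steps_72`` are the *average daily* totals over the previous 48/72 h.
  Floors and the three active-level minute counts follow the same
  sum-then-daily-average rule.
* Heart rate and walking/running speed are averaged over recorded minutes;
  ``maxHR_w`` is the window maximum.
* Per-minute activity is discretized into sedentary / lightly active / very
  active from steps and the age-predicted heart-rate zones
  (HRmax = 220 - age, zone boundaries at 0.5/0.7/1.0 x HRmax).
* Sleep duration (total and per stage), bedtime, wake-up time and sleeping
  heart rate come from sleep sessions intersecting the window.

Windows are half-open ``(end - w, end]``.  Bedtime is reported on a shifted
clock (12:00 -> 36:00) so 23:30 and 00:30 are numerically adjacent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import SubjectDataset, ValidationError

logger = logging.getLogger("wearbp")

WINDOWS = (24, 48, 72)
VALID_HORIZONS = (0, 12, 24, 48)

#: feature families summarized at each of the 24/48/72-hour windows,
#: in canonical order (ties in importance rankings break toward the left).
WINDOW_FAMILIES = (
    "steps",
    "sedentary",
    "lightly_active",
    "very_active",
    "floors",
    "speed",
    "heart_rate",
    "maxHR",
    "sleep",
    "light_sleep",
    "rem_sleep",
    "deep_sleep",
    "bed_time",
    "up_time",
    "slpHR",
)

ARIMA_FEATURES = ("SBP_arima", "DBP_arima")

#: default completeness thresholds: a window summary is missing when fewer
#: than this fraction of the window's minutes carry the needed channel.
MIN_COVERAGE = {"hr": 0.5, "speed": 0.5, "steps": 0.25, "floors": 0.25}

_NS_PER_MIN = 60_000_000_000


def canonical_feature_names(include_arima: bool = False) -> list[str]:
    names = [f"{fam}_{w}" for w in WINDOWS for fam in WINDOW_FAMILIES]
    names += ["heart_rate_1", "measure_time"]
    if include_arima:
        names += list(ARIMA_FEATURES)
    return names


def compute_hr_max(age: float) -> float:
    """Age-predicted maximum heart rate, 220 - age (beats/min)."""
    if not 18 <= age <= 120:
        raise ValidationError(f"age {age} outside [18, 120]")
    return 220.0 - float(age)


@dataclass(frozen=True)
class HRZones:
    """Heart-rate zones with upper bounds at 0.5, 0.7 and 1.0 x HRmax."""

    hr_max: float

    @property
    def boundaries(self) -> tuple[float, float, float]:
        return (0.5 * self.hr_max, 0.7 * self.hr_max, self.hr_max)

    @classmethod
    def from_age(cls, age: float) -> "HRZones":
        return cls(hr_max=compute_hr_max(age))


def assign_hr_zone(hr, zones: HRZones):
    """Zone 1: hr <= 0.5 HRmax; zone 2: <= 0.7 HRmax; zone 3 above."""
    hr = np.asarray(hr, dtype=float)
    zone = np.where(hr <= 0.5 * zones.hr_max, 1, np.where(hr <= 0.7 * zones.hr_max, 2, 3))
    return zone if zone.ndim else int(zone)


def classify_active_level(steps, hr, zones: HRZones):
    """Per-minute activity level from steps and HR zone.

    sedentary: steps < 10 or zone 1 (a missing HR also counts as sedentary);
    lightly active: steps >= 10 and zone 2; very active: steps >= 10 and zone 3.
    Returns 0/1/2 codes for sedentary/lightly/very.
    """
    steps = np.asarray(steps, dtype=float)
    hr = np.asarray(hr, dtype=float)
    zone = np.where(np.isnan(hr), 1, assign_hr_zone(np.where(np.isnan(hr), 1.0, hr), zones))
    level = np.where((steps < 10) | (zone == 1), 0, np.where(zone == 2, 1, 2))
    return level if level.ndim else int(level)


@dataclass
class FeatureTable:
    """One row per retained BP reading: engineered features plus targets."""

    subject_id: str
    df: pd.DataFrame  # columns: timestamp, <features...>, sbp, dbp
    feature_names: list[str]
    missing_mask: pd.DataFrame | None = None  # pre-imputation missingness
    n_dropped: int = 0
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def X(self) -> pd.DataFrame:
        return self.df[self.feature_names]

    def y(self, target: str) -> pd.Series:
        if target not in ("sbp", "dbp"):
            raise ValidationError(f"unknown target {target!r}")
        return self.df[target]

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            subject_id=self.subject_id,
            df=self.df.copy(),
            feature_names=list(self.feature_names),
            missing_mask=None if self.missing_mask is None else self.missing_mask.copy(),
            n_dropped=self.n_dropped,
            meta=dict(self.meta),
        )

    def subset(self, idx) -> "FeatureTable":
        out = self.copy()
        out.df = out.df.iloc[idx].reset_index(drop=True)
        if out.missing_mask is not None:
            out.missing_mask = out.missing_mask.iloc[idx].reset_index(drop=True)
        return out

    def with_columns(self, **cols) -> "FeatureTable":
        """Return a copy with extra feature columns attached (e.g. ARIMA)."""
        out = self.copy()
        for name, values in cols.items():
            out.df[name] = np.asarray(values, dtype=float)
            if name not in out.feature_names:
                out.feature_names.append(name)
        return out


def impute_median(table: FeatureTable, medians: pd.Series | None = None) -> FeatureTable:
    """Fill missing feature cells with per-feature medians.

    ``medians`` lets a caller impute held-out rows with medians computed on
    training rows only (no test leakage); by default the table's own medians
    are used.  The pre-imputation missingness mask is kept on the result.
    """
    out = table.copy()
    if out.missing_mask is None:
        out.missing_mask = out.df[out.feature_names].isna()
    if medians is None:
        medians = out.df[out.feature_names].median()
    out.df[out.feature_names] = out.df[out.feature_names].fillna(medians)
    return out


# ---------------------------------------------------------------------------
# Window machinery


class _SubjectContext:
    """Minute-grid prefix sums and sleep intervals for O(1) window queries."""

    def __init__(self, dataset: SubjectDataset):
        minutes = dataset.minutes
        if len(minutes) == 0:
            raise ValidationError("empty minute stream")
        self.zones = HRZones.from_age(dataset.age)

        idx = minutes.index.floor("min")
        t0 = idx.min()
        t1 = idx.max()
        n = int((t1 - t0) // pd.Timedelta(minutes=1)) + 1
        self.grid_start_ns = t0.value
        self.n = n

        pos = ((idx.asi8 - self.grid_start_ns) // _NS_PER_MIN).astype(np.int64)

        def channel(col):
            arr = np.full(n, np.nan)
            arr[pos] = minutes[col].to_numpy(dtype=float)
            return arr

        hr = channel("heart_rate")
        steps = channel("steps")
        speed = channel("speed")
        floors = channel("floors")

        level = classify_active_level(np.where(np.isnan(steps), 0.0, steps), hr, self.zones)
        has_row = np.zeros(n, dtype=bool)
        has_row[pos] = True

        self.hr = hr
        self.hr_ok = ~np.isnan(hr)
        steps_ok = has_row & ~np.isnan(steps)
        floors_ok = has_row & ~np.isnan(floors)
        speed_ok = ~np.isnan(speed)

        def cum(x):
            out = np.zeros(n + 1)
            np.cumsum(x, out=out[1:])
            return out

        self.c_steps = cum(np.where(steps_ok, steps, 0.0))
        self.c_floors = cum(np.where(floors_ok, floors, 0.0))
        self.c_hr_sum = cum(np.where(self.hr_ok, hr, 0.0))
        self.c_hr_cnt = cum(self.hr_ok)
        self.c_speed_sum = cum(np.where(speed_ok, speed, 0.0))
        self.c_speed_cnt = cum(speed_ok)
        self.c_steps_cnt = cum(steps_ok)
        self.c_floors_cnt = cum(floors_ok)
        self.c_row_cnt = cum(has_row)
        # active levels only count minutes with a step record
        self.c_level = [cum(steps_ok & (level == code)) for code in (0, 1, 2)]

        # sleep sessions -> per-stage intervals + grouped sleep periods
        sleep = dataset.sleep
        self.s_start = sleep["start"].to_numpy(dtype="datetime64[ns]").astype(np.int64)
        self.s_end = sleep["end"].to_numpy(dtype="datetime64[ns]").astype(np.int64)
        self.s_stage = sleep["stage"].to_numpy()
        self._build_periods()

        asleep = np.zeros(n, dtype=bool)
        for s, e in zip(self.s_start, self.s_end):
            a = max(0, int(np.ceil((s - self.grid_start_ns) / _NS_PER_MIN)))
            b = min(n, int(np.ceil((e - self.grid_start_ns) / _NS_PER_MIN)))
            if b > a:
                asleep[a:b] = True
        self.c_slp_hr_sum = cum(np.where(asleep & self.hr_ok, hr, 0.0))
        self.c_slp_hr_cnt = cum(asleep & self.hr_ok)

    def _build_periods(self):
        """Group abutting sessions (gap <= 60 min) into whole-night periods."""
        starts, ends = [], []
        order = np.argsort(self.s_start, kind="stable")
        for i in order:
            s, e = self.s_start[i], self.s_end[i]
            if starts and s - ends[-1] <= 60 * _NS_PER_MIN:
                ends[-1] = max(ends[-1], e)
            else:
                starts.append(s)
                ends.append(e)
        self.p_start = np.array(starts, dtype=np.int64)
        self.p_end = np.array(ends, dtype=np.int64)

    # -- window primitives ---------------------------------------------------

    def _idx(self, t_ns: int) -> int:
        """Number of grid minutes with timestamp <= t."""
        k = (t_ns - self.grid_start_ns) // _NS_PER_MIN + 1
        return int(min(max(k, 0), self.n))

    def _span(self, t0_ns: int, t1_ns: int) -> tuple[int, int]:
        return self._idx(t0_ns), self._idx(t1_ns)

    def sleep_overlap_hours(self, t0_ns: int, t1_ns: int, stage: str | None = None):
        if stage is None:
            s, e = self.p_start, self.p_end
        else:
            keep = self.s_stage == stage
            s, e = self.s_start[keep], self.s_end[keep]
        if len(s) == 0:
            return 0.0
        ov = np.minimum(e, t1_ns) - np.maximum(s, t0_ns)
        return float(np.maximum(ov, 0).sum()) / 3.6e12

    def bed_up_times(self, t0_ns: int, t1_ns: int):
        """Mean bedtime (shifted clock) and wake time of main sleeps ending
        in the window, one per night (the longest when several end the same
        day)."""
        inside = (self.p_end > t0_ns) & (self.p_end <= t1_ns)
        if not inside.any():
            return np.nan, np.nan
        s, e = self.p_start[inside], self.p_end[inside]
        day = e // (1440 * _NS_PER_MIN)
        beds, ups = [], []
        for d in np.unique(day):
            sel = day == d
            j = np.argmax((e - s)[sel])  # main sleep = longest that night
            beds.append(_clock_hours(s[sel][j], shifted=True))
            ups.append(_clock_hours(e[sel][j], shifted=False))
        return float(np.mean(beds)), float(np.mean(ups))

    def window_features(self, end_ns: int, w_hours: int) -> dict[str, float]:
        t0 = end_ns - w_hours * 60 * _NS_PER_MIN
        a, b = self._span(t0, end_ns)
        nmin = w_hours * 60
        days = w_hours / 24.0
        out: dict[str, float] = {}

        def total(c):
            return c[b] - c[a]

        steps_cov = total(self.c_steps_cnt) / nmin
        hr_cov = total(self.c_hr_cnt) / nmin
        # speed exists only while moving; gate it on overall wear coverage
        speed_cov = total(self.c_row_cnt) / nmin
        floors_cov = total(self.c_floors_cnt) / nmin

        out["steps"] = total(self.c_steps) / days if steps_cov >= MIN_COVERAGE["steps"] else np.nan
        out["floors"] = (
            total(self.c_floors) / days if floors_cov >= MIN_COVERAGE["floors"] else np.nan
        )
        for code, fam in enumerate(("sedentary", "lightly_active", "very_active")):
            out[fam] = (
                total(self.c_level[code]) / days
                if steps_cov >= MIN_COVERAGE["steps"]
                else np.nan
            )
        out["heart_rate"] = (
            total(self.c_hr_sum) / total(self.c_hr_cnt)
            if hr_cov >= MIN_COVERAGE["hr"]
            else np.nan
        )
        out["speed"] = (
            total(self.c_speed_sum) / total(self.c_speed_cnt)
            if speed_cov >= MIN_COVERAGE["speed"] and total(self.c_speed_cnt) > 0
            else np.nan
        )
        if hr_cov >= MIN_COVERAGE["hr"] and b > a:
            seg = self.hr[a:b]
            out["maxHR"] = np.nanmax(seg) if self.hr_ok[a:b].any() else np.nan
        else:
            out["maxHR"] = np.nan

        # sleep summaries: daily averages for 48/72-h windows, like steps
        first_sleep = self.p_start[0] if len(self.p_start) else None
        if first_sleep is None or t0 < first_sleep - 12 * 60 * _NS_PER_MIN and w_hours > 24:
            for fam in ("sleep", "light_sleep", "rem_sleep", "deep_sleep"):
                out[fam] = np.nan
        else:
            out["sleep"] = self.sleep_overlap_hours(t0, end_ns) / days
            for stage in ("light", "rem", "deep"):
                out[f"{stage}_sleep"] = self.sleep_overlap_hours(t0, end_ns, stage) / days
        bed, up = self.bed_up_times(t0, end_ns)
        out["bed_time"], out["up_time"] = bed, up
        n_slp = total(self.c_slp_hr_cnt)
        out["slpHR"] = total(self.c_slp_hr_sum) / n_slp if n_slp >= 30 else np.nan
        return out

    def hour_mean_hr(self, end_ns: int) -> float:
        a, b = self._span(end_ns - 60 * _NS_PER_MIN, end_ns)
        cnt = self.c_hr_cnt[b] - self.c_hr_cnt[a]
        if cnt / 60.0 < MIN_COVERAGE["hr"]:
            return np.nan
        return (self.c_hr_sum[b] - self.c_hr_sum[a]) / cnt

    def steps_coverage(self, end_ns: int, w_hours: int = 24) -> float:
        a, b = self._span(end_ns - w_hours * 60 * _NS_PER_MIN, end_ns)
        return (self.c_steps_cnt[b] - self.c_steps_cnt[a]) / (w_hours * 60)


def _clock_hours(t_ns: int, shifted: bool = False) -> float:
    h = (t_ns % (1440 * _NS_PER_MIN)) / (60 * _NS_PER_MIN)
    if shifted and h < 12:
        h += 24.0
    return h


def extract_window_features(
    dataset: SubjectDataset,
    t_end: pd.Timestamp,
    horizon_shift: float = 0.0,
    context: "_SubjectContext | None" = None,
) -> dict[str, float]:
    """Feature row (targets unfilled) for a reading at ``t_end``.

    ``horizon_shift`` moves the window end back by that many hours, so the
    model predicts h hours ahead of its freshest lifestyle data.
    """
    ctx = context or _SubjectContext(dataset)
    end_ns = int(pd.Timestamp(t_end).value) - int(horizon_shift * 3600e9)
    row: dict[str, float] = {}
    for w in WINDOWS:
        for fam, val in ctx.window_features(end_ns, w).items():
            row[f"{fam}_{w}"] = val
    row["heart_rate_1"] = ctx.hour_mean_hr(end_ns)
    row["measure_time"] = _clock_hours(int(pd.Timestamp(t_end).value))
    return row


def dedup_bp(bp: pd.DataFrame, policy: str = "mean", session_hours: float = 2.0) -> pd.DataFrame:
    """Collapse redundant same-session readings (gap <= ``session_hours``).

    ``mean`` averages timestamps and values; ``first`` keeps the earliest;
    ``none`` keeps everything.
    """
    if policy == "none" or len(bp) <= 1:
        return bp.reset_index(drop=True)
    t = bp["timestamp"].to_numpy(dtype="datetime64[ns]").astype(np.int64)
    gap = np.diff(t) > session_hours * 3.6e12
    group = np.concatenate([[0], np.cumsum(gap)])
    if policy == "first":
        keep = np.concatenate([[True], gap])
        return bp[keep].reset_index(drop=True)
    if policy != "mean":
        raise ValidationError(f"unknown dedup policy {policy!r}")
    g = bp.copy()
    g["_t"] = t
    agg = g.groupby(group).agg({"_t": "mean", "sbp": "mean", "dbp": "mean"})
    return pd.DataFrame(
        {
            "timestamp": pd.to_datetime(agg["_t"].round().astype(np.int64)),
            "sbp": agg["sbp"].to_numpy(),
            "dbp": agg["dbp"].to_numpy(),
        }
    )


def build_feature_table(
    dataset: SubjectDataset,
    horizon_shift: float = 0.0,
    dedup_policy: str = "mean",
    impute: bool = True,
) -> FeatureTable:
    """One row per retained BP reading, features from the shifted windows.

    Readings whose shifted 24-h window lacks the minimum step coverage are
    dropped and counted in ``n_dropped``.  Missing features are imputed with
    subject-level medians unless ``impute=False`` (cross-validation imputes
    per training fold instead); the missingness mask is retained either way.
    """
    if horizon_shift not in VALID_HORIZONS:
        raise ValidationError(f"horizon_shift must be one of {VALID_HORIZONS}")
    if len(dataset.bp) == 0:
        raise ValidationError("dataset has no BP readings")
    ctx = _SubjectContext(dataset)
    bp = dedup_bp(dataset.bp, dedup_policy)

    rows, targets, times = [], [], []
    n_dropped = 0
    for _, reading in bp.iterrows():
        t = pd.Timestamp(reading["timestamp"])
        end_ns = int(t.value) - int(horizon_shift * 3600e9)
        if ctx.steps_coverage(end_ns) < MIN_COVERAGE["steps"]:
            n_dropped += 1
            continue
        rows.append(extract_window_features(dataset, t, horizon_shift, context=ctx))
        targets.append((reading["sbp"], reading["dbp"]))
        times.append(t)
    if not rows:
        raise ValidationError(
            f"all {len(bp)} readings dropped: insufficient wearable coverage "
            f"at horizon {horizon_shift}h"
        )
    if n_dropped:
        logger.info("dropped %d readings with insufficient look-back", n_dropped)

    names = canonical_feature_names()
    df = pd.DataFrame(rows, columns=names)
    df.insert(0, "timestamp", pd.DatetimeIndex(times))
    df["sbp"] = [t[0] for t in targets]
    df["dbp"] = [t[1] for t in targets]
    table = FeatureTable(
        subject_id=dataset.subject_id,
        df=df.reset_index(drop=True),
        feature_names=names,
        missing_mask=df[names].isna().reset_index(drop=True),
        n_dropped=n_dropped,
    )
    return impute_median(table) if impute else table
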