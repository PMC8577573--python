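"""Synthetic wearable + blood-pressure cohorts with planted lifestyle effects.

The generator emulates the measurement regime of a home-monitoring study:
minute-level wearable channels (heart rate, steps, walking speed, floors)
with circadian structure and Poisson-seeded walking bouts, nightly sleep
sessions staged light/REM/deep, and twice-daily BP readings (~08:30 and
~19:30) with clock jitter and random missingness.

Blood pressure is generated as

    BP_j = base + sum_e coef_e * z_e(j) + r_j,     r_j = ar * r_{j-1} + eps_j

where ``z_e(j)`` is the *realized* lifestyle feature at reading j — computed
with the same window rules the features module applies — standardized by the
generator's own fixed scale constants (not sample statistics), and ``eps`` is
Gaussian with sd ``noise_sd`` (ar = 0 gives i.i.d. noise).  Ground truth
therefore states exactly which features carry signal and with what sign,
which makes feature-selection and recommendation pipelines testable end to
end without any clinical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data_io import SubjectDataset, ValidationError
from .features import _SubjectContext, extract_window_features

_MIN = 1440  # minutes per day


@dataclass(frozen=True)
class EffectSpec:
    """A planted linear lifestyle effect on BP.

    ``coefficient`` is in mmHg per standardized unit of the named feature;
    ``applies_to`` selects the target ('sbp', 'dbp' or 'both').
    """

    feature_name: str
    coefficient: float
    applies_to: str = "sbp"

    def targets(self) -> tuple[str, ...]:
        if self.applies_to == "both":
            return ("sbp", "dbp")
        if self.applies_to not in ("sbp", "dbp"):
            raise ValidationError(f"applies_to must be sbp/dbp/both, got {self.applies_to!r}")
        return (self.applies_to,)


@dataclass(frozen=True)
class SimProfile:
    """Study-condition parameters for one simulated subject."""

    age: float = 55.0
    days: int = 90
    bp_base_sbp: float = 128.0
    bp_base_dbp: float = 82.0
    ar_coefficient: float = 0.3
    noise_sd: float = 4.0
    effects: tuple[EffectSpec, ...] = ()
    missing_bp_rate: float = 0.05
    bp_time_jitter_sd: float = 20.0  # minutes
    wearable_dropout_rate: float = 0.02  # per minute
    # daily-structure parameters (means / sds of the latent day variables)
    steps_day_mean: float = 7000.0
    steps_day_rel_sd: float = 0.35
    bedtime_mean: float = 23.0  # shifted clock hours
    bedtime_sd: float = 0.7
    sleep_hours_mean: float = 7.3
    sleep_hours_sd: float = 0.6
    hr_rest: float = 62.0
    hr_day_offset_sd: float = 3.0

    def validate(self) -> "SimProfile":
        if self.days < 7:
            raise ValidationError("profile.days must be >= 7")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if not abs(self.ar_coefficient) < 1:
            raise ValidationError("|ar_coefficient| must be < 1")
        for p in (self.missing_bp_rate, self.wearable_dropout_rate):
            if not 0 <= p <= 1:
                raise ValidationError("rates must lie in [0, 1]")
        for eff in self.effects:
            if not np.isfinite(eff.coefficient):
                raise ValidationError("effect coefficient must be finite")
            eff.targets()
        return self


@dataclass
class GroundTruth:
    """What the generator actually planted, for downstream verification."""

    profile: SimProfile
    generative_means: pd.DataFrame  # per-reading sbp/dbp means (pre AR/noise)
    scale_constants: dict = field(default_factory=dict)  # feature -> (mu, sd)
    top_features: list = field(default_factory=list)  # ranked by |coefficient|

    def effect_sign(self, feature_name: str, target: str = "sbp") -> float:
        for eff in self.profile.effects:
            if eff.feature_name == feature_name and target in eff.targets():
                return float(np.sign(eff.coefficient))
        return 0.0


def _scale_constants(profile: SimProfile) -> dict[str, tuple[float, float]]:
    """Analytic (mu, sd) per feature family, fixed by the profile's design
    parameters so ground truth is independent of the realized sample."""
    mu_sleep_hr = profile.hr_rest - 5.0
    base: dict[str, tuple[float, float]] = {
        "steps": (profile.steps_day_mean, profile.steps_day_mean * profile.steps_day_rel_sd),
        "floors": (8.0, 4.0),
        "sedentary": (820.0, 60.0),
        "lightly_active": (45.0, 25.0),
        "very_active": (25.0, 18.0),
        "speed": (4.8, 0.7),
        "heart_rate": (profile.hr_rest + 6.0, profile.hr_day_offset_sd),
        "maxHR": (150.0, 15.0),
        "sleep": (profile.sleep_hours_mean, profile.sleep_hours_sd),
        "light_sleep": (profile.sleep_hours_mean * 0.55, profile.sleep_hours_sd * 0.55),
        "rem_sleep": (profile.sleep_hours_mean * 0.25, profile.sleep_hours_sd * 0.35),
        "deep_sleep": (profile.sleep_hours_mean * 0.20, profile.sleep_hours_sd * 0.35),
        "bed_time": (profile.bedtime_mean, profile.bedtime_sd),
        "up_time": (
            (profile.bedtime_mean % 24) + profile.sleep_hours_mean,
            np.hypot(profile.bedtime_sd, profile.sleep_hours_sd),
        ),
        "slpHR": (mu_sleep_hr, profile.hr_day_offset_sd),
    }
    out: dict[str, tuple[float, float]] = {}
    for w in (24, 48, 72):
        shrink = np.sqrt(w / 24.0)  # daily averages have smaller sd
        for fam, (mu, sd) in base.items():
            out[f"{fam}_{w}"] = (mu, sd / shrink)
    out["heart_rate_1"] = (profile.hr_rest + 4.0, profile.hr_day_offset_sd + 2.0)
    out["measure_time"] = (14.0, 5.5)
    return out


def simulate_subject(
    profile: SimProfile, seed: int, subject_id: str = "sim"
) -> tuple[SubjectDataset, GroundTruth]:
    """Simulate one subject; identical (profile, seed) gives identical output."""
    profile.validate()
    rng = np.random.default_rng(seed)
    days = profile.days

    # --- latent day variables -------------------------------------------
    step_mult = np.maximum(rng.normal(1.0, profile.steps_day_rel_sd, days), 0.1)
    bedtime = rng.normal(profile.bedtime_mean, profile.bedtime_sd, days + 1)  # night d
    sleep_hours = np.maximum(rng.normal(profile.sleep_hours_mean, profile.sleep_hours_sd, days + 1), 3.0)
    hr_offset = rng.normal(0.0, profile.hr_day_offset_sd, days + 1)

    origin = pd.Timestamp("2024-01-01 00:00:00")
    n = days * _MIN
    tod = (np.arange(n) % _MIN) / 60.0  # clock hours per minute
    day_ix = np.arange(n) // _MIN

    # --- sleep sessions (night d-1 .. days-1; bedtime on shifted clock) --
    sessions = []
    for d in range(-1, days):
        # bedtime is on the shifted clock: 24.5 means 00:30 the next day
        start = (origin + pd.Timedelta(hours=d * 24 + bedtime[d + 1])).floor("min")
        sessions.extend(_stage_sessions(start, sleep_hours[d + 1], rng))
    sleep_df = pd.DataFrame(sessions, columns=["start", "end", "stage"]).sort_values(
        "start", kind="stable"
    ).reset_index(drop=True)
    asleep = np.zeros(n, dtype=bool)
    for s, e in zip(sleep_df["start"], sleep_df["end"]):
        a = max(int((s - origin).total_seconds() // 60), 0)
        b = min(max(int(np.ceil((e - origin).total_seconds() / 60)), 0), n)
        if b > a:
            asleep[a:b] = True

    # --- steps / speed: Poisson walking bouts during waking hours --------
    steps = np.zeros(n)
    speed = np.full(n, np.nan)
    for d in range(days):
        n_bouts = max(rng.poisson(8), 1)
        budget = profile.steps_day_mean * step_mult[d]
        weights = rng.dirichlet(np.ones(n_bouts) * 2.0)
        for k in range(n_bouts):
            start_min = d * _MIN + int(rng.uniform(7.0, 21.5) * 60)
            dur = max(int(rng.normal(15, 5)), 4)
            bout_speed = float(np.clip(rng.normal(4.8, 0.7), 2.5, 8.0))
            sl = slice(start_min, min(start_min + dur, (d + 1) * _MIN))
            m = max(sl.stop - sl.start, 1)
            steps[sl] += (budget * 0.75) * weights[k] / m
            speed[sl] = bout_speed
        # ambient background movement over the waking day
        wake = (day_ix == d) & ~asleep & (tod > 6.5) & (tod < 22.5)
        steps[wake] += (budget * 0.25) / max(wake.sum(), 1)
    steps[asleep] = 0.0  # no steps while asleep
    speed[asleep] = np.nan
    steps = np.round(steps)

    # --- heart rate: circadian baseline + activity coupling --------------
    hr = (
        profile.hr_rest
        + 6.0 * np.sin((tod - 9.0) / 24.0 * 2 * np.pi)
        + hr_offset[day_ix + 1]
        + rng.normal(0, 2.0, n)
    )
    hr[asleep] -= 7.0
    active = ~np.isnan(speed)
    hr_max = 220.0 - profile.age
    # bout HR rises into zones 2/3 proportionally to walking speed
    hr[active] = np.maximum(hr[active], 0.5 * hr_max + (speed[active] - 2.0) * 0.085 * hr_max)
    hr = np.clip(hr, 40, hr_max - 1)

    floors = np.zeros(n)
    idx_f = rng.choice(np.flatnonzero(~asleep & (tod > 7) & (tod < 22)), size=days * 8)
    np.add.at(floors, idx_f, 1.0)

    minutes = pd.DataFrame(
        {
            "heart_rate": np.round(hr, 1),
            "steps": steps,
            "speed": np.round(speed, 2),
            "floors": floors,
        },
        index=origin + pd.to_timedelta(np.arange(n), unit="min"),
    )
    minutes.index.name = "timestamp"
    if profile.wearable_dropout_rate > 0:
        keep = rng.random(n) >= profile.wearable_dropout_rate
        minutes = minutes[keep]

    # --- BP reading times -------------------------------------------------
    times = []
    for d in range(days):
        for clock in (8.5, 19.5):
            if rng.random() < profile.missing_bp_rate:
                continue
            jitter = rng.normal(0, profile.bp_time_jitter_sd)
            t = origin + pd.Timedelta(days=d, hours=clock, minutes=round(jitter))
            times.append(t.floor("min"))
    times = sorted(set(times))
    if not times:
        raise ValidationError("all BP readings thinned out; lower missing_bp_rate")

    # --- BP values: planted effects on realized features ------------------
    dataset = SubjectDataset(
        subject_id=subject_id,
        age=profile.age,
        minutes=minutes,
        sleep=sleep_df,
        bp=pd.DataFrame({"timestamp": times, "sbp": 0.0, "dbp": 0.0}),
    )
    scale = _scale_constants(profile)
    ctx = _SubjectContext(dataset)
    means = {"sbp": [], "dbp": []}
    for t in times:
        row = extract_window_features(dataset, t, 0.0, context=ctx)
        mean = {"sbp": profile.bp_base_sbp, "dbp": profile.bp_base_dbp}
        for eff in profile.effects:
            mu, sd = scale[eff.feature_name]
            v = row.get(eff.feature_name, np.nan)
            z = 0.0 if not np.isfinite(v) or sd == 0 else (v - mu) / sd
            for tgt in eff.targets():
                mean[tgt] += eff.coefficient * z
        means["sbp"].append(mean["sbp"])
        means["dbp"].append(mean["dbp"])

    J = len(times)
    bp_vals = {}
    for tgt in ("sbp", "dbp"):
        resid = np.zeros(J)
        eps = rng.normal(0, profile.noise_sd, J) if profile.noise_sd > 0 else np.zeros(J)
        for j in range(J):
            resid[j] = profile.ar_coefficient * (resid[j - 1] if j else 0.0) + eps[j]
        bp_vals[tgt] = np.asarray(means[tgt]) + resid
    # keep readings physiologically ordered (sbp > dbp); values stay at full
    # precision so exact-recovery checks of the planted model are possible
    bp_vals["dbp"] = np.minimum(bp_vals["dbp"], bp_vals["sbp"] - 1.0)
    dataset.bp["sbp"] = bp_vals["sbp"]
    dataset.bp["dbp"] = bp_vals["dbp"]

    truth = GroundTruth(
        profile=profile,
        generative_means=pd.DataFrame(
            {"timestamp": times, "sbp": means["sbp"], "dbp": means["dbp"]}
        ),
        scale_constants=scale,
        top_features=sorted(
            {e.feature_name for e in profile.effects},
            key=lambda f: -max(abs(e.coefficient) for e in profile.effects if e.feature_name == f),
        ),
    )
    return dataset.validate(), truth


def _stage_sessions(start: pd.Timestamp, dur_hours: float, rng) -> list[tuple]:
    """Partition one night into ~90-min cycles of light/deep/light/REM."""
    out = []
    t = start
    remaining = dur_hours * 60.0
    while remaining > 1:
        cycle = min(remaining, rng.normal(90, 8))
        fr = np.maximum(rng.normal([0.40, 0.22, 0.18, 0.20], 0.03), 0.05)
        fr = fr / fr.sum()
        for stage, f in zip(("light", "deep", "light", "rem"), fr):
            mins = max(round(cycle * f), 1)
            end = t + pd.Timedelta(minutes=mins)
            out.append((t, end, stage))
            t = end
        remaining -= cycle
    return out


def simulate_cohort(
    n_subjects: int,
    profile_template: SimProfile,
    seed: int,
    effect_jitter: float = 0.0,
) -> list[tuple[SubjectDataset, GroundTruth]]:
    """Simulate ``n_subjects`` subjects with deterministically derived seeds.

    ``effect_jitter`` > 0 perturbs each subject's effect coefficients with a
    relative Gaussian factor, creating inter-individual heterogeneity in the
    planted lifestyle->BP dependencies.
    """
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    profile_template.validate()
    out = []
    master = np.random.default_rng(seed)
    for i in range(n_subjects):
        sub_seed = int(master.integers(0, 2**31 - 1))
        profile = profile_template
        if effect_jitter > 0 and profile.effects:
            jit = np.random.default_rng(sub_seed + 1)
            effects = tuple(
                replace(e, coefficient=e.coefficient * float(jit.normal(1.0, effect_jitter)))
                for e in profile.effects
            )
            profile = replace(profile, effects=effects)
        out.append(simulate_subject(profile, sub_seed, subject_id=f"S{i + 1:02d}"))
    return out
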