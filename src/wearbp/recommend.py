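"""Personalized lifestyle recommendations from Shapley importance.

Only factors a subject can deliberately change are eligible: measurement
time, every heart-rate summary and the BP time-series forecast features are
excluded even when they rank highest.  Window variants of one factor
(steps_24/steps_48/steps_72) collapse into a single base factor whose
importance is the maximum over its windows, so one lifestyle factor is
never recommended three times.  The direction of effect comes from the
association between a feature's values and its per-sample Shapley values:
a clearly negative correlation means higher values lower predicted BP
("increase"), clearly positive means "decrease", and a weak or
non-monotone association yields "regularize".
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ValidationError
from .evaluation import TrendSlope, bp_trend_slope, weekly_bp_stats
from .features import FeatureTable
from .rfsv import TrainedRFSV

logger = logging.getLogger("wearbp")

#: factors the subject cannot deliberately change
NON_ACTIONABLE_PREFIXES = ("heart_rate", "maxHR", "slpHR")
NON_ACTIONABLE_EXACT = ("measure_time", "SBP_arima", "DBP_arima")

_WINDOW_SUFFIX = re.compile(r"^(?P<base>.+)_(?:1|24|48|72)$")

#: association threshold |r| below which the effect is called non-monotone
DIRECTION_THRESHOLD = 0.2


def actionable_filter(features: list[str]) -> list[str]:
    """Drop non-actionable feature names, preserving order."""
    out = []
    for name in features:
        if name in NON_ACTIONABLE_EXACT or name.startswith(NON_ACTIONABLE_PREFIXES):
            continue
        out.append(name)
    return out


def collapse_time_windows(feature_name: str) -> str:
    """steps_24 -> steps; bed_time_48 -> bed_time; idempotent."""
    m = _WINDOW_SUFFIX.match(feature_name)
    if m:
        return m.group("base")
    if feature_name not in NON_ACTIONABLE_EXACT and "_" not in feature_name:
        return feature_name
    if not m:
        logger.info("no window suffix recognized in %r; returned unchanged", feature_name)
    return feature_name


@dataclass(frozen=True)
class Recommendation:
    rank: int
    base_factor: str
    source_features: tuple[str, ...]
    direction: str  # increase | decrease | regularize
    mean_abs_shap: float  # mmHg
    evidence: dict
    target: str


@dataclass
class SubjectReport:
    subject_id: str
    target: str
    bp_summary: dict  # average / minimum / maximum over the period
    recommendations: list[Recommendation]
    trend: TrendSlope | None = None
    weekly: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def effect_direction(
    report, table: FeatureTable, feature: str, threshold: float = DIRECTION_THRESHOLD
) -> tuple[str, float]:
    """Direction from Pearson r between feature values and its phi column.

    r <= -threshold: higher values lower predicted BP -> "increase";
    r >= +threshold -> "decrease"; otherwise -> "regularize".
    Returns (direction, r).
    """
    if report.values is None:
        raise ValidationError("effect direction needs per-sample Shapley values")
    k = report.feature_names.index(feature)
    x = table.df[feature].to_numpy(dtype=float)
    if getattr(report, "sample_rows", None) is not None:
        x = x[report.sample_rows]
    phi = report.values[:, k]
    if len(x) != len(phi):
        raise ValidationError("table rows do not match the Shapley matrix")
    ok = np.isfinite(x)
    if x[ok].std() == 0 or phi[ok].std() == 0:
        return "regularize", 0.0
    r = float(np.corrcoef(x[ok], phi[ok])[0, 1])
    if r <= -threshold:
        return "increase", r
    if r >= threshold:
        return "decrease", r
    return "regularize", r


def generate_recommendations(
    rfsv: TrainedRFSV,
    table: FeatureTable,
    top_n: int = 3,
    threshold: float = DIRECTION_THRESHOLD,
) -> SubjectReport:
    """Top actionable lifestyle factors by mean |phi|, with directions."""
    report = rfsv.importance
    if report.method != "shap" or report.values is None:
        raise ValidationError("recommendations require SHAP importance with per-sample values")

    flags: list[str] = []
    actionable = actionable_filter(report.ranking())
    families: dict[str, dict] = {}
    for name in actionable:
        base = collapse_time_windows(name)
        fam = families.setdefault(base, {"features": [], "importance": 0.0, "top": name})
        fam["features"].append(name)
        imp = float(report.mean_abs[name])
        if imp > fam["importance"]:
            fam["importance"] = imp
            fam["top"] = name

    ranked = sorted(families.items(), key=lambda kv: -kv[1]["importance"])
    if len(ranked) < top_n:
        flags.append(f"only {len(ranked)} actionable factor families available")
    recs = []
    for rank, (base, fam) in enumerate(ranked[:top_n], start=1):
        direction, r = effect_direction(report, table, fam["top"], threshold)
        recs.append(
            Recommendation(
                rank=rank,
                base_factor=base,
                source_features=tuple(fam["features"]),
                direction=direction,
                mean_abs_shap=fam["importance"],
                evidence={"value_shap_r": r, "top_feature": fam["top"]},
                target=rfsv.target,
            )
        )

    y = table.y(rfsv.target)
    readings = table.df[["timestamp", "sbp", "dbp"]]
    return SubjectReport(
        subject_id=table.subject_id,
        target=rfsv.target,
        bp_summary={
            "average": float(y.mean()),
            "minimum": float(y.min()),
            "maximum": float(y.max()),
        },
        recommendations=recs,
        trend=bp_trend_slope(readings, target=rfsv.target) if len(readings) >= 2 else None,
        weekly=weekly_bp_stats(readings, target=rfsv.target),
        flags=flags,
    )


def format_report(report: SubjectReport) -> str:
    lines = [
        f"Subject {report.subject_id} — target {report.target.upper()}",
        (
            f"BP over period: average {report.bp_summary['average']:.1f}, "
            f"min {report.bp_summary['minimum']:.1f}, max {report.bp_summary['maximum']:.1f} mmHg"
        ),
    ]
    if report.trend is not None:
        lines.append(f"Trend slope: {report.trend.slope:+.3f} mmHg/day")
    for rec in report.recommendations:
        lines.append(
            f"  {rec.rank}. {rec.base_factor}: {rec.direction} "
            f"(mean |SHAP| {rec.mean_abs_shap:.2f} mmHg, r={rec.evidence['value_shap_r']:+.2f})"
        )
    for flag in report.flags:
        lines.append(f"  note: {flag}")
    return "\n".join(lines)
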