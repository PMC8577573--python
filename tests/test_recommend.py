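import numpy as np
import pandas as pd
import pytest

from wearbp.data_io import ValidationError
from wearbp.features import FeatureTable
from wearbp.recommend import (
    actionable_filter,
    collapse_time_windows,
    effect_direction,
    format_report,
    generate_recommendations,
)
from wearbp.rfsv import ImportanceReport, RFParams, train_rfsv

from conftest import make_profile
from wearbp.features import build_feature_table
from wearbp.synthetic_data import simulate_subject


def test_actionable_filter_rules():
    assert actionable_filter(["heart_rate_1", "speed_24", "steps_72"]) == [
        "speed_24",
        "steps_72",
    ]
    assert actionable_filter(["SBP_arima", "measure_time"]) == []
    assert actionable_filter(["sleep_24"]) == ["sleep_24"]
    assert actionable_filter(["maxHR_48", "slpHR_24", "DBP_arima", "bed_time_24"]) == [
        "bed_time_24"
    ]


@pytest.mark.parametrize(
    "name,base",
    [
        ("steps_24", "steps"),
        ("steps_48", "steps"),
        ("deep_sleep_72", "deep_sleep"),
        ("bed_time_48", "bed_time"),
        ("heart_rate_1", "heart_rate"),
        ("steps", "steps"),  # idempotent
    ],
)
def test_collapse_time_windows(name, base):
    assert collapse_time_windows(name) == base
    assert collapse_time_windows(collapse_time_windows(name)) == base


def synthetic_report(phi_fn, n=100, seed=0):
    """Report + table where phi(feature) is a chosen function of its value."""
    rng = np.random.default_rng(seed)
    x = rng.normal(5.0, 2.0, n)
    noise = rng.normal(size=n)
    phi = np.column_stack([phi_fn(x), noise * 0.1])
    names = ["speed_24", "steps_24"]
    df = pd.DataFrame({"timestamp": pd.date_range("2024-01-01", periods=n, freq="12h")})
    df["speed_24"] = x
    df["steps_24"] = rng.normal(size=n)
    df["sbp"] = 120.0
    df["dbp"] = 80.0
    table = FeatureTable("t", df, names)
    report = ImportanceReport(
        feature_names=names,
        mean_abs=pd.Series(np.abs(phi).mean(0), index=names),
        method="shap",
        values=phi,
        baseline=120.0,
    )
    return report, table


def test_direction_negative_association_means_increase():
    """phi = -2 * (x - mean): higher values lower predicted BP."""
    report, table = synthetic_report(lambda x: -2.0 * (x - x.mean()))
    direction, r = effect_direction(report, table, "speed_24")
    assert direction == "increase"
    assert r == pytest.approx(-1.0)


def test_direction_positive_association_means_decrease():
    report, table = synthetic_report(lambda x: 1.5 * (x - x.mean()))
    direction, r = effect_direction(report, table, "speed_24")
    assert direction == "decrease"
    assert r == pytest.approx(1.0)


def test_direction_null_association_regularizes():
    """phi shuffled against values: the regularize rate matches the null
    distribution of Pearson r at n=100 (about 95% below |r| = 0.2)."""
    from scipy import stats

    n, n_seeds = 100, 80
    regularized = 0
    for seed in range(n_seeds):
        rng = np.random.default_rng(seed)
        report, table = synthetic_report(
            lambda x: rng.permutation(2.0 * (x - x.mean())), n=n, seed=seed
        )
        direction, _ = effect_direction(report, table, "speed_24")
        regularized += direction == "regularize"
    # under independence r*sqrt(n-2)/sqrt(1-r^2) ~ t(n-2)
    t_crit = 0.2 * np.sqrt(n - 2) / np.sqrt(1 - 0.2**2)
    p_null = 2 * stats.t.cdf(t_crit, df=n - 2) - 1
    rate = regularized / n_seeds
    assert rate >= 0.85
    assert abs(rate - p_null) <= 3 * np.sqrt(p_null * (1 - p_null) / n_seeds)


def test_direction_zero_variance_regularizes():
    report, table = synthetic_report(lambda x: -2.0 * (x - x.mean()))
    table.df["speed_24"] = 4.0
    direction, r = effect_direction(report, table, "speed_24")
    assert direction == "regularize" and r == 0.0


def fitted_rfsv(seed=0, **profile_kw):
    ds, truth = simulate_subject(make_profile(days=60, **profile_kw), seed)
    table = build_feature_table(ds)
    model = train_rfsv(
        table, "sbp", RFParams(n_trees=150, seed=seed), background_size=48, max_explained=96
    )
    return model, table, truth


def test_recommendations_skip_non_actionable_top_feature():
    """heart_rate_1 carries planted signal but is never recommended; the
    actionable causal families surface with correct directions."""
    model, table, _ = fitted_rfsv(seed=2)
    report = generate_recommendations(model, table, top_n=3)
    factors = [r.base_factor for r in report.recommendations]
    assert "heart_rate" not in factors
    assert "measure_time" not in factors
    by_factor = {r.base_factor: r for r in report.recommendations}
    assert by_factor["steps"].direction == "increase"  # planted coefficient -5
    assert by_factor["bed_time"].direction == "decrease"  # planted +4
    assert [r.rank for r in report.recommendations] == [1, 2, 3]


def test_report_summary_matches_training_readings():
    model, table, _ = fitted_rfsv(seed=3)
    report = generate_recommendations(model, table)
    y = table.df["sbp"]
    assert report.bp_summary["average"] == pytest.approx(y.mean())
    assert report.bp_summary["minimum"] == pytest.approx(y.min())
    assert report.bp_summary["maximum"] == pytest.approx(y.max())
    text = format_report(report)
    assert "steps" in text and "Trend slope" in text


def test_recommendations_deterministic():
    model, table, _ = fitted_rfsv(seed=4)
    a = generate_recommendations(model, table)
    b = generate_recommendations(model, table)
    assert a.recommendations == b.recommendations


def test_families_collapse_to_distinct_factors():
    model, table, _ = fitted_rfsv(seed=5)
    report = generate_recommendations(model, table, top_n=3)
    factors = [r.base_factor for r in report.recommendations]
    assert len(factors) == len(set(factors))
    for rec in report.recommendations:
        bases = {collapse_time_windows(f) for f in rec.source_features}
        assert bases == {rec.base_factor}


def test_all_features_excluded_flags_empty_report():
    names = ["heart_rate_1", "measure_time", "SBP_arima"]
    phi = np.zeros((10, 3))
    df = pd.DataFrame(
        {"timestamp": pd.date_range("2024-01-01", periods=10, freq="12h")}
    )
    for n in names:
        df[n] = 1.0
    df["sbp"], df["dbp"] = 120.0, 80.0
    table = FeatureTable("t", df, names)
    report = ImportanceReport(
        feature_names=names,
        mean_abs=pd.Series([1.0, 0.5, 0.2], index=names),
        method="shap",
        values=phi,
        baseline=120.0,
    )

    class Stub:
        importance = report
        target = "sbp"

    out = generate_recommendations(Stub(), table)
    assert out.recommendations == []
    assert out.flags


def test_alt_importance_rejected_for_recommendations():
    model, table, _ = fitted_rfsv(seed=6)
    from dataclasses import replace

    class Stub:
        importance = replace(model.importance, method="pearson", values=None)
        target = "sbp"

    with pytest.raises(ValidationError):
        generate_recommendations(Stub(), table)
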