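import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wearbp.data_io import ValidationError
from wearbp.evaluation import (
    ArimaOptions,
    bp_trend_slope,
    compare_models,
    compute_metrics,
    cross_validate,
    make_folds,
    paired_ttest,
    weekly_bp_stats,
)
from wearbp.features import build_feature_table
from wearbp.rfsv import RFParams
from wearbp.synthetic_data import EffectSpec, simulate_subject

from conftest import make_profile


def independent_metrics(pred, act):
    """The printed formulas, re-coded from scratch for cross-checking."""
    n = len(act)
    mae = sum(abs(p - a) for p, a in zip(pred, act)) / n
    rmse = (sum((p - a) ** 2 for p, a in zip(pred, act)) / n) ** 0.5
    mape = n * mae / sum(abs(a) for a in act) * 100.0
    ybar = sum(act) / n
    r2 = 1 - sum((p - a) ** 2 for p, a in zip(pred, act)) / sum((a - ybar) ** 2 for a in act)
    return mae, rmse, mape, r2


def test_perfect_prediction():
    m = compute_metrics([120.0, 130.0], [120.0, 130.0])
    assert (m.mae, m.rmse, m.mape) == (0.0, 0.0, 0.0)
    assert m.r2 == 1.0


def test_worked_example():
    """predicted [121,119] vs actual [120,120]: MAE 1, RMSE 1, MAPE 5/6 %."""
    m = compute_metrics([121.0, 119.0], [120.0, 120.0])
    assert m.mae == pytest.approx(1.0)
    assert m.rmse == pytest.approx(1.0)
    assert m.mape == pytest.approx(2 * 1.0 / 240.0 * 100.0)  # 0.8333%


def test_metrics_match_independent_formulas():
    rng = np.random.default_rng(0)
    for _ in range(5):
        act = rng.uniform(90, 160, 100)
        pred = act + rng.normal(0, 5, 100)
        m = compute_metrics(pred, act)
        mae, rmse, mape, r2 = independent_metrics(pred, act)
        assert m.mae == pytest.approx(mae, abs=1e-10)
        assert m.rmse == pytest.approx(rmse, abs=1e-10)
        assert m.mape == pytest.approx(mape, abs=1e-10)
        assert m.r2 == pytest.approx(r2, abs=1e-10)


def test_mae_never_exceeds_rmse():
    rng = np.random.default_rng(1)
    for _ in range(20):
        act = rng.uniform(80, 180, 50)
        pred = act + rng.standard_t(3, 50) * rng.uniform(0.5, 8)
        m = compute_metrics(pred, act)
        assert m.mae <= m.rmse + 1e-12
    # equality iff all absolute errors are equal
    m = compute_metrics([121.0, 119.0], [120.0, 120.0])
    assert m.mae == pytest.approx(m.rmse)


def test_metrics_validation():
    with pytest.raises(ValidationError):
        compute_metrics([1.0, 2.0], [1.0])
    m = compute_metrics([1.0, -1.0], [0.0, 0.0])
    assert np.isnan(m.mape)  # sum |actual| = 0 flagged as undefined


def test_paired_ttest_matches_t_distribution():
    """p-value equals the closed-form evaluation of the t CDF."""
    rng = np.random.default_rng(2)
    d = rng.normal(0.5, 1.0, 50)
    a = np.abs(rng.normal(5, 1, 50))
    res = paired_ttest(a + d, a)
    t_stat = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
    p = 2 * stats.t.sf(abs(t_stat), df=len(d) - 1)
    assert res.statistic == pytest.approx(t_stat, abs=1e-10)
    assert res.p_value == pytest.approx(p, abs=1e-10)


def test_paired_ttest_degenerate_cases():
    a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    same = paired_ttest(a, a)
    assert same.p_value == 1.0 and not same.degenerate
    shifted = paired_ttest(a + 1.0, a)  # constant nonzero difference
    assert shifted.degenerate and shifted.p_value == 0.0


def test_trend_slope_exact_line():
    ts = pd.Timestamp("2024-01-01") + pd.to_timedelta(np.arange(60) * 12, unit="h")
    readings = pd.DataFrame(
        {"timestamp": ts, "sbp": 120.0 + 0.5 * np.arange(60) * 0.5, "dbp": 80.0}
    )
    trend = bp_trend_slope(readings, target="sbp")
    assert trend.slope == pytest.approx(0.5)  # +0.25 per reading = 0.5/day
    assert trend.intercept == pytest.approx(120.0)
    flat = bp_trend_slope(readings, target="dbp")
    assert flat.slope == pytest.approx(0.0)


def test_trend_slope_recovers_generating_slope():
    """Noisy decreasing series: slope within 3 SE of the true -0.3/day."""
    rng = np.random.default_rng(3)
    days = np.arange(60) * 0.5
    ts = pd.Timestamp("2024-01-01") + pd.to_timedelta(days, unit="D")
    y = 130.0 - 0.3 * days + rng.normal(0, 3, 60)
    readings = pd.DataFrame({"timestamp": ts, "sbp": y, "dbp": 80.0})
    fit = stats.linregress(days, y)
    trend = bp_trend_slope(readings, target="sbp")
    assert trend.slope == pytest.approx(fit.slope)
    assert abs(trend.slope - (-0.3)) <= 3 * fit.stderr


def test_weekly_stats_constant_series():
    ts = pd.Timestamp("2024-01-01") + pd.to_timedelta(np.arange(56) * 12, unit="h")
    readings = pd.DataFrame({"timestamp": ts, "sbp": 125.0, "dbp": 80.0})
    w = weekly_bp_stats(readings, "sbp")
    assert w["first_week"]["mean"] == w["first_week"]["max"] == 125.0
    assert w["last_week"]["mean"] == 125.0


def make_table(days=30, seed=0, **profile_kw):
    ds, _ = simulate_subject(make_profile(days=days, **profile_kw), seed)
    return build_feature_table(ds, impute=False)


def test_simple_mean_cv_identities():
    table = make_table(days=20, noise_sd=0.0, ar_coefficient=0.0, effects=())
    res = cross_validate(table, model="simple_mean", target="sbp", k=5, repeats=1, seed=0)
    assert res.metrics.mae == pytest.approx(0.0)  # constant target

    # two-level target 100/140, 10 rows each: held-out MAE is the in-sample
    # half-spread (20) inflated by n/(n - fold size) because the training
    # mean shrinks away from the held-out class -> bounded by 20 * 20/16
    table2 = table.subset(np.arange(20))
    table2.df["sbp"] = np.where(np.arange(20) < 10, 100.0, 140.0)
    res2 = cross_validate(table2, model="simple_mean", target="sbp", k=5, repeats=1, seed=0)
    assert 0.0 < res2.metrics.mae <= 25.0


def test_cv_deterministic_given_seed():
    table = make_table(days=25, seed=4)
    a = cross_validate(table, "rf", "sbp", k=5, repeats=1, seed=3, params=RFParams(30, seed=0))
    b = cross_validate(table, "rf", "sbp", k=5, repeats=1, seed=3, params=RFParams(30, seed=0))
    assert np.array_equal(a.predictions, b.predictions)
    assert a.metrics == b.metrics


def test_loo_reduction():
    """k = n with one repeat is leave-one-out: every row predicted once."""
    table = make_table(days=15, seed=5)
    n = len(table)
    res = cross_validate(table, "simple_mean", "sbp", k=n, repeats=1, seed=0)
    assert res.metrics.n == n
    assert sorted(res.row_index.tolist()) == list(range(n))


def test_rfsv_beats_simple_mean_on_planted_effects(study_table):
    """Planted lifestyle signal: RFSV held-out MAE < SimpleMean MAE."""
    res_rfsv = cross_validate(
        study_table, "rfsv", "sbp", k=5, repeats=1, seed=1,
        params=RFParams(n_trees=150, seed=0), background_size=40, max_explained=60,
        arima_opts=ArimaOptions(max_p=1, max_q=1),
    )
    res_mean = cross_validate(study_table, "simple_mean", "sbp", k=5, repeats=1, seed=1)
    assert res_rfsv.metrics.mae < res_mean.metrics.mae


def test_fold_consistency_across_models():
    """compare_models evaluates every model on identical fold assignments."""
    ds, _ = simulate_subject(make_profile(days=25), 6)
    cmp = compare_models(
        ds, targets=("sbp",), models=("simple_mean", "rf"), horizons=(0,),
        seed=2, k=5, repeats=2, params=RFParams(n_trees=30, seed=0),
    )
    ra = cmp.results[("simple_mean", "sbp", 0)]
    rb = cmp.results[("rf", "sbp", 0)]
    for fa, fb in zip(ra.fold_assignments, rb.fold_assignments):
        assert np.array_equal(fa, fb)
    assert np.array_equal(ra.row_index, rb.row_index)


def test_arima_beats_rf_when_only_dynamics(tmp_path):
    """Strong AR(1) BP with no lifestyle effects: the one-step forecast
    model wins against lifestyle-only RF."""
    ds, _ = simulate_subject(
        make_profile(days=60, noise_sd=2.0, ar_coefficient=0.85, effects=()), 17
    )
    cmp = compare_models(
        ds, targets=("sbp",), models=("arima", "rf"), horizons=(0,),
        seed=0, k=5, repeats=1, params=RFParams(n_trees=100, seed=0),
        arima_opts=ArimaOptions(max_p=1, max_q=1, max_d=1),
    )
    t = cmp.table.set_index("model")
    assert t.loc["arima", "mae"] < t.loc["rf", "mae"]


def test_degenerate_cohort_all_models_zero_error():
    """No noise, no AR, no effects: every model predicts the constant."""
    ds, _ = simulate_subject(
        make_profile(days=20, noise_sd=0.0, ar_coefficient=0.0, effects=()), 8
    )
    cmp = compare_models(
        ds, targets=("sbp",), models=("simple_mean", "arima", "rf"), horizons=(0,),
        seed=0, k=5, repeats=1, params=RFParams(n_trees=20, seed=0),
        arima_opts=ArimaOptions(max_p=1, max_q=1, max_d=1),
    )
    assert (cmp.table["mae"] < 1e-6).all()


def test_make_folds_balanced():
    rng = np.random.default_rng(0)
    ids = make_folds(23, 5, rng)
    counts = np.bincount(ids, minlength=5)
    assert counts.min() >= 4 and counts.max() <= 5


def test_chronological_folds_are_contiguous_blocks():
    ids = make_folds(23, 5, np.random.default_rng(0), chronological=True)
    assert (np.diff(ids) >= 0).all()  # non-decreasing: contiguous in time
    assert np.bincount(ids, minlength=5).min() >= 4
    table = make_table(days=20, seed=7)
    res = cross_validate(table, "simple_mean", "sbp", k=5, repeats=1, seed=0,
                         chronological=True)
    assert (np.diff(res.fold_assignments[0]) >= 0).all()
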