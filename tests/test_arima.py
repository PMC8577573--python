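import numpy as np
import pandas as pd
import pytest

from wearbp.arima_features import (
    ArimaModelSpec,
    arima_one_step_forecasts,
    fit_best_arima,
    one_step_predictions,
    resample_bp_series,
)
from wearbp.data_io import ValidationError


def readings_from(times_h, values):
    ts = pd.Timestamp("2024-01-01") + pd.to_timedelta(times_h, unit="h")
    return pd.DataFrame({"timestamp": ts, "sbp": values, "dbp": np.asarray(values) - 40.0})


def make_spec(order, params, trend="n", period=2, **kw):
    defaults = dict(
        seasonal_order=(0, 0, 0, period),
        delta=0.0,
        ar_coefs=np.array([]),
        ma_coefs=np.array([]),
        sigma2=1.0,
        score=0.0,
    )
    defaults.update(kw)
    return ArimaModelSpec(order=order, trend=trend, params=np.asarray(params, float), **defaults)


def test_linear_midpoint_interpolation():
    """Grid point halfway between 120 and 130 reads 125."""
    series = resample_bp_series(readings_from([0.0, 10.0], [120.0, 130.0]), "sbp", 5.0)
    assert series.values == pytest.approx([120.0, 125.0, 130.0])


def test_interpolation_through_knots():
    """Readings exactly on the grid come back unchanged, mask all false."""
    series = resample_bp_series(
        readings_from([0, 12, 24, 36], [120.0, 126.0, 118.0, 124.0]), "sbp", 12.0
    )
    assert series.values == pytest.approx([120.0, 126.0, 118.0, 124.0])
    assert not series.interpolated_mask.any()


def test_piecewise_linear_oracle():
    """Each grid value equals the direct two-point interpolation formula."""
    t = np.array([0.0, 7.0, 26.0])
    v = np.array([118.0, 131.0, 122.0])
    series = resample_bp_series(readings_from(t, v), "sbp", 6.0)
    for k, g in enumerate(series.times_hours()):
        i = np.searchsorted(t, g, side="right") - 1
        i = min(i, len(t) - 2)
        expect = v[i] + (v[i + 1] - v[i]) * (g - t[i]) / (t[i + 1] - t[i])
        assert series.values[k] == pytest.approx(expect, abs=1e-9)
    # no extrapolation past the last reading
    assert series.times_hours()[-1] <= t[-1]


def test_interpolation_bounded_by_bracketing_readings():
    rng = np.random.default_rng(0)
    t = np.sort(rng.uniform(0, 200, 40))
    v = rng.uniform(100, 160, 40)
    series = resample_bp_series(readings_from(t, v), "sbp", 12.0)
    assert series.values.min() >= v.min() - 1e-12
    assert series.values.max() <= v.max() + 1e-12


def test_too_few_readings_rejected():
    with pytest.raises(ValidationError):
        resample_bp_series(readings_from([0.0], [120.0]), "sbp", 12.0)


def test_white_noise_selects_empty_orders():
    """On zero-mean white noise the criterion picks (0,0,0): every candidate
    with extra parameters scores a worse AICc."""
    rng = np.random.default_rng(3)
    series = resample_bp_series(
        readings_from(np.arange(200) * 12.0, 120 + rng.normal(0, 3, 200)), "sbp", 12.0
    )
    spec = fit_best_arima(series, max_p=1, max_q=1, max_d=1, seasonal=False)
    assert spec.order == (0, 0, 0)


def test_random_walk_selects_differencing():
    """y_t = y_{t-1} + eps needs d >= 1; the criterion must prefer it."""
    rng = np.random.default_rng(4)
    walk = 120 + np.cumsum(rng.normal(0, 2, 250))
    series = resample_bp_series(readings_from(np.arange(250) * 12.0, walk), "sbp", 12.0)
    spec = fit_best_arima(series, max_p=1, max_q=1, max_d=1, seasonal=False)
    assert spec.order[1] >= 1


def test_constant_series_degenerate_fit():
    series = resample_bp_series(
        readings_from(np.arange(20) * 12.0, np.full(20, 121.0)), "sbp", 12.0
    )
    spec = fit_best_arima(series)
    assert spec.order == (0, 1, 0)
    assert spec.sigma2 == 0.0
    pred = one_step_predictions(spec, series.values)
    assert pred[1:] == pytest.approx(121.0)


def test_random_walk_forecast_is_last_value():
    """(0,1,0) with delta=0: the one-step forecast repeats the last grid
    value before the reading."""
    vals = np.array([120.0, 118.0, 123.0, 119.0, 118.0])
    readings = readings_from(np.arange(5) * 12.0 + 3.0, vals)  # off-grid times
    series = resample_bp_series(readings_from(np.arange(5) * 12.0, vals), "sbp", 12.0)
    spec = make_spec((0, 1, 0), [4.0], sigma2=4.0)
    fc = arima_one_step_forecasts(spec, series, readings)
    # reading at grid_time + 3h: last grid value strictly before it
    assert fc == pytest.approx([120.0, 118.0, 123.0, 119.0, 118.0])


def test_ar1_closed_form_forecast():
    """(1,0,0) with alpha=0.5: forecast = mean + 0.5 * (last - mean)."""
    mean = 120.0
    vals = np.array([120.0, 124.0, 118.0, 130.0, 120.0, 116.0, 124.0, 120.0])
    series = resample_bp_series(readings_from(np.arange(8) * 12.0, vals), "sbp", 12.0)
    # statsmodels 'c' trend parameter is the intercept delta = mean*(1-alpha)
    spec = make_spec((1, 0, 0), [mean * 0.5, 0.5, 1.0], trend="c",
                     ar_coefs=np.array([0.5]), delta=mean * 0.5)
    pred = one_step_predictions(spec, series.values)
    expect = mean + 0.5 * (vals[:-1] - mean)
    assert pred[1:-1] == pytest.approx(expect, abs=1e-8)


def test_first_reading_has_no_forecast():
    vals = np.array([120.0, 122.0, 119.0, 125.0])
    readings = readings_from(np.arange(4) * 12.0, vals)
    series = resample_bp_series(readings, "sbp", 12.0)
    spec = make_spec((0, 1, 0), [1.0])
    fc = arima_one_step_forecasts(spec, series, readings)
    assert np.isnan(fc[0])
    assert not np.isnan(fc[1:]).any()


def test_ar1_one_step_mse_near_innovation_variance():
    """Selected model's one-step MSE approaches sigma^2 on AR(1) data."""
    rng = np.random.default_rng(8)
    n, alpha, sigma = 300, 0.8, 2.0
    y = np.zeros(n)
    for i in range(1, n):
        y[i] = alpha * y[i - 1] + rng.normal(0, sigma)
    readings = readings_from(np.arange(n) * 12.0, 125 + y)
    series = resample_bp_series(readings, "sbp", 12.0)
    spec = fit_best_arima(series, max_p=2, max_q=2, max_d=1, seasonal=False)
    fc = arima_one_step_forecasts(spec, series, readings)
    mse = np.nanmean((fc[1:] - readings["sbp"].to_numpy()[1:]) ** 2)
    innovation_mse = np.mean((y[1:] - alpha * y[:-1]) ** 2)  # realized irreducible error
    assert mse == pytest.approx(innovation_mse, rel=0.10)
    assert mse == pytest.approx(sigma**2, rel=0.20)


def test_shift_equivariance_of_forecasts():
    """Adding a constant to the series shifts forecasts by that constant."""
    rng = np.random.default_rng(9)
    y = 120 + np.cumsum(rng.normal(0, 1.5, 80))
    r1 = readings_from(np.arange(80) * 12.0, y)
    r2 = readings_from(np.arange(80) * 12.0, y + 50.0)
    s1 = resample_bp_series(r1, "sbp", 12.0)
    s2 = resample_bp_series(r2, "sbp", 12.0)
    spec1 = fit_best_arima(s1, max_p=1, max_q=1, max_d=1, seasonal=False)
    spec2 = fit_best_arima(s2, max_p=1, max_q=1, max_d=1, seasonal=False)
    assert spec1.order == spec2.order
    f1 = arima_one_step_forecasts(spec1, s1, r1)
    f2 = arima_one_step_forecasts(spec2, s2, r2)
    assert np.nanmax(np.abs((f2 - f1) - 50.0)) < 0.15


def test_beats_simple_mean_on_ar1():
    """One-step ARIMA beats the training-mean forecast on persistent AR(1)."""
    wins = 0
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        n = 200
        y = np.zeros(n)
        for i in range(1, n):
            y[i] = 0.7 * y[i - 1] + rng.normal(0, 2)
        readings = readings_from(np.arange(n) * 12.0, 125 + y)
        series = resample_bp_series(readings, "sbp", 12.0)
        spec = fit_best_arima(series, max_p=1, max_q=1, max_d=1, seasonal=False)
        fc = arima_one_step_forecasts(spec, series, readings)
        actual = readings["sbp"].to_numpy()
        mse_arima = np.nanmean((fc[1:] - actual[1:]) ** 2)
        mse_mean = np.mean((actual.mean() - actual[1:]) ** 2)
        wins += mse_arima < mse_mean
    assert wins >= 10 * 0.95
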