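"""SARIMA one-step-forecast features from irregular blood-pressure series.

Home BP readings are unevenly spaced, while ARIMA-family models need an
evenly spaced series.  Each subject's SBP/DBP series is therefore resampled
onto a regular grid (default spacing 12 h, matching the two-readings-a-day
protocol) by linear interpolation between the closest readings before and
after each grid point, without extrapolation.  An exhaustive search over
(p, d, q) — and seasonal (P, D, Q) with a one-day period — picks the model
with the lowest information criterion (AICc by default).  The fitted model's
one-step-ahead forecasts, conditioned only on grid history strictly before
each reading, become the features ``SBP_arima`` and ``DBP_arima``; the
resampled series itself is never used as a prediction target.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from statsmodels.tsa.statespace.sarimax import SARIMAX

from .data_io import ValidationError

logger = logging.getLogger("wearbp")


@dataclass
class EvenSeries:
    """Evenly spaced BP values interpolated from irregular readings."""

    grid_start: pd.Timestamp
    spacing: float  # hours
    values: np.ndarray
    interpolated_mask: np.ndarray  # True where no reading within spacing/2

    def __len__(self) -> int:
        return len(self.values)

    def times_hours(self) -> np.ndarray:
        return np.arange(len(self.values)) * self.spacing


@dataclass
class ArimaModelSpec:
    """A fitted (S)ARIMA model: orders, coefficients and fit score."""

    order: tuple[int, int, int]
    seasonal_order: tuple[int, int, int, int]  # (P, D, Q, T)
    trend: str  # 'c' when a constant delta is estimated, else 'n'
    params: np.ndarray  # statsmodels parameter vector
    delta: float
    ar_coefs: np.ndarray
    ma_coefs: np.ndarray
    sigma2: float
    score: float  # information criterion value
    criterion: str = "aicc"

    @property
    def n_coefs(self) -> int:
        return sum(self.order[::2]) + sum(self.seasonal_order[:3:2])


def resample_bp_series(readings: pd.DataFrame, target: str, spacing: float = 12.0) -> EvenSeries:
    """Linear interpolation of the ``target`` column onto a regular grid.

    The grid is anchored at the first reading and never extends past the
    last one (no extrapolation).
    """
    if len(readings) < 2:
        raise ValidationError("need >= 2 BP readings to resample")
    t = readings["timestamp"].to_numpy(dtype="datetime64[ns]").astype(np.int64)
    y = readings[target].to_numpy(dtype=float)
    t_h = (t - t[0]) / 3.6e12
    n = int(np.floor(t_h[-1] / spacing)) + 1
    grid = np.arange(n) * spacing
    values = np.interp(grid, t_h, y)
    nearest = np.minimum(
        np.abs(grid[:, None] - t_h[None, :]).min(axis=1), np.inf
    )
    return EvenSeries(
        grid_start=pd.Timestamp(readings["timestamp"].iloc[0]),
        spacing=spacing,
        values=values,
        interpolated_mask=nearest > spacing / 2,
    )


def _candidate_orders(max_p, max_d, max_q, seasonal, period):
    seas = (
        [(P, D, Q) for P, D, Q in product((0, 1), (0, 1), (0, 1))]
        if seasonal and period >= 2
        else [(0, 0, 0)]
    )
    cands = []
    for d, D in product(range(max_d + 1), sorted({s[1] for s in seas})):
        if d + D > 3:
            continue
        for p, q in product(range(max_p + 1), range(max_q + 1)):
            for P, Ds, Q in seas:
                if Ds != D:
                    continue
                cands.append(((p, d, q), (P, D, Q, period)))
    # visit simpler models first so criterion ties resolve to fewer parameters
    cands.sort(key=lambda c: (c[0][0] + c[0][2] + c[1][0] + c[1][2], c[0][1] + c[1][1], c))
    return cands


def _fit_one(values, order, seasonal_order, trend):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = SARIMAX(
            values,
            order=order,
            seasonal_order=seasonal_order if seasonal_order[3] >= 2 else (0, 0, 0, 0),
            trend=trend,
        )
        return model.fit(disp=False, maxiter=100)


def fit_best_arima(
    series: EvenSeries,
    max_p: int = 3,
    max_q: int = 3,
    max_d: int = 2,
    seasonal: bool = True,
    criterion: str = "aicc",
) -> ArimaModelSpec:
    """Exhaustive order search minimizing an information criterion.

    Every (p, d, q) within bounds — crossed with seasonal (P, D, Q) at the
    one-day period when ``seasonal`` — is fit; failures are skipped and
    logged.  Deterministic given the series and bounds.
    """
    values = np.asarray(series.values, dtype=float)
    if len(values) < 8:
        raise ValidationError("series too short to fit (need >= 8 points)")
    period = int(round(24.0 / series.spacing))
    if np.ptp(values) == 0:
        # degenerate constant series: a driftless random walk reproduces it
        logger.info("constant series: returning (0,1,0) with zero variance")
        return ArimaModelSpec(
            order=(0, 1, 0),
            seasonal_order=(0, 0, 0, period),
            trend="n",
            params=np.array([0.0]),
            delta=0.0,
            ar_coefs=np.array([]),
            ma_coefs=np.array([]),
            sigma2=0.0,
            score=-np.inf,
            criterion=criterion,
        )

    best = None
    for order, seasonal_order in _candidate_orders(max_p, max_d, max_q, seasonal, period):
        trend = "c" if order[1] + seasonal_order[1] == 0 else "n"
        try:
            res = _fit_one(values, order, seasonal_order, trend)
            score = float(getattr(res, criterion))
        except Exception as exc:  # noqa: BLE001 — candidate failures are expected
            logger.debug("order %s%s failed: %s", order, seasonal_order, exc)
            continue
        if not np.isfinite(score):
            continue
        if best is None or score < best[0] - 1e-9:
            best = (score, order, seasonal_order, trend, res)
    if best is None:
        raise ValidationError("every candidate ARIMA order failed to fit")
    score, order, seasonal_order, trend, res = best
    params = np.asarray(res.params, dtype=float)
    return ArimaModelSpec(
        order=order,
        seasonal_order=seasonal_order,
        trend=trend,
        params=params,
        delta=float(res.params[0]) if trend == "c" else 0.0,
        ar_coefs=np.asarray(res.polynomial_ar)[1:] * -1.0,
        ma_coefs=np.asarray(res.polynomial_ma)[1:],
        sigma2=float(res.params[-1]),
        score=score,
        criterion=criterion,
    )


def one_step_predictions(spec: ArimaModelSpec, values: np.ndarray) -> np.ndarray:
    """In-sample one-step-ahead predictions: entry i is conditioned on
    values[:i] only.  Entry len(values) (appended) is the out-of-sample
    one-step forecast."""
    values = np.asarray(values, dtype=float)
    if spec.order == (0, 1, 0) and spec.seasonal_order[:3] == (0, 0, 0) and spec.trend == "n":
        # driftless random walk: the one-step forecast is the last value,
        # exactly (the Kalman filter only approximates this under diffuse
        # initialization)
        return np.concatenate([[values[0]], values])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = SARIMAX(
            values,
            order=spec.order,
            seasonal_order=spec.seasonal_order if spec.seasonal_order[3] >= 2 else (0, 0, 0, 0),
            trend=spec.trend,
        )
        res = model.smooth(spec.params)
        in_sample = np.asarray(res.get_prediction(dynamic=False).predicted_mean)
        ahead = float(np.asarray(res.forecast(1))[0])
    return np.concatenate([in_sample, [ahead]])


def arima_one_step_forecasts(
    spec: ArimaModelSpec, series: EvenSeries, readings: pd.DataFrame
) -> np.ndarray:
    """One-step forecast aligned to each reading time.

    For a reading at time u the forecast is the model's prediction for the
    first grid point at/after u, conditioned on grid values strictly before
    u (look-back only: interpolated grid values after a reading depend on
    it).  Readings before the second grid point get NaN.
    """
    pred = one_step_predictions(spec, series.values)
    t = readings["timestamp"].to_numpy(dtype="datetime64[ns]").astype(np.int64)
    u_h = (t - series.grid_start.value) / 3.6e12
    # number of grid points strictly before u
    count = np.ceil(u_h / series.spacing - 1e-9).astype(int)
    count = np.clip(count, 0, len(series))
    out = np.full(len(u_h), np.nan)
    ok = count >= 1
    out[ok] = pred[count[ok]]
    return out
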