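"""Prediction metrics, repeated cross-validation and model ablations.

Metrics: MAE, RMSE, the aggregate MAPE (n*MAE divided by the sum of
absolute actuals, as a percentage — not the mean of per-sample percentage
errors) and the standard coefficient of determination R^2.

``compare_models`` runs the ablation ladder on one subject's data: the
SimpleMean baseline (training-mean predictor), the ARIMA one-step forecast
used directly as the prediction, RF on lifestyle features only, RF-ARIMA
(adds the SBP_arima/DBP_arima forecast features) and RFSV (adds
Shapley-value feature selection), across prediction horizons, with folds
shared between models so paired t-tests on per-sample errors are valid.
Imputation and the ARIMA/SHAP stages are fit on training folds only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .arima_features import arima_one_step_forecasts, fit_best_arima, resample_bp_series
from .data_io import ValidationError
from .features import ARIMA_FEATURES, FeatureTable, build_feature_table, impute_median
from .rfsv import RFParams, train_rf, train_rfsv

logger = logging.getLogger("wearbp")

MODELS = ("simple_mean", "arima", "rf", "rf_arima", "rfsv")


@dataclass(frozen=True)
class EvalMetrics:
    mae: float
    rmse: float
    mape: float  # percent
    r2: float
    n: int


@dataclass(frozen=True)
class TrendSlope:
    slope: float  # mmHg per day
    intercept: float  # mmHg at period start
    period: tuple[pd.Timestamp, pd.Timestamp]
    target: str


def compute_metrics(predicted, actual) -> EvalMetrics:
    predicted = np.asarray(predicted, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if predicted.shape != actual.shape or predicted.ndim != 1 or len(predicted) == 0:
        raise ValidationError("predicted and actual must be equal-length 1-d vectors")
    err = predicted - actual
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err**2)))
    denom = float(np.sum(np.abs(actual)))
    if denom == 0:
        logger.warning("sum |actual| is zero; MAPE undefined, reporting NaN")
        mape = np.nan
    else:
        mape = len(actual) * mae / denom * 100.0
    sst = float(np.sum((actual - actual.mean()) ** 2))
    r2 = 1.0 - float(np.sum(err**2)) / sst if sst > 0 else np.nan
    return EvalMetrics(mae=mae, rmse=rmse, mape=mape, r2=r2, n=len(actual))


@dataclass(frozen=True)
class PairedTTest:
    statistic: float
    p_value: float
    degenerate: bool = False


def paired_ttest(errors_a, errors_b) -> PairedTTest:
    """Two-sided paired Student's t-test on per-sample error differences."""
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise ValidationError("need equal-length paired samples, n >= 3")
    diff = a - b
    if np.std(diff, ddof=1) == 0:
        if np.mean(diff) == 0:
            return PairedTTest(statistic=0.0, p_value=1.0)
        return PairedTTest(statistic=np.inf, p_value=0.0, degenerate=True)
    res = stats.ttest_rel(a, b)
    return PairedTTest(statistic=float(res.statistic), p_value=float(res.pvalue))


def bp_trend_slope(readings: pd.DataFrame, period=None, target: str = "sbp") -> TrendSlope:
    """OLS slope of BP against time in days over ``period``."""
    df = readings
    if period is not None:
        lo, hi = pd.Timestamp(period[0]), pd.Timestamp(period[1])
        df = df[(df["timestamp"] >= lo) & (df["timestamp"] <= hi)]
    if len(df) < 2:
        raise ValidationError("need >= 2 readings in the period for a trend")
    t0 = pd.Timestamp(df["timestamp"].iloc[0])
    days = (df["timestamp"] - t0).dt.total_seconds().to_numpy() / 86400.0
    fit = stats.linregress(days, df[target].to_numpy(dtype=float))
    return TrendSlope(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        period=(t0, pd.Timestamp(df["timestamp"].iloc[-1])),
        target=target,
    )


def weekly_bp_stats(readings: pd.DataFrame, target: str = "sbp") -> dict:
    """Mean and max of daily-mean BP in the first and last calendar week."""
    df = readings.copy()
    df["day"] = df["timestamp"].dt.floor("D")
    daily = df.groupby("day")[target].mean()
    first = daily.iloc[: min(7, len(daily))]
    last = daily.iloc[-min(7, len(daily)):]
    return {
        "first_week": {"mean": float(first.mean()), "max": float(first.max())},
        "last_week": {"mean": float(last.mean()), "max": float(last.max())},
    }


# ---------------------------------------------------------------------------
# Cross-validation and ablations


@dataclass
class CVResult:
    metrics: EvalMetrics  # over all pooled held-out predictions
    per_fold: list[dict]
    fold_assignments: list[np.ndarray]  # per repeat: fold id per row
    predictions: np.ndarray  # pooled held-out predictions
    actuals: np.ndarray
    row_index: np.ndarray  # table row of each pooled prediction


def make_folds(
    n: int, k: int, rng: np.random.Generator, chronological: bool = False
) -> np.ndarray:
    """Fold id per row, sizes as equal as possible.

    Random assignment follows the stated protocol; ``chronological`` makes
    each fold a contiguous time block instead, which is stricter when the
    target is autocorrelated (no future rows in the training set's
    neighborhood of a test row).
    """
    if chronological:
        ids = np.zeros(n, dtype=int)
        for f, chunk in enumerate(np.array_split(np.arange(n), k)):
            ids[chunk] = f
        return ids
    ids = np.tile(np.arange(k), n // k + 1)[:n]
    rng.shuffle(ids)
    return ids


@dataclass(frozen=True)
class ArimaOptions:
    spacing: float = 12.0
    max_p: int = 2
    max_q: int = 2
    max_d: int = 1
    seasonal: bool = False
    criterion: str = "aicc"


def _fold_arima_columns(
    table: FeatureTable, train_idx: np.ndarray, opts: ArimaOptions
) -> dict[str, np.ndarray]:
    """SBP_arima/DBP_arima for all rows, fit on training-fold readings only."""
    cols = {}
    train_readings = table.df.iloc[np.sort(train_idx)][["timestamp", "sbp", "dbp"]]
    for target, name in (("sbp", "SBP_arima"), ("dbp", "DBP_arima")):
        series = resample_bp_series(train_readings, target, opts.spacing)
        spec = fit_best_arima(
            series,
            max_p=opts.max_p,
            max_q=opts.max_q,
            max_d=opts.max_d,
            seasonal=opts.seasonal,
            criterion=opts.criterion,
        )
        cols[name] = arima_one_step_forecasts(spec, series, table.df)
    return cols


def _fit_predict(
    model: str,
    train: FeatureTable,
    test: FeatureTable,
    target: str,
    params: RFParams,
    ratio: float,
    background_size: int,
    max_explained: int | None,
) -> np.ndarray:
    if model == "simple_mean":
        return np.full(len(test), float(train.y(target).mean()))
    if model == "arima":
        col = "SBP_arima" if target == "sbp" else "DBP_arima"
        return test.df[col].to_numpy(dtype=float)
    base_features = [f for f in train.feature_names if f not in ARIMA_FEATURES]
    if model == "rf":
        rf = train_rf(train, target, params, feature_names=base_features)
        return rf.predict(test.df)
    if model == "rf_arima":
        rf = train_rf(train, target, params)
        return rf.predict(test.df)
    if model == "rfsv":
        rfsv = train_rfsv(
            train,
            target,
            params,
            ratio=ratio,
            background_size=background_size,
            max_explained=max_explained,
        )
        return rfsv.final_model.predict(test.df)
    raise ValidationError(f"unknown model {model!r}; choose from {MODELS}")


def cross_validate(
    table: FeatureTable,
    model: str = "rf",
    target: str = "sbp",
    k: int = 5,
    repeats: int = 5,
    seed: int = 0,
    params: RFParams | None = None,
    ratio: float = 0.5,
    background_size: int = 64,
    max_explained: int | None = 128,
    arima_opts: ArimaOptions | None = None,
    folds: list[np.ndarray] | None = None,
    arima_cache: dict | None = None,
    chronological: bool = False,
) -> CVResult:
    """Repeated k-fold CV with per-training-fold imputation and ARIMA/SHAP.

    Folds are random (non-chronological) per repeat; pass ``folds`` to share
    assignments across models.  A failing fold is flagged, logged and
    excluded from the pooled metrics.
    """
    n = len(table)
    if not 2 <= k <= n:
        raise ValidationError(f"folds must satisfy 2 <= k <= {n} rows (k = n is leave-one-out)")
    params = params or RFParams(seed=seed)
    arima_opts = arima_opts or ArimaOptions()
    if folds is None:
        rng = np.random.default_rng(seed)
        folds = [make_folds(n, k, rng, chronological) for _ in range(repeats)]
    needs_arima = model in ("arima", "rf_arima", "rfsv")

    per_fold, preds, acts, rows = [], [], [], []
    for rep, fold_ids in enumerate(folds):
        for fold in range(k):
            test_idx = np.flatnonzero(fold_ids == fold)
            train_idx = np.flatnonzero(fold_ids != fold)
            try:
                work = table
                if needs_arima:
                    key = (rep, fold)
                    if arima_cache is not None and key in arima_cache:
                        cols = arima_cache[key]
                    else:
                        cols = _fold_arima_columns(table, train_idx, arima_opts)
                        if arima_cache is not None:
                            arima_cache[key] = cols
                    work = table.with_columns(**cols)
                train = impute_median(work.subset(train_idx))
                train_medians = work.df[work.feature_names].iloc[train_idx].median()
                test = impute_median(work.subset(test_idx), medians=train_medians)
                yhat = _fit_predict(
                    model, train, test, target, params, ratio, background_size, max_explained
                )
            except Exception as exc:  # noqa: BLE001 — fold isolation is the contract
                logger.warning("fold (%d, %d) failed for %s: %s", rep, fold, model, exc)
                per_fold.append({"repeat": rep, "fold": fold, "failed": True, "error": str(exc)})
                continue
            y = table.y(target).to_numpy(dtype=float)[test_idx]
            m = compute_metrics(yhat, y)
            per_fold.append({"repeat": rep, "fold": fold, "failed": False, "metrics": m})
            preds.append(yhat)
            acts.append(y)
            rows.append(test_idx)
    if not preds:
        raise ValidationError(f"every CV fold failed for model {model!r}")
    predictions = np.concatenate(preds)
    actuals = np.concatenate(acts)
    return CVResult(
        metrics=compute_metrics(predictions, actuals),
        per_fold=per_fold,
        fold_assignments=folds,
        predictions=predictions,
        actuals=actuals,
        row_index=np.concatenate(rows),
    )


@dataclass
class ModelComparison:
    subject_id: str
    table: pd.DataFrame  # model, target, horizon, mae, rmse, mape, r2, n
    p_values: pd.DataFrame  # model_a, model_b, target, horizon, p_value
    results: dict = field(default_factory=dict)  # (model, target, horizon) -> CVResult


def compare_models(
    dataset,
    targets=("sbp", "dbp"),
    models=MODELS,
    horizons=(0,),
    seed: int = 0,
    k: int = 5,
    repeats: int = 1,
    params: RFParams | None = None,
    arima_opts: ArimaOptions | None = None,
    test_pairs: tuple[tuple[str, str], ...] | None = None,
    **cv_kwargs,
) -> ModelComparison:
    """Ablation over models and horizons with folds shared across models."""
    params = params or RFParams(seed=seed)
    rows, pvals, results = [], [], {}
    for horizon in horizons:
        table = build_feature_table(dataset, horizon_shift=horizon, impute=False)
        rng = np.random.default_rng(seed + 1000 * int(horizon))
        folds = [make_folds(len(table), k, rng) for _ in range(repeats)]
        arima_cache: dict = {}
        for target in targets:
            for model in models:
                res = cross_validate(
                    table,
                    model=model,
                    target=target,
                    k=k,
                    repeats=repeats,
                    seed=seed,
                    params=params,
                    arima_opts=arima_opts,
                    folds=folds,
                    arima_cache=arima_cache,
                    **cv_kwargs,
                )
                results[(model, target, horizon)] = res
                m = res.metrics
                rows.append(
                    {
                        "subject_id": dataset.subject_id,
                        "model": model,
                        "target": target,
                        "horizon": horizon,
                        "mae": m.mae,
                        "rmse": m.rmse,
                        "mape": m.mape,
                        "r2": m.r2,
                        "n": m.n,
                    }
                )
            pairs = test_pairs
            if pairs is None:
                pairs = tuple(("rfsv", m) for m in models if m != "rfsv" and "rfsv" in models)
            for a, b in pairs:
                ra, rb = results.get((a, target, horizon)), results.get((b, target, horizon))
                if ra is None or rb is None or len(ra.predictions) != len(rb.predictions):
                    continue
                tt = paired_ttest(
                    np.abs(ra.predictions - ra.actuals), np.abs(rb.predictions - rb.actuals)
                )
                pvals.append(
                    {
                        "model_a": a,
                        "model_b": b,
                        "target": target,
                        "horizon": horizon,
                        "p_value": tt.p_value,
                        "degenerate": tt.degenerate,
                    }
                )
    return ModelComparison(
        subject_id=dataset.subject_id,
        table=pd.DataFrame(rows),
        p_values=pd.DataFrame(pvals),
        results=results,
    )
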