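"""Random-forest BP models with Shapley-value feature selection (RFSV).

Pipeline: fit a random forest on all engineered features, attribute its
predictions with exact interventional Tree SHAP, rank features by the mean
absolute Shapley value over training samples, keep the top fraction
(default 0.5), and refit the forest on the kept features.  Alternative
importance scorers (absolute Pearson correlation, information gain on
quantile bins, mean-decrease-impurity) are provided for comparison.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.metrics import mutual_info_score

from .data_io import ValidationError
from .features import FeatureTable
from .shapley import tree_shap_interventional

logger = logging.getLogger("wearbp")


@dataclass(frozen=True)
class RFParams:
    """Random-forest settings: 500 trees, per-split candidate fraction 0.33,
    minimum samples to split 2."""

    n_trees: int = 500
    feature_ratio_per_tree: float = 0.33
    min_samples_split: int = 2
    seed: int = 0

    def validate(self) -> "RFParams":
        if self.n_trees < 1:
            raise ValidationError("n_trees must be >= 1")
        if not 0 < self.feature_ratio_per_tree <= 1:
            raise ValidationError("feature_ratio_per_tree must be in (0, 1]")
        return self


@dataclass
class RFModel:
    """A fitted forest plus its feature list and training medians."""

    estimator: RandomForestRegressor
    feature_names: list[str]
    medians: pd.Series
    target: str

    def matrix(self, rows: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in rows.columns]
        if missing:
            raise ValidationError(f"rows lack model features {missing}")
        X = rows[self.feature_names].astype(float).fillna(self.medians)
        if not np.isfinite(X.to_numpy()).all():
            raise ValidationError("non-finite feature cells after imputation")
        return X.to_numpy()

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        return self.estimator.predict(self.matrix(rows))


@dataclass
class ImportanceReport:
    """Per-feature importance; for SHAP also the per-sample phi matrix."""

    feature_names: list[str]
    mean_abs: pd.Series  # mean |phi| (SHAP) or scalar score per feature
    method: str  # shap | pearson | info_gain | impurity
    values: np.ndarray | None = None  # (J, K) Shapley matrix
    baseline: float | None = None  # expected prediction over background
    sample_rows: np.ndarray | None = None  # table rows explained (None = all)

    def ranking(self) -> list[str]:
        # stable sort: ties break toward the canonical feature order
        order = np.argsort(-self.mean_abs.to_numpy(), kind="stable")
        return [self.feature_names[i] for i in order]


@dataclass
class TrainedRFSV:
    """All stages of the selection pipeline, recorded."""

    pre_model: RFModel
    importance: ImportanceReport
    selected_features: list[str]
    final_model: RFModel
    ratio: float
    target: str
    meta: dict = field(default_factory=dict)


def _rows_of(table) -> pd.DataFrame:
    return table.df if isinstance(table, FeatureTable) else table


def train_rf(
    table: FeatureTable,
    target: str,
    params: RFParams = RFParams(),
    feature_names: list[str] | None = None,
) -> RFModel:
    """Fit a bagged forest of regression trees with per-split feature
    subsampling; deterministic given ``params.seed``."""
    params.validate()
    names = list(feature_names) if feature_names is not None else list(table.feature_names)
    df = table.df
    medians = df[names].median()
    X = df[names].astype(float).fillna(medians)
    if X.isna().any().any():
        # a column that is entirely missing cannot be imputed
        bad = list(X.columns[X.isna().any()])
        raise ValidationError(f"features with no observed values: {bad}")
    complete = int((~table.X()[names].isna().any(axis=1)).sum()) if names else 0
    if complete < 20:
        raise ValidationError(f"need >= 20 complete rows, have {complete}")
    y = table.y(target).to_numpy(dtype=float)
    est = RandomForestRegressor(
        n_estimators=params.n_trees,
        max_features=params.feature_ratio_per_tree,
        min_samples_split=params.min_samples_split,
        random_state=params.seed,
        n_jobs=1,
    )
    est.fit(X.to_numpy(), y)
    return RFModel(estimator=est, feature_names=names, medians=medians, target=target)


def predict(model, rows) -> np.ndarray:
    """Predict mmHg per row; a TrainedRFSV uses its final (selected) model."""
    rows = _rows_of(rows)
    if isinstance(model, TrainedRFSV):
        model = model.final_model
    return model.predict(rows)


def shap_importance(
    model: RFModel,
    table: FeatureTable,
    background: pd.DataFrame | np.ndarray | None = None,
    background_size: int = 200,
    sample_rows: np.ndarray | None = None,
    seed: int = 0,
) -> ImportanceReport:
    """Per-sample interventional Shapley values and their mean |phi| ranking.

    The background defaults to the table's own rows, subsampled to
    ``background_size`` with ``seed``.  ``sample_rows`` restricts which rows
    are explained (all by default).
    """
    df = _rows_of(table)
    X = model.matrix(df)
    if sample_rows is not None:
        X = X[np.asarray(sample_rows)]
    if background is None:
        Z = model.matrix(df)
        if Z.shape[0] > background_size:
            rng = np.random.default_rng(seed)
            Z = Z[rng.choice(Z.shape[0], background_size, replace=False)]
    else:
        Z = background if isinstance(background, np.ndarray) else model.matrix(background)
    if Z.shape[0] == 0:
        raise ValidationError("background sample is empty")
    phi, baseline = tree_shap_interventional(model.estimator, X, Z)
    mean_abs = pd.Series(np.abs(phi).mean(axis=0), index=model.feature_names)
    return ImportanceReport(
        feature_names=list(model.feature_names),
        mean_abs=mean_abs,
        method="shap",
        values=phi,
        baseline=baseline,
        sample_rows=None if sample_rows is None else np.asarray(sample_rows),
    )


def select_features(report: ImportanceReport, ratio: float = 0.5) -> list[str]:
    """Top ceil(ratio * K) features by mean importance, stable ties.

    The kept set is returned in the report's canonical feature order so a
    ratio of 1.0 reproduces the original feature list exactly.
    """
    if not 0 < ratio <= 1:
        raise ValidationError("selection ratio must be in (0, 1]")
    k = math.ceil(ratio * len(report.feature_names))
    keep = set(report.ranking()[:k])
    return [f for f in report.feature_names if f in keep]


def train_rfsv(
    table: FeatureTable,
    target: str,
    params: RFParams = RFParams(),
    ratio: float = 0.5,
    background_size: int = 64,
    max_explained: int | None = None,
) -> TrainedRFSV:
    """train on all features -> SHAP ranking -> keep top ratio -> retrain."""
    pre = train_rf(table, target, params)
    n = len(_rows_of(table))
    sample_rows = None
    if max_explained is not None and n > max_explained:
        sample_rows = np.random.default_rng(params.seed).choice(n, max_explained, replace=False)
    report = shap_importance(
        pre, table, background_size=background_size, sample_rows=sample_rows, seed=params.seed
    )
    selected = select_features(report, ratio)
    final = train_rf(table, target, params, feature_names=selected)
    return TrainedRFSV(
        pre_model=pre,
        importance=report,
        selected_features=selected,
        final_model=final,
        ratio=ratio,
        target=target,
    )


def alt_importance(
    method: str,
    table: FeatureTable,
    target: str,
    model: RFModel | None = None,
    n_bins: int = 10,
) -> ImportanceReport:
    """Alternative importance scorers: |Pearson r|, information gain over
    quantile bins, or the forest's mean decrease in impurity."""
    df = _rows_of(table)
    names = list(table.feature_names) if isinstance(table, FeatureTable) else [
        c for c in df.columns if c not in ("timestamp", "sbp", "dbp")
    ]
    y = df[target].to_numpy(dtype=float)
    scores = np.zeros(len(names))
    if method == "pearson":
        for i, f in enumerate(names):
            x = df[f].to_numpy(dtype=float)
            ok = np.isfinite(x)
            if x[ok].std() == 0 or y[ok].std() == 0:
                logger.info("pearson: zero-variance feature %s -> 0", f)
                continue
            scores[i] = abs(np.corrcoef(x[ok], y[ok])[0, 1])
    elif method == "info_gain":
        y_bins = _quantile_bins(y, n_bins)
        for i, f in enumerate(names):
            x = df[f].to_numpy(dtype=float)
            ok = np.isfinite(x)
            if np.unique(x[ok]).size < 2:
                logger.info("info_gain: zero-variance feature %s -> 0", f)
                continue
            scores[i] = mutual_info_score(y_bins[ok], _quantile_bins(x[ok], n_bins))
    elif method == "impurity":
        if model is None:
            raise ValidationError("impurity importance requires a trained model")
        imp = pd.Series(model.estimator.feature_importances_, index=model.feature_names)
        scores = imp.reindex(names).fillna(0.0).to_numpy()
    else:
        raise ValidationError(f"unknown importance method {method!r}")
    return ImportanceReport(
        feature_names=names, mean_abs=pd.Series(scores, index=names), method=method
    )


def _quantile_bins(x: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.digitize(x, edges)
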