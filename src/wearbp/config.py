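"""Declarative run configuration for the end-to-end pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .data_io import ValidationError


@dataclass
class RunConfig:
    """Every stage's knobs in one place; defaults follow the method's
    stated settings (500 trees, 0.33 per-split feature fraction, min split 2,
    selection ratio 0.5, 5 folds x 5 repeats, one-day seasonal period)."""

    out_dir: str = "wearbp_run"
    seed: int = 0
    # cohort simulation
    n_subjects: int = 3
    days: int = 90
    noise_sd: float = 4.0
    ar_coefficient: float = 0.3
    missing_bp_rate: float = 0.05
    effect_jitter: float = 0.0
    # features
    horizon: int = 0
    dedup_policy: str = "mean"
    # random forest
    n_trees: int = 500
    feature_ratio_per_tree: float = 0.33
    min_samples_split: int = 2
    # selection
    selection_ratio: float = 0.5
    background_size: int = 64
    max_explained: int | None = 128
    importance: str = "shap"
    # arima
    spacing: float = 12.0
    max_p: int = 2
    max_q: int = 2
    max_d: int = 1
    seasonal: bool = False
    criterion: str = "aicc"
    # evaluation
    folds: int = 5
    repeats: int = 5
    models: tuple = ("simple_mean", "arima", "rf", "rf_arima", "rfsv")
    targets: tuple = ("sbp", "dbp")
    # recommendation
    top_n: int = 3
    direction_threshold: float = 0.2
    recommendation_templates: dict = field(default_factory=dict)

    def validate(self) -> "RunConfig":
        if self.folds < 2:
            raise ValidationError("folds must be >= 2")
        if self.repeats < 1:
            raise ValidationError("repeats must be >= 1")
        if not 0 < self.selection_ratio <= 1:
            raise ValidationError("selection_ratio must be in (0, 1]")
        if self.horizon not in (0, 12, 24, 48):
            raise ValidationError("horizon must be one of 0, 12, 24, 48")
        return self

    def to_dict(self, include_paths: bool = True) -> dict:
        d = asdict(self)
        d["models"] = list(self.models)
        d["targets"] = list(self.targets)
        if not include_paths:
            d.pop("out_dir")
        return d

    def hash(self) -> str:
        # the output location does not affect what is computed
        blob = json.dumps(self.to_dict(include_paths=False), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.models = tuple(cfg.models)
        cfg.targets = tuple(cfg.targets)
        return cfg.validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
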