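"""Stage orchestration: simulate -> featurize -> arima -> train -> evaluate
-> recommend, with per-stage seeds fanned out from one global seed and a
manifest recording config hash and artifact checksums for reproducibility."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import data_io
from .arima_features import arima_one_step_forecasts, fit_best_arima, resample_bp_series
from .config import RunConfig
from .evaluation import ArimaOptions, compare_models
from .features import build_feature_table
from .recommend import format_report, generate_recommendations
from .rfsv import RFParams, train_rfsv
from .synthetic_data import EffectSpec, SimProfile, simulate_cohort

logger = logging.getLogger("wearbp")

#: lifestyle effects planted by the default simulation profile
DEFAULT_EFFECTS = (
    EffectSpec("steps_24", -5.0, "both"),
    EffectSpec("bed_time_24", 4.0, "both"),
    EffectSpec("heart_rate_1", 4.0, "both"),
)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def default_profile(config: RunConfig) -> SimProfile:
    return SimProfile(
        days=config.days,
        noise_sd=config.noise_sd,
        ar_coefficient=config.ar_coefficient,
        missing_bp_rate=config.missing_bp_rate,
        effects=DEFAULT_EFFECTS,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    # simulate ------------------------------------------------------------
    profile = default_profile(config)
    cohort = simulate_cohort(
        config.n_subjects,
        profile,
        stage_seed(config.seed, "simulate"),
        effect_jitter=config.effect_jitter,
    )
    truth_rows = []
    for ds, truth in cohort:
        sub = out / ds.subject_id
        sub.mkdir(exist_ok=True)
        data_io.write_subject_dataset(
            ds, sub / "wearable.csv", sub / "sleep.csv", sub / "bp.csv"
        )
        artifacts += [sub / "wearable.csv", sub / "sleep.csv", sub / "bp.csv"]
        for eff in truth.profile.effects:
            truth_rows.append(
                {
                    "subject_id": ds.subject_id,
                    "feature_name": eff.feature_name,
                    "coefficient": eff.coefficient,
                    "target": eff.applies_to,
                }
            )
    pd.DataFrame(truth_rows).to_csv(out / "ground_truth.csv", index=False)
    artifacts.append(out / "ground_truth.csv")

    arima_opts = ArimaOptions(
        spacing=config.spacing,
        max_p=config.max_p,
        max_q=config.max_q,
        max_d=config.max_d,
        seasonal=config.seasonal,
        criterion=config.criterion,
    )
    params = RFParams(
        n_trees=config.n_trees,
        feature_ratio_per_tree=config.feature_ratio_per_tree,
        min_samples_split=config.min_samples_split,
        seed=stage_seed(config.seed, "train"),
    )

    comparison_rows, pval_rows, reports = [], [], []
    for ds, truth in cohort:
        sub = out / ds.subject_id
        # featurize + arima columns (full-series fit, for the artifact) ----
        table = build_feature_table(ds, horizon_shift=config.horizon, dedup_policy=config.dedup_policy)
        for target, name in (("sbp", "SBP_arima"), ("dbp", "DBP_arima")):
            series = resample_bp_series(table.df, target, config.spacing)
            spec = fit_best_arima(
                series, config.max_p, config.max_q, config.max_d, config.seasonal, config.criterion
            )
            table = table.with_columns(**{name: arima_one_step_forecasts(spec, series, table.df)})
        data_io.write_feature_table(table, sub / "features.csv")
        artifacts.append(sub / "features.csv")

        # train + importance + recommend ----------------------------------
        for target in config.targets:
            rfsv = train_rfsv(
                table,
                target,
                params,
                ratio=config.selection_ratio,
                background_size=config.background_size,
                max_explained=config.max_explained,
            )
            imp = rfsv.importance.mean_abs.sort_values(ascending=False)
            imp.rename("mean_abs_shap").to_csv(sub / f"importance_{target}.csv")
            artifacts.append(sub / f"importance_{target}.csv")
            report = generate_recommendations(
                rfsv, table, top_n=config.top_n, threshold=config.direction_threshold
            )
            reports.append(report)
            (sub / f"recommendation_{target}.txt").write_text(format_report(report) + "\n")
            artifacts.append(sub / f"recommendation_{target}.txt")

        # evaluate ---------------------------------------------------------
        comparison = compare_models(
            ds,
            targets=config.targets,
            models=config.models,
            horizons=(config.horizon,),
            seed=stage_seed(config.seed, "evaluate"),
            k=config.folds,
            repeats=config.repeats,
            params=params,
            arima_opts=arima_opts,
            background_size=config.background_size,
            max_explained=config.max_explained,
        )
        comparison_rows.append(comparison.table)
        pval_rows.append(comparison.p_values)

    pd.concat(comparison_rows, ignore_index=True).to_csv(out / "comparison.csv", index=False)
    artifacts.append(out / "comparison.csv")
    pd.concat(pval_rows, ignore_index=True).to_csv(out / "p_values.csv", index=False)
    artifacts.append(out / "p_values.csv")

    manifest = {
        "config": config.to_dict(include_paths=False),
        "config_hash": config.hash(),
        "seed": config.seed,
        "stage_seeds": {s: stage_seed(config.seed, s) for s in ("simulate", "train", "evaluate")},
        "artifacts": {str(p.relative_to(out)): _sha256(p) for p in sorted(set(artifacts))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %d artifacts in %s", len(artifacts), out)
    return manifest
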