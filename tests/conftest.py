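import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestRegressor

from wearbp.features import build_feature_table
from wearbp.synthetic_data import EffectSpec, SimProfile, simulate_subject

#: three planted lifestyle effects; heart_rate_1 is deliberately
#: non-actionable so recommendation filtering is exercised.
CAUSAL_EFFECTS = (
    EffectSpec("steps_24", -5.0, "both"),
    EffectSpec("bed_time_24", 4.0, "both"),
    EffectSpec("heart_rate_1", 4.0, "both"),
)


def make_profile(**kw) -> SimProfile:
    defaults = dict(
        days=90,
        noise_sd=4.0,
        ar_coefficient=0.3,
        missing_bp_rate=0.0,
        wearable_dropout_rate=0.0,
        effects=CAUSAL_EFFECTS,
    )
    defaults.update(kw)
    return SimProfile(**defaults)


@pytest.fixture(scope="session")
def small_subject():
    """14-day clean subject with planted effects, plus its ground truth."""
    ds, truth = simulate_subject(make_profile(days=14, noise_sd=2.0), seed=11)
    return ds, truth


@pytest.fixture(scope="session")
def small_table(small_subject):
    ds, _ = small_subject
    return build_feature_table(ds)


@pytest.fixture(scope="session")
def study_subject():
    """Full 90-day study-protocol subject (noise 4 mmHg, AR 0.3)."""
    ds, truth = simulate_subject(make_profile(), seed=5)
    return ds, truth


@pytest.fixture(scope="session")
def study_table(study_subject):
    ds, _ = study_subject
    return build_feature_table(ds)


def tiny_forest(seed: int, n_features: int = 5, n_trees: int = 4, depth: int = 3,
                n_rows: int = 40):
    """A small random forest plus explained rows and a background sample."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n_rows, n_features))
    coefs = rng.normal(size=n_features) * (rng.random(n_features) > 0.3)
    y = X @ coefs + 0.3 * rng.normal(size=n_rows)
    forest = RandomForestRegressor(
        n_estimators=n_trees, max_depth=depth, max_features=0.6, random_state=seed
    ).fit(X, y)
    return forest, X[: min(4, n_rows)], X[rng.choice(n_rows, 5, replace=False)]


def write_subject_files(tmp_path, minutes_rows, sleep_rows, bp_rows):
    """Write raw CSVs from literal row lists; returns the three paths."""
    w = tmp_path / "wearable.csv"
    s = tmp_path / "sleep.csv"
    b = tmp_path / "bp.csv"
    w.write_text("timestamp,heart_rate,steps,speed,floors\n" + "".join(minutes_rows))
    s.write_text("start,end,stage\n" + "".join(sleep_rows))
    b.write_text("timestamp,sbp,dbp\n" + "".join(bp_rows))
    return w, s, b
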