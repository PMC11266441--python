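"""Gradient-boosting learner over model input tables.

A LightGBM regressor is trained on the numeric feature columns plus the field
location treated as a categorical feature.  The configuration keeps the
library's regression defaults (100 trees, learning rate 0.1, 31 leaves) since
no tuned values are part of the method; single-threaded deterministic mode
guarantees bit-identical predictions for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import lightgbm as lgb

from .errors import SchemaError
from .model_inputs import ModelInput


@dataclass
class GBMConfig:
    num_trees: int = 100
    learning_rate: float = 0.1
    max_leaves: int = 31
    min_data_in_leaf: int = 20
    feature_fraction: float = 1.0
    bagging_fraction: float = 1.0
    seed: int = 0
    categorical_features: tuple = ("Field_Location",)
    n_jobs: int = 1
    deterministic: bool = True

    def __post_init__(self):
        if min(self.num_trees, self.max_leaves, self.min_data_in_leaf) < 1:
            raise ValueError("counts must be positive")
        for f in (self.feature_fraction, self.bagging_fraction):
            if not 0 < f <= 1:
                raise ValueError("fractions must lie in (0, 1]")


@dataclass
class PredictionSet:
    records: pd.DataFrame  # Env, Hybrid, y_observed, y_predicted
    model_kind: str
    fold: int = 0
    repetition: int = 0

    def __post_init__(self):
        if not np.all(np.isfinite(self.records["y_predicted"])):
            raise ValueError("non-finite predictions")


def _feature_frame(mi: ModelInput, rows: pd.DataFrame, cfg: GBMConfig, categories):
    feats = rows[list(mi.feature_cols)].copy()
    for c in cfg.categorical_features:
        feats[c] = pd.Categorical(rows[c], categories=categories[c])
    return feats


def fit_predict(
    train: pd.DataFrame,
    valid: pd.DataFrame,
    model_input: ModelInput,
    cfg: GBMConfig | None = None,
    fold: int = 0,
    repetition: int = 0,
) -> PredictionSet:
    """Train on ``train`` rows and predict the ``valid`` rows of a ModelInput.

    Both frames must carry the ModelInput's feature schema; the categorical
    vocabulary is the union of both so unseen-level encoding is consistent.
    """
    cfg = cfg or GBMConfig()
    if len(train) == 0:
        raise ValueError("empty training set")
    needed = set(model_input.feature_cols) | set(cfg.categorical_features) | {"y"}
    for name, df in (("train", train), ("valid", valid)):
        missing = needed - set(df.columns)
        if missing:
            raise SchemaError(f"{name} table lacks columns {sorted(missing)}")

    categories = {
        c: sorted(set(train[c]) | set(valid[c])) for c in cfg.categorical_features
    }
    X_train = _feature_frame(model_input, train, cfg, categories)
    X_valid = _feature_frame(model_input, valid, cfg, categories)

    params = dict(
        n_estimators=cfg.num_trees,
        learning_rate=cfg.learning_rate,
        num_leaves=cfg.max_leaves,
        min_child_samples=cfg.min_data_in_leaf,
        colsample_bytree=cfg.feature_fraction,
        subsample=cfg.bagging_fraction,
        subsample_freq=1 if cfg.bagging_fraction < 1 else 0,
        random_state=cfg.seed,
        n_jobs=cfg.n_jobs,
        deterministic=cfg.deterministic,
        force_row_wise=True,
        verbose=-1,
    )
    model = lgb.LGBMRegressor(**params)
    model.fit(X_train, train["y"].to_numpy(), categorical_feature=list(cfg.categorical_features))
    pred = model.predict(X_valid)
    records = pd.DataFrame(
        {
            "Env": valid["Env"].to_numpy(),
            "Hybrid": valid["Hybrid"].to_numpy(),
            "y_observed": valid["y"].to_numpy(),
            "y_predicted": pred,
        }
    )
    return PredictionSet(records, model_input.model_name, fold=fold, repetition=repetition)
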