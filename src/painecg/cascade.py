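"""Dual-model pain cascade: binary detection gating intensity estimation.

The architecture mirrors clinical decision-making: a random-forest
classifier first decides whether pain is present (CoVAS = 0 vs > 0); only
when it fires does a random-forest regressor estimate intensity on the
0-100 CoVAS scale. Features are median-imputed and standardized with
statistics from the training split only, then reduced by recursive feature
elimination (drop the lowest-Gini feature until ``rfe_k`` remain).

By default the regressor is trained on ground-truth pain rows
(covas_value > 0); ``regressor_gated_by_classifier=True`` trains it on the
rows the fitted classifier calls pain instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.feature_selection import RFE
from sklearn.model_selection import GroupShuffleSplit, train_test_split

from .errors import ValidationError
from .features import FEATURE_COLUMNS

__all__ = [
    "TrainConfig",
    "Scaler",
    "CascadeModel",
    "standardize",
    "select_features_rfe",
    "fit_cascade",
    "predict_cascade",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TrainConfig:
    test_fraction: float = 0.2
    n_trees: int = 100
    max_depth: int | None = None
    rfe_k: int = 10
    seed: int = 0
    split_grouping: Literal["by_session", "by_window"] = "by_window"
    threshold: float = 0.5
    regressor_gated_by_classifier: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValidationError("test_fraction must lie in (0, 1)")
        if self.rfe_k < 1:
            raise ValidationError("rfe_k must be >= 1")


@dataclass
class Scaler:
    """Per-feature median (for imputation), mean and SD from the training split."""

    median: pd.Series
    mean: pd.Series
    sd: pd.Series

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table[self.mean.index].copy()
        out = out.fillna(self.median)
        return (out - self.mean) / self.sd


@dataclass
class CascadeModel:
    scaler: Scaler
    selected_features: list[str]
    classifier: RandomForestClassifier
    regressor: RandomForestRegressor | None
    config: TrainConfig = field(default_factory=TrainConfig)


def standardize(
    table: pd.DataFrame, scaler: Scaler | None = None, columns: Sequence[str] | None = None
) -> tuple[pd.DataFrame, Scaler]:
    """Median-impute then z-score feature columns; fit on this table unless a scaler is given.

    Training columns come out with mean 0 and sample SD 1; zero-variance
    columns get SD set to 1 (warning) so they pass through centered.
    """
    if scaler is None:
        cols = list(columns) if columns is not None else [
            c for c in table.columns if c in FEATURE_COLUMNS
        ]
        sub = table[cols]
        median = sub.median()
        filled = sub.fillna(median)
        mean = filled.mean()
        sd = filled.std(ddof=1)
        zero_var = sd.index[(sd == 0) | sd.isna()]
        if len(zero_var):
            logger.warning("zero-variance column(s) %s: SD set to 1", list(zero_var))
            sd = sd.copy()
            sd[zero_var] = 1.0
        scaler = Scaler(median=median, mean=mean, sd=sd)
    return scaler.transform(table), scaler


def select_features_rfe(
    table: pd.DataFrame,
    labels: Sequence,
    rfe_k: int,
    config: TrainConfig | None = None,
) -> list[str]:
    """Recursive feature elimination: iteratively drop the lowest-Gini feature.

    Backed by a seeded random-forest classifier refit after each single-feature
    elimination until ``rfe_k`` features remain; deterministic given the seed.
    """
    config = config or TrainConfig()
    if rfe_k > table.shape[1]:
        raise ValidationError(f"rfe_k={rfe_k} exceeds {table.shape[1]} features")
    if rfe_k == table.shape[1]:
        return list(table.columns)
    estimator = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        max_features="sqrt",
        random_state=config.seed,
        n_jobs=1,
    )
    rfe = RFE(estimator, n_features_to_select=rfe_k, step=1)
    rfe.fit(table.to_numpy(), np.asarray(labels))
    return [c for c, keep in zip(table.columns, rfe.support_) if keep]


def _split(
    table: pd.DataFrame, config: TrainConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    y = (table["covas_value"] > 0).astype(int)
    if config.split_grouping == "by_session" and "session" in table.columns:
        splitter = GroupShuffleSplit(
            n_splits=1, test_size=config.test_fraction, random_state=config.seed
        )
        train_idx, test_idx = next(splitter.split(table, groups=table["session"]))
        return table.iloc[train_idx], table.iloc[test_idx]
    train, test = train_test_split(
        table, test_size=config.test_fraction, random_state=config.seed, stratify=y
    )
    return train, test


def fit_cascade(
    feature_table: pd.DataFrame, config: TrainConfig | None = None
) -> tuple[CascadeModel, pd.DataFrame]:
    """Fit the cascade on a feature table; returns (model, held-out test rows).

    The split is stratified by the binary pain label at ``test_fraction``
    (or grouped by session). Scaler and RFE use the training split only; the
    regressor sees training rows with covas_value > 0 and the raw 0-100
    CoVAS as its target.
    """
    config = config or TrainConfig()
    if "covas_value" not in feature_table.columns:
        raise ValidationError("feature table must carry a covas_value column")
    y_all = (feature_table["covas_value"] > 0).astype(int)
    if y_all.nunique() < 2:
        raise ValidationError("training data must contain both pain and no-pain rows")

    train, test = _split(feature_table, config)
    y_train = (train["covas_value"] > 0).astype(int)
    if y_train.nunique() < 2:
        raise ValidationError("training split is single-class; adjust the split")

    X_train, scaler = standardize(train)
    rfe_k = min(config.rfe_k, X_train.shape[1])
    selected = select_features_rfe(X_train, y_train, rfe_k, config)

    classifier = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_depth=config.max_depth,
        max_features="sqrt",
        random_state=config.seed,
        n_jobs=1,
    )
    classifier.fit(X_train[selected].to_numpy(), y_train.to_numpy())

    if config.regressor_gated_by_classifier:
        prob = classifier.predict_proba(X_train[selected].to_numpy())[:, 1]
        pain_mask = prob >= config.threshold
    else:
        pain_mask = (train["covas_value"] > 0).to_numpy()
    n_pain = int(pain_mask.sum())
    regressor = None
    if n_pain >= 2:
        if n_pain < 10:
            logger.warning("only %d pain rows available for the regressor", n_pain)
        regressor = RandomForestRegressor(
            n_estimators=config.n_trees,
            max_depth=config.max_depth,
            random_state=config.seed,
            n_jobs=1,
        )
        regressor.fit(
            X_train.loc[pain_mask, selected].to_numpy(),
            train.loc[pain_mask, "covas_value"].to_numpy(),
        )
    else:
        logger.warning("no pain rows in the training split; regressor not fitted")

    model = CascadeModel(
        scaler=scaler,
        selected_features=list(selected),
        classifier=classifier,
        regressor=regressor,
        config=config,
    )
    return model, test


def predict_cascade(model: CascadeModel, feature_rows: pd.DataFrame) -> pd.DataFrame:
    """Run the cascade: probability, binary label, and gated intensity per row.

    ``pain_label`` is 1 when probability >= threshold (ties count as pain);
    intensity is the regressor output clipped to [0, 100] for pain rows and
    exactly 0 otherwise.
    """
    missing = [
        c for c in model.selected_features
        if c not in feature_rows.columns
    ]
    if missing:
        raise ValidationError(f"rows are missing selected feature(s): {missing}")
    X, _ = standardize(feature_rows, scaler=model.scaler)
    Xs = X[model.selected_features].to_numpy()
    prob = model.classifier.predict_proba(Xs)[:, 1]
    label = (prob >= model.config.threshold).astype(int)
    intensity = np.zeros(len(prob))
    if model.regressor is not None and label.any():
        raw = model.regressor.predict(Xs[label == 1])
        intensity[label == 1] = np.clip(raw, 0.0, 100.0)
    return pd.DataFrame(
        {
            "pain_probability": prob,
            "pain_label": label,
            "intensity": intensity,
        },
        index=feature_rows.index,
    )


def save_model(model: CascadeModel, path) -> None:
    """Serialize the fitted cascade (scaler, feature list, both forests) to one archive."""
    joblib.dump(model, path)


def load_model(path) -> CascadeModel:
    model = joblib.load(path)
    if not isinstance(model, CascadeModel):
        raise ValidationError(f"{path} does not contain a CascadeModel")
    return model
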