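"""Feature assembly and the gradient-boosted decision-tree classifier.

Two feature variants of the same classifier are compared throughout:

``default``
    raw timing — the event day plus the elapsed times (lags) since the
    last, second-to-last, ... repetition of the (user, token) pair, up to
    ``max_lags`` columns (10 by default);
``ppe``
    cognition-engineered timing — the event day plus just two columns,
    the PPE model time ``T`` and the stability term of the decay rate.

Both variants see identical raw information; the ``ppe`` variant differs
only in the inductive bias of its preprocessing. Feature tables come in a
``slice`` mode (user, token and timing only — the near-universal features)
and a ``full`` mode that adds exercise metadata.

The classifier is LightGBM with native categorical splits, which handles
the thousands of user/token levels without one-hot blowup and routes
missing timing values (first exposures) through dedicated branches.
Single-class training labels produce a flagged *degenerate* model that
scores every row at the base rate; tiny training slices in the
limited-data experiments rely on that behavior to register chance-level
predictions rather than errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import lightgbm as lgb
import numpy as np
import pandas as pd

__all__ = [
    "CATEGORICAL_COLUMNS",
    "FULL_MODE_COLUMNS",
    "FeatureTable",
    "ModelConfig",
    "FittedModel",
    "build_feature_table",
    "train",
    "predict",
    "importance",
    "tune",
]

#: Columns treated as categorical when present.
CATEGORICAL_COLUMNS = [
    "user",
    "token",
    "format",
    "prompt",
    "root_dependency",
    "prev_token",
    "next_token",
    "session",
    "client",
]

#: Extra columns included in "full" mode when present in the log.
FULL_MODE_COLUMNS = [
    "format",
    "prompt",
    "root_dependency",
    "prev_token",
    "next_token",
    "session",
    "client",
    "seconds",
    "token_length",
    "exercise_total_tokens",
]

_VARIANTS = ("default", "ppe")


@dataclass
class FeatureTable:
    """A design matrix plus label vector for one model variant.

    ``frame`` holds the feature columns and the binary ``label`` column,
    row-aligned to the originating events.
    """

    frame: pd.DataFrame
    categorical: list[str]
    variant: str
    mode: str

    @property
    def feature_columns(self) -> list[str]:
        return [c for c in self.frame.columns if c != "label"]

    @property
    def X(self) -> pd.DataFrame:
        return self.frame[self.feature_columns]

    @property
    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=np.int8)

    def subset(self, mask) -> "FeatureTable":
        return FeatureTable(
            frame=self.frame[np.asarray(mask, dtype=bool)].reset_index(drop=True),
            categorical=list(self.categorical),
            variant=self.variant,
            mode=self.mode,
        )


@dataclass(frozen=True)
class ModelConfig:
    """Fixed, versioned boosting hyperparameters.

    Defaults give a reproducible baseline; :func:`tune` can refine them on
    a chronological validation split. ``min_child_samples`` doubles as the
    mechanism by which very small training slices yield constant
    (chance-level) scores: with fewer rows than the minimum leaf size no
    split is admissible.
    """

    n_estimators: int = 500
    num_leaves: int = 31
    learning_rate: float = 0.05
    min_child_samples: int = 10
    feature_fraction: float = 1.0
    bagging_fraction: float = 1.0
    bagging_freq: int = 0
    max_cat_to_onehot: int = 4
    cat_smooth: float = 10.0
    seed: int = 0

    def lgbm_params(self) -> dict:
        return {
            "n_estimators": self.n_estimators,
            "num_leaves": self.num_leaves,
            "learning_rate": self.learning_rate,
            "min_child_samples": self.min_child_samples,
            "colsample_bytree": self.feature_fraction,
            "subsample": self.bagging_fraction,
            "subsample_freq": self.bagging_freq,
            "max_cat_to_onehot": self.max_cat_to_onehot,
            "cat_smooth": self.cat_smooth,
            "random_state": self.seed,
            "n_jobs": 1,
            "deterministic": True,
            "force_row_wise": True,
            "verbose": -1,
        }


@dataclass
class FittedModel:
    """A trained ensemble plus the schema needed to score new rows."""

    config: ModelConfig
    columns: list[str]
    categorical: list[str]
    categories: dict[str, pd.Index] = field(default_factory=dict)
    booster: lgb.LGBMClassifier | None = None
    degenerate: bool = False
    base_rate: float = 0.5


def build_feature_table(
    log: pd.DataFrame,
    features: pd.DataFrame,
    variant: str = "ppe",
    mode: str = "slice",
    max_lags: int = 10,
) -> FeatureTable:
    """Assemble the design matrix for one variant from a log and its PPE features.

    ``slice`` mode keeps the near-universal columns only: user, token, day,
    and the variant's timing columns; ``full`` mode adds whatever exercise
    metadata the log carries. ``features`` must be the row-aligned output
    of :func:`ppeboost.ppe_features.annotate` on the same log.
    """
    if variant not in _VARIANTS:
        raise ValueError(f"variant must be one of {_VARIANTS}, got {variant!r}")
    if mode not in ("slice", "full"):
        raise ValueError(f"mode must be 'slice' or 'full', got {mode!r}")
    if len(log) != len(features):
        raise ValueError("features are not aligned to the log")

    cols: dict[str, pd.Series] = {
        "user": log["user"],
        "token": log["token"],
        "days": log["day"].astype(float),
    }
    if variant == "default":
        lag_names = [f"lag_{k}" for k in range(1, max_lags + 1)]
        missing = [c for c in lag_names if c not in features.columns]
        if missing:
            raise ValueError(f"features lack lag columns {missing}; re-annotate with max_lags={max_lags}")
        for c in lag_names:
            cols[c] = features[c].to_numpy()
    else:
        cols["model_time"] = features["model_time"].to_numpy()
        cols["stability"] = features["stability"].to_numpy()
    if mode == "full":
        for c in FULL_MODE_COLUMNS:
            if c in log.columns and not log[c].isna().all():
                cols[c] = log[c]
    frame = pd.DataFrame(cols, index=log.index).reset_index(drop=True)
    frame["label"] = log["label"].to_numpy(dtype=np.int8)
    categorical = [c for c in CATEGORICAL_COLUMNS if c in frame.columns]
    for c in categorical:
        frame[c] = frame[c].astype("category")
    for c in frame.columns:
        if c != "label" and c not in categorical:
            frame[c] = pd.to_numeric(frame[c], errors="raise").astype(float)
    return FeatureTable(frame=frame, categorical=categorical, variant=variant, mode=mode)


def train(table: FeatureTable, config: ModelConfig | None = None) -> FittedModel:
    """Fit the gradient-boosted classifier for P(label = 1).

    Deterministic given (data, config, seed). If the training labels are
    single-class the result is a flagged degenerate model whose score is
    the constant base rate.
    """
    config = config or ModelConfig()
    y = table.y
    model = FittedModel(
        config=config,
        columns=table.feature_columns,
        categorical=list(table.categorical),
    )
    classes = np.unique(y)
    if len(y) == 0 or len(classes) < 2:
        model.degenerate = True
        model.base_rate = float(y.mean()) if len(y) else 0.5
        return model
    X = table.X.copy()
    for c in table.categorical:
        model.categories[c] = X[c].cat.categories
    est = lgb.LGBMClassifier(objective="binary", **config.lgbm_params())
    est.fit(X, y, categorical_feature=table.categorical)
    model.booster = est
    model.base_rate = float(y.mean())
    return model


def predict(model: FittedModel, table: FeatureTable) -> np.ndarray:
    """Score rows with a fitted model; one probability of error per row.

    Columns are aligned by name to the training schema; categorical levels
    unseen in training are routed to the engine's missing branch.
    """
    missing = [c for c in model.columns if c not in table.frame.columns]
    if missing:
        raise ValueError(f"prediction table lacks training columns {missing}")
    n = len(table.frame)
    if model.degenerate or model.booster is None:
        return np.full(n, model.base_rate)
    if n == 0:
        return np.empty(0)
    X = table.frame[model.columns].copy()
    for c, cats in model.categories.items():
        X[c] = pd.Categorical(X[c].astype(object), categories=cats)
    return model.booster.predict_proba(X)[:, 1]


def importance(model: FittedModel) -> pd.DataFrame:
    """Normalized impurity-reduction feature importances, in percent.

    The share for a feature is the fraction of the total training-loss
    reduction attributable to splits on it; shares sum to 100. Degenerate
    models report all zeros.
    """
    if model.degenerate or model.booster is None:
        gains = np.zeros(len(model.columns))
    else:
        gains = model.booster.booster_.feature_importance(importance_type="gain").astype(float)
    total = gains.sum()
    pct = gains * 0.0 if total == 0 else 100.0 * gains / total
    out = pd.DataFrame({"feature": model.columns, "importance_pct": pct})
    return out.sort_values("importance_pct", ascending=False, ignore_index=True)


def tune(
    table: Sequence | FeatureTable,
    candidates: Sequence[ModelConfig],
    val_fraction: float = 0.1,
) -> ModelConfig:
    """Pick the candidate config with best AUC on a chronological validation split.

    The last ``val_fraction`` of each user's rows (stable order) form the
    validation set — no cross validation, respecting the temporal structure
    of learning data.
    """
    from .evaluation import auc  # local import to avoid a cycle

    if not candidates:
        raise ValueError("no candidate configs supplied")
    frame = table.frame
    grp = frame.groupby("user", sort=False, observed=True)
    n_fit = np.floor((1.0 - val_fraction) * grp["user"].transform("size")).astype(int)
    in_fit = (grp.cumcount() < n_fit).to_numpy()
    fit_t, val_t = table.subset(in_fit), table.subset(~in_fit)
    best, best_auc = candidates[0], -np.inf
    for cand in candidates:
        scores = predict(train(fit_t, cand), val_t)
        a = auc(val_t.y, scores)
        if a > best_auc:
            best, best_auc = cand, a
    return best


def with_seed(config: ModelConfig, seed: int) -> ModelConfig:
    """A copy of ``config`` with a different training seed."""
    return replace(config, seed=seed)
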