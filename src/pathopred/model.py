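"""Instance-weighted gradient-boosted-tree training and validation protocols.

The learner is a binary-logistic gradient boosted tree ensemble (XGBoost) in
which every training example carries a weight that scales its first- and
second-order gradient in the loss. Missing feature values are handled natively
through learned default split directions — no imputation. On top of the bare
learner this module implements the framework's validation protocols: k-fold
cross-validation in which only high-confidence core variants are ever held
out while add-on examples supplement every training fold, nested
cross-validation (inner loop for hyperparameter selection, outer loop for
unbiased performance estimation), and leave-one-variant-out scoring.

Trees are grown with the exact greedy method and a fixed base score of 0.5
(zero log-odds margin), which makes two contracts hold exactly: a zero-weight
example never affects the fit, and an example of weight 2 is equivalent to
the same example duplicated with weight 1 (subsampling off).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

from .errors import (
    ConfigurationError,
    DegenerateLabelsError,
    SchemaError,
    StratificationError,
)
from .metrics import MetricBundle, evaluate_binary
from .weighting import WeightConfig, apply_weight_config, rebalance

LABEL_TO_INT = {"positive": 1, "negative": 0}


@dataclass(frozen=True)
class AlgoHyperparams:
    """Algorithm-level hyperparameters of the boosted ensemble."""

    n_trees: int = 150
    max_depth: int = 4
    learning_rate: float = 0.1
    min_child_weight: float = 1.0
    subsample: float = 1.0
    colsample: float = 1.0
    seed: int = 0
    #: "exact" makes the zero-weight and weight-duplication contracts exact;
    #: "hist" trades that for speed on large training pools.
    tree_method: str = "exact"

    def __post_init__(self) -> None:
        if self.tree_method not in ("exact", "hist", "approx"):
            raise ConfigurationError(f"unknown tree_method {self.tree_method!r}")
        if self.n_trees < 0 or self.max_depth < 1:
            raise ConfigurationError("n_trees must be >= 0 and max_depth >= 1")
        if not (0.0 < self.subsample <= 1.0 and 0.0 < self.colsample <= 1.0):
            raise ConfigurationError("subsample and colsample must lie in (0, 1]")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")


@dataclass
class TrainedModel:
    """A fitted ensemble plus the feature-name order it expects.

    ``base_margin`` is the log-odds the empty ensemble predicts (0, since the
    base score is pinned at 0.5).
    """

    booster: xgb.Booster
    feature_names: list[str]
    base_margin: float = 0.0


@dataclass(frozen=True)
class FoldResult:
    """Train/validation balanced-PR areas for one cross-validation fold."""

    fold: int
    train_aubprc: float
    val_aubprc: float


def labels01(df: pd.DataFrame) -> np.ndarray:
    """Map the table's positive/negative labels onto {1, 0}."""
    bad = ~df["label"].isin(LABEL_TO_INT)
    if bad.any():
        raise DegenerateLabelsError("only positive/negative records may train")
    return df["label"].map(LABEL_TO_INT).to_numpy(dtype=int)


def _dmatrix(X: pd.DataFrame, feature_names: Sequence[str], **kwargs) -> xgb.DMatrix:
    missing = [c for c in feature_names if c not in X.columns]
    if missing:
        raise SchemaError(f"feature columns absent from table: {missing}")
    return xgb.DMatrix(
        X[list(feature_names)].to_numpy(dtype=float),
        feature_names=list(feature_names),
        missing=np.nan,
        nthread=1,
        **kwargs,
    )


def fit(
    X: pd.DataFrame,
    y: Sequence[int],
    weights: Sequence[float] | None,
    params: AlgoHyperparams = AlgoHyperparams(),
    feature_cols: Sequence[str] | None = None,
) -> TrainedModel:
    """Fit a weighted binary-logistic GBT ensemble.

    Requires at least one positively weighted example of each class; examples
    with weight zero have no effect on the fitted model.
    """
    y = np.asarray(y, dtype=int)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ConfigurationError("weights must be non-negative")
    if w[y == 1].sum() <= 0 or w[y == 0].sum() <= 0:
        raise DegenerateLabelsError(
            "training requires positive total weight on both classes"
        )
    feature_cols = list(feature_cols or X.columns)
    dtrain = _dmatrix(X, feature_cols, label=y, weight=w)
    booster = xgb.train(
        {
            "objective": "binary:logistic",
            "tree_method": params.tree_method,
            "base_score": 0.5,
            "eta": params.learning_rate,
            "max_depth": params.max_depth,
            "min_child_weight": params.min_child_weight,
            "subsample": params.subsample,
            "colsample_bytree": params.colsample,
            "seed": params.seed,
            "nthread": 1,
        },
        dtrain,
        num_boost_round=params.n_trees,
    )
    return TrainedModel(booster=booster, feature_names=feature_cols)


def predict(model: TrainedModel, X: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Score variants: returns (lod, score) with score = sigmoid(lod).

    The lod (log-odds margin) is more positive for inferred-pathogenic
    variants; the score maps it to (0, 1).
    """
    dm = _dmatrix(X, model.feature_names)
    lod = model.booster.predict(dm, output_margin=True)
    return lod, expit(lod)


def stack_training_sets(
    sets: Mapping[str, pd.DataFrame], weights: Mapping[str, np.ndarray]
) -> pd.DataFrame:
    """Concatenate per-set tables, attaching their weights in a column."""
    parts = []
    for set_id, df in sets.items():
        part = df.copy()
        part["weight"] = np.asarray(weights[set_id], dtype=float)
        if "set_id" not in part.columns:
            part["set_id"] = set_id
        parts.append(part)
    return pd.concat(parts, ignore_index=True)


def _stratified_folds(y: np.ndarray, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    if k < 2:
        raise StratificationError("k must be at least 2")
    if min((y == 1).sum(), (y == 0).sum()) < k:
        raise StratificationError(
            f"cannot stratify {k} folds: smaller class has fewer than {k} members"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(y)), y))


def cross_validate(
    core: pd.DataFrame,
    addons: Mapping[str, pd.DataFrame],
    feature_cols: Sequence[str],
    weight_config: WeightConfig,
    params: AlgoHyperparams = AlgoHyperparams(),
    k: int = 10,
    seed: int = 0,
    bp_target: float = 0.9,
) -> list[FoldResult]:
    """k-fold cross-validation with add-on supplementation.

    The core set is split into label-stratified folds; every training fold is
    the remaining core examples plus *all* add-on examples (add-ons are never
    held out), weighted per the weight configuration and rebalanced so total
    positive weight matches total negative weight. Validation folds contain
    core examples only and are scored unweighted; the train-side area is
    computed on the fold's core training portion, also unweighted.
    """
    y_core = labels01(core)
    sets = {"core": core, **addons}
    set_weights = apply_weight_config(sets, weight_config)
    core_w = set_weights["core"]
    addon_frames = [addons[s] for s in addons]
    addon_w = (
        np.concatenate([set_weights[s] for s in addons]) if addons else np.empty(0)
    )
    addon_X = (
        pd.concat(addon_frames, ignore_index=True)
        if addon_frames
        else core.iloc[0:0]
    )
    y_addon = labels01(addon_X) if len(addon_X) else np.empty(0, dtype=int)

    results = []
    for fold, (train_idx, val_idx) in enumerate(_stratified_folds(y_core, k, seed)):
        X_train = pd.concat([core.iloc[train_idx], addon_X], ignore_index=True)
        y_train = np.concatenate([y_core[train_idx], y_addon])
        w_train = rebalance(np.concatenate([core_w[train_idx], addon_w]), y_train)
        model = fit(X_train, y_train, w_train, params, feature_cols)
        lod_val, _ = predict(model, core.iloc[val_idx])
        lod_train, _ = predict(model, core.iloc[train_idx])
        results.append(
            FoldResult(
                fold=fold,
                train_aubprc=evaluate_binary(
                    lod_train, y_core[train_idx], bp_target
                ).aubprc_pointwise,
                val_aubprc=evaluate_binary(
                    lod_val, y_core[val_idx], bp_target
                ).aubprc_pointwise,
            )
        )
    return results


@dataclass
class OuterFoldOutcome:
    """One outer fold of nested cross-validation."""

    fold: int
    bundle: MetricBundle
    params: AlgoHyperparams
    weight_config: WeightConfig
    val_index: np.ndarray = field(repr=False, default=None)


def nested_cv(
    core: pd.DataFrame,
    addons: Mapping[str, pd.DataFrame],
    feature_cols: Sequence[str],
    search_space,
    outer_k: int = 10,
    inner_k: int = 10,
    n_trials: int = 300,
    seed: int = 0,
    select_window: int = 30,
) -> list[OuterFoldOutcome]:
    """Nested cross-validation: tune inside each outer-training core, test on
    the held-out outer fold.

    For each outer fold the sequential optimizer is run on the outer-training
    core (inner ``inner_k``-fold cross-validation, add-ons supplementing every
    inner fold), the early-stopping selector picks the final trial, a model is
    trained on the full outer-training data with the selected configuration,
    and a metric bundle is computed on the held-out outer core fold. Held-out
    outer records never enter any inner stage of their own outer loop.
    """
    from .tuning import run_search, select_final_trial  # local: avoids module cycle

    y_core = labels01(core)
    outcomes = []
    for fold, (train_idx, val_idx) in enumerate(
        _stratified_folds(y_core, outer_k, seed)
    ):
        inner_core = core.iloc[train_idx].reset_index(drop=True)
        trials = run_search(
            search_space,
            inner_core,
            addons,
            feature_cols,
            n_trials=n_trials,
            k=inner_k,
            seed=(seed * 10_007 + fold) % (2**31 - 1),
        )
        best = select_final_trial(trials, window=select_window)
        params, weight_config = search_space.decode(best.assignment)
        sets = {"core": inner_core, **addons}
        wmap = apply_weight_config(sets, weight_config)
        X_train = stack_training_sets(sets, wmap)
        y_train = labels01(X_train)
        w_train = rebalance(X_train["weight"].to_numpy(), y_train)
        model = fit(X_train, y_train, w_train, params, feature_cols)
        lod, _ = predict(model, core.iloc[val_idx])
        outcomes.append(
            OuterFoldOutcome(
                fold=fold,
                bundle=evaluate_binary(lod, y_core[val_idx]),
                params=params,
                weight_config=weight_config,
                val_index=np.asarray(val_idx),
            )
        )
    return outcomes


def loo_scores(
    records: pd.DataFrame,
    feature_cols: Sequence[str],
    params: AlgoHyperparams = AlgoHyperparams(),
) -> tuple[pd.DataFrame, int]:
    """Leave-one-variant-out scoring of the training variants.

    Each record with non-zero weight is scored by an ensemble retrained on all
    training data minus that record (same hyperparameters and seed);
    zero-weight records — which cannot influence the fit — receive the
    full-model score. Returns the scored table and the retrain count.
    """
    if "weight" not in records.columns:
        raise SchemaError("records must carry a 'weight' column")
    y = labels01(records)
    w = records["weight"].to_numpy(dtype=float)
    full = fit(records, y, w, params, feature_cols)
    lod, score = predict(full, records)
    lod, score = lod.copy(), score.copy()
    retrains = 0
    for i in np.flatnonzero(w > 0):
        mask = np.ones(len(records), dtype=bool)
        mask[i] = False
        model_i = fit(
            records.iloc[mask], y[mask], w[mask], params, feature_cols
        )
        lod_i, score_i = predict(model_i, records.iloc[[i]])
        lod[i], score[i] = lod_i[0], score_i[0]
        retrains += 1
    out = records[["protein_id", "position", "ref_aa", "alt_aa"]].copy()
    out["lod"] = lod
    out["score"] = score
    return out, retrains
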