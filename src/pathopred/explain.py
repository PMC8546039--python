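"""Shapley-based attribution of predictions and of model performance.

Every prediction's log-odds (lod) output is decomposed additively over
features and feature pairs with Shapley interaction values computed by the
tree ensemble itself (path-dependent tree traversal with cover-weighted
expectations): the result for one variant is a symmetric feature-by-feature
matrix whose diagonal holds individual contributions and whose off-diagonal
cells hold the halved pairwise interaction shares, satisfying

    base_value + sum(matrix) = lod        (to numerical tolerance).

Output contributions become *performance* contributions by signing them with
the training label (a contribution pushing a putatively benign variant toward
pathogenic hurt performance) and scaling by the tuned training weight.
Performance matrices are finally aggregated over training variants into
feature-group tables: a group's individual term folds in its within-group
interactions, pairwise differential terms sum both symmetric halves between
distinct groups, and the group total is individual plus all its pairwise
differentials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb

from .errors import ConfigurationError, SchemaError
from .model import TrainedModel, _dmatrix

LABEL_SIGN = {"positive": 1.0, "negative": -1.0, 1: 1.0, 0: -1.0}


@dataclass
class ContributionMatrix:
    """Shapley interaction decomposition of one prediction's lod."""

    base_value: float
    matrix: np.ndarray
    feature_names: list[str]

    @property
    def lod(self) -> float:
        return float(self.base_value + self.matrix.sum())


@dataclass
class GroupContributionTable:
    """Feature-group performance contributions (weighted over variants)."""

    partition: dict[str, str]
    individual: dict[str, float]
    pairwise: dict[str, dict[str, float]]

    @property
    def total(self) -> dict[str, float]:
        return {
            g: self.individual[g] + sum(self.pairwise[g].values())
            for g in self.individual
        }


def output_contributions(
    model: TrainedModel, X: pd.DataFrame
) -> list[ContributionMatrix]:
    """Per-variant Shapley interaction matrices of the model's lod output.

    The ensemble's own interaction-value computation is used; entries are
    symmetric and the additivity identity holds for every row.
    """
    dm = _dmatrix(X, model.feature_names)
    inter = model.booster.predict(dm, pred_interactions=True)
    out = []
    for m in inter:
        # last row/column belongs to the bias term
        base = float(m[-1, :].sum() + m[:-1, -1].sum())
        out.append(
            ContributionMatrix(
                base_value=base,
                matrix=np.array(m[:-1, :-1], dtype=float),
                feature_names=list(model.feature_names),
            )
        )
    return out


def performance_contributions(
    contrib: ContributionMatrix, label, weight: float
) -> np.ndarray:
    """Signed, weight-scaled contribution matrix of one training variant.

    Positive-labeled variants keep their sign; negative-labeled variants are
    negated (output pushing toward pathogenic hurt performance there). The
    result scales linearly with the tuned training weight.
    """
    if weight < 0:
        raise ConfigurationError("weight must be non-negative")
    try:
        sign = LABEL_SIGN[label]
    except (KeyError, TypeError):
        raise ConfigurationError(f"label must be positive/negative, got {label!r}")
    return sign * weight * contrib.matrix


def aggregate_group_contributions(
    matrices: Sequence[np.ndarray],
    weights: Sequence[float],
    partition: Mapping[str, str],
    feature_names: Sequence[str],
) -> GroupContributionTable:
    """Aggregate per-variant performance matrices into a feature-group table.

    ``matrices`` are already signed performance matrices; ``weights`` are the
    tuned training weights used for the weighted mean over variants. Every
    feature must be assigned to a group.
    """
    feature_names = list(feature_names)
    missing = [f for f in feature_names if f not in partition]
    if missing:
        raise ConfigurationError(f"features not assigned to any group: {missing}")
    weights = np.asarray(weights, dtype=float)
    if weights.sum() <= 0:
        raise ConfigurationError("total aggregation weight must be positive")
    stack = np.asarray(matrices, dtype=float)
    mean_matrix = np.tensordot(weights, stack, axes=(0, 0)) / weights.sum()

    groups = sorted(set(partition[f] for f in feature_names))
    index_of = {g: [i for i, f in enumerate(feature_names) if partition[f] == g] for g in groups}
    individual = {}
    pairwise: dict[str, dict[str, float]] = {g: {} for g in groups}
    for g in groups:
        gi = index_of[g]
        block = mean_matrix[np.ix_(gi, gi)]
        individual[g] = float(block.sum())  # diagonal plus within-group interactions
        for h in groups:
            if h == g:
                continue
            hi = index_of[h]
            # one cross-block of the symmetric matrix: half of the (g,h)
            # interaction mass, so that summing group totals conserves the
            # whole matrix (each cross cell counted exactly once overall)
            pairwise[g][h] = float(mean_matrix[np.ix_(gi, hi)].sum())
    return GroupContributionTable(
        partition=dict(partition), individual=individual, pairwise=pairwise
    )
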