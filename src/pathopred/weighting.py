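"""Per-variant training weights from logistic functions of quality properties.

Each training set (core or add-on) is associated with zero or more
quality-informative properties. Every property feeds a three-parameter
logistic ``L / (1 + exp(-k * (x - x0)))`` — maximum weight ``L`` in (0, 1],
midpoint ``x0`` on the transformed property scale, growth rate ``k`` of free
sign — and a variant's weight is the product of its set's logistic factors.
The logistic parameters are hyperparameters tuned jointly with the learner.
After weighting, positive-example weights are rescaled so the total positive
weight equals the total negative weight.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ConfigurationError, RebalanceError

logger = logging.getLogger(__name__)

TRANSFORMS = ("identity", "neg_log10")


@dataclass(frozen=True)
class LogisticWeightFn:
    """One logistic weighting factor: maximum L, midpoint x0, growth rate k."""

    L: float = 1.0
    x0: float = 0.0
    k: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.L <= 1.0):
            raise ConfigurationError(f"L must lie in (0, 1], got {self.L}")
        if not math.isfinite(self.k) or not math.isfinite(self.x0):
            raise ConfigurationError("k and x0 must be finite")


@dataclass(frozen=True)
class PropertyWeight:
    """A (property, transform, logistic) triple applied to one training set."""

    property_name: str
    transform: str = "identity"
    fn: LogisticWeightFn = LogisticWeightFn()

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ConfigurationError(f"unknown transform {self.transform!r}")


@dataclass
class WeightConfig:
    """Per-set lists of property weight functions; unlisted sets weigh 1."""

    per_set: dict[str, list[PropertyWeight]] = field(default_factory=dict)

    def for_set(self, set_id: str) -> list[PropertyWeight]:
        return self.per_set.get(set_id, [])


def logistic_weight(x: float, fn: LogisticWeightFn) -> float:
    """Evaluate ``L / (1 + exp(-k (x - x0)))`` with saturating arithmetic."""
    return float(fn.L * expit(fn.k * (x - fn.x0)))


def neg_log10(values: np.ndarray) -> np.ndarray:
    """-log10 transform for frequency-scale properties.

    Missing and zero values map to -log10 of half the smallest positive value
    observed in the input (one notch rarer than anything detected), keeping
    undetected variants on the rare end of the scale.
    """
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, np.nan)
    positive = values > 0
    if positive.any():
        floor = values[positive].min() / 2.0
    else:
        floor = np.finfo(float).tiny
    filled = np.where(positive, values, floor)
    out = -np.log10(filled)
    if (~positive).any():
        logger.debug(
            "neg_log10: %d undetected values mapped to -log10(%g)",
            int((~positive).sum()),
            floor,
        )
    return out


def set_weights(
    records: pd.DataFrame,
    specs: Sequence[PropertyWeight],
) -> np.ndarray:
    """Weights for the records of one training set.

    The weight is the product over the set's configured properties of the
    logistic factor of the (transformed) property value. A record missing a
    configured property contributes the neutral factor L/2 for it; an empty
    property list gives every record weight 1.
    """
    n = len(records)
    weights = np.ones(n, dtype=float)
    for spec in specs:
        if spec.property_name not in records.columns:
            raise ConfigurationError(
                f"property {spec.property_name!r} absent from records"
            )
        values = records[spec.property_name].to_numpy(dtype=float)
        if spec.transform == "neg_log10":
            values = neg_log10(values)
        factors = np.empty(n, dtype=float)
        missing = ~np.isfinite(values)
        if missing.any():
            logger.warning(
                "%d records missing property %r: neutral factor L/2 used",
                int(missing.sum()),
                spec.property_name,
            )
        factors[missing] = spec.fn.L / 2.0
        if (~missing).any():
            factors[~missing] = spec.fn.L * expit(
                spec.fn.k * (values[~missing] - spec.fn.x0)
            )
        weights *= factors
    return weights


def apply_weight_config(
    sets: Mapping[str, pd.DataFrame], config: WeightConfig
) -> dict[str, np.ndarray]:
    """Weights for every training set under one weight configuration."""
    return {set_id: set_weights(df, config.for_set(set_id)) for set_id, df in sets.items()}


def rebalance(weights: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Rescale positive weights so total positive weight equals total negative.

    Negative weights are untouched. Raises :class:`RebalanceError` when either
    side has zero total weight.
    """
    weights = np.asarray(weights, dtype=float)
    labels = np.asarray(labels).astype(bool)
    pos_total = weights[labels].sum()
    neg_total = weights[~labels].sum()
    if pos_total <= 0 or neg_total <= 0:
        raise RebalanceError(
            f"cannot rebalance: total positive weight {pos_total}, "
            f"total negative weight {neg_total}"
        )
    out = weights.copy()
    out[labels] *= neg_total / pos_total
    return out
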