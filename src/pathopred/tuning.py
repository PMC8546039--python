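"""Joint Bayesian optimization of learner and weight-function hyperparameters.

All hyperparameters — the boosted-tree settings and the (L, x0, k) of every
logistic weight function — are searched jointly. The optimizer is a seeded
sequential model-based search in the tree-structured-Parzen-estimator family:
after a uniform random start-up phase, observed trials are split into a
good and a bad fraction by objective, each dimension's good and bad values are
modeled with Parzen (Gaussian kernel) densities, candidates are drawn from the
good density and ranked by the good/bad density ratio — the quantity whose
maximization is equivalent to maximizing expected improvement. Each trial is
scored by k-fold cross-validation on the core set (add-ons supplementing every
training fold) with the objective being the mean validation balanced-PR area.

Because repeated interrogation of the validation folds can overfit the
hyperparameters themselves, the final trial is picked by an early-stopping
rule rather than by the best objective: trials are ordered by mean *training*
area, a moving average of the validation objective is computed along that
order, and the first window where the moving average starts to descend (the
"fittest region" before validation performance decays) supplies the trial
with the best validation objective.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, PathopredError
from .model import AlgoHyperparams, FoldResult, cross_validate
from .weighting import LogisticWeightFn, PropertyWeight, WeightConfig, neg_log10

logger = logging.getLogger(__name__)

#: Default search ranges for the learner; all overridable per dimension.
DEFAULT_ALGO_RANGES: dict[str, tuple] = {
    "n_trees": ("int", 50, 500),
    "max_depth": ("int", 3, 10),
    "learning_rate": ("loguniform", 0.01, 0.3),
    "min_child_weight": ("uniform", 0.5, 10.0),
    "subsample": ("uniform", 0.6, 1.0),
    "colsample": ("uniform", 0.6, 1.0),
}
#: Ranges for the logistic weight parameters; x0 spans the observed property
#: quantiles on the transformed scale.
L_RANGE = (0.1, 1.0)
K_RANGE = (-20.0, 20.0)
X0_QUANTILES = (0.01, 0.99)


@dataclass(frozen=True)
class Dim:
    """One search dimension: uniform, log-uniform, or integer-uniform."""

    name: str
    kind: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "loguniform", "int"):
            raise ConfigurationError(f"unknown dimension kind {self.kind!r}")
        if not self.lo < self.hi:
            raise ConfigurationError(f"empty range for {self.name}")
        if self.kind == "loguniform" and self.lo <= 0:
            raise ConfigurationError("log-uniform range must be positive")

    def to_internal(self, x: float) -> float:
        return math.log(x) if self.kind == "loguniform" else float(x)

    def from_internal(self, u: float) -> float:
        x = math.exp(u) if self.kind == "loguniform" else u
        x = min(max(x, self.lo), self.hi)
        return int(round(x)) if self.kind == "int" else float(x)

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "loguniform":
            return self.from_internal(rng.uniform(math.log(self.lo), math.log(self.hi)))
        return self.from_internal(rng.uniform(self.lo, self.hi))

    @property
    def internal_bounds(self) -> tuple[float, float]:
        if self.kind == "loguniform":
            return math.log(self.lo), math.log(self.hi)
        return self.lo, self.hi


@dataclass
class SearchSpace:
    """Joint space of learner and per-set logistic-weight hyperparameters.

    ``weight_props`` lists, per training set, the (property, transform) pairs
    to hyperparameterize; every pair contributes an L, x0 and k dimension,
    with the x0 range taken from the observed 1st-99th percentile of the
    transformed property.
    """

    dims: list[Dim]
    weight_props: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    #: algorithm settings held fixed (not searched), e.g. {"tree_method": "hist"}
    fixed_algo: dict = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        sets: Mapping[str, pd.DataFrame],
        weight_props: Mapping[str, Sequence[tuple[str, str]]] | None = None,
        algo_ranges: Mapping[str, tuple] | None = None,
        fixed_algo: Mapping[str, object] | None = None,
    ) -> "SearchSpace":
        ranges = {**DEFAULT_ALGO_RANGES, **(algo_ranges or {})}
        # a None override removes the dimension (the fixed default applies)
        dims = [Dim(name, *spec) for name, spec in ranges.items() if spec is not None]
        wp = {k: list(v) for k, v in (weight_props or {}).items()}
        for set_id, props in wp.items():
            if set_id not in sets:
                raise ConfigurationError(f"weighted set {set_id!r} not provided")
            for prop, transform in props:
                values = sets[set_id][prop].to_numpy(dtype=float)
                if transform == "neg_log10":
                    values = neg_log10(values)
                values = values[np.isfinite(values)]
                if len(values) == 0:
                    raise ConfigurationError(
                        f"no finite values of {prop!r} in set {set_id!r}"
                    )
                lo, hi = np.quantile(values, X0_QUANTILES)
                if not lo < hi:
                    lo, hi = lo - 0.5, hi + 0.5
                prefix = f"w::{set_id}::{prop}"
                dims.append(Dim(f"{prefix}::L", "uniform", *L_RANGE))
                dims.append(Dim(f"{prefix}::x0", "uniform", float(lo), float(hi)))
                dims.append(Dim(f"{prefix}::k", "uniform", *K_RANGE))
        return cls(dims=dims, weight_props=wp, fixed_algo=dict(fixed_algo or {}))

    def sample(self, rng: np.random.Generator) -> dict[str, float]:
        return {d.name: d.sample(rng) for d in self.dims}

    def decode(self, assignment: Mapping[str, float]) -> tuple[AlgoHyperparams, WeightConfig]:
        """Split a flat assignment into learner params and a weight config."""
        algo_kwargs = {
            name: assignment[name] for name in DEFAULT_ALGO_RANGES if name in assignment
        }
        if "n_trees" in algo_kwargs:
            algo_kwargs["n_trees"] = int(algo_kwargs["n_trees"])
        if "max_depth" in algo_kwargs:
            algo_kwargs["max_depth"] = int(algo_kwargs["max_depth"])
        params = AlgoHyperparams(**{**self.fixed_algo, **algo_kwargs})
        per_set: dict[str, list[PropertyWeight]] = {}
        for set_id, props in self.weight_props.items():
            specs = []
            for prop, transform in props:
                prefix = f"w::{set_id}::{prop}"
                specs.append(
                    PropertyWeight(
                        property_name=prop,
                        transform=transform,
                        fn=LogisticWeightFn(
                            L=float(assignment[f"{prefix}::L"]),
                            x0=float(assignment[f"{prefix}::x0"]),
                            k=float(assignment[f"{prefix}::k"]),
                        ),
                    )
                )
            per_set[set_id] = specs
        return params, WeightConfig(per_set=per_set)


@dataclass
class TrialRecord:
    """One evaluated hyperparameter assignment."""

    trial_id: int
    assignment: dict[str, float]
    mean_train_aubprc: float
    mean_val_aubprc: float
    fold_results: list[FoldResult] = field(default_factory=list)
    failed: bool = False


def _parzen_logpdf(x: np.ndarray, points: np.ndarray, span: float) -> np.ndarray:
    """Log density of a Gaussian-kernel Parzen estimate at ``x``."""
    n = len(points)
    bw = max(points.std(ddof=0) * n ** (-0.2), 1e-3 * span)
    z = (x[:, None] - points[None, :]) / bw
    log_k = -0.5 * z**2 - 0.5 * math.log(2 * math.pi) - math.log(bw)
    return np.logaddexp.reduce(log_k, axis=1) - math.log(n)


def _suggest(
    space: SearchSpace,
    history: list[TrialRecord],
    rng: np.random.Generator,
    n_startup: int,
    gamma: float,
    n_candidates: int,
) -> dict[str, float]:
    finished = [t for t in history if not t.failed]
    if len(history) < n_startup or len(finished) < 4:
        return space.sample(rng)
    objectives = np.array([t.mean_val_aubprc for t in finished])
    n_good = max(2, int(math.ceil(gamma * len(finished))))
    good_idx = sorted(np.argsort(-objectives)[:n_good].tolist())
    assignment = {}
    for dim in space.dims:
        values = np.array([dim.to_internal(t.assignment[dim.name]) for t in finished])
        good = values[good_idx]
        bad = np.delete(values, good_idx)
        lo, hi = dim.internal_bounds
        span = hi - lo
        bw = max(good.std(ddof=0) * len(good) ** (-0.2), 1e-3 * span)
        cand = good[rng.integers(0, len(good), size=n_candidates)]
        cand = np.clip(cand + rng.normal(0.0, bw, size=n_candidates), lo, hi)
        score = _parzen_logpdf(cand, good, span)
        if len(bad):
            score = score - _parzen_logpdf(cand, bad, span)
        assignment[dim.name] = dim.from_internal(float(cand[int(np.argmax(score))]))
    return assignment


def run_search(
    space: SearchSpace,
    core: pd.DataFrame,
    addons: Mapping[str, pd.DataFrame],
    feature_cols: Sequence[str],
    n_trials: int = 300,
    k: int = 10,
    seed: int = 0,
    n_startup: int = 10,
    gamma: float = 0.25,
    n_candidates: int = 24,
) -> list[TrialRecord]:
    """Sequential model-based hyperparameter search.

    Every trial is evaluated with the same seeded ``k``-fold core split
    (objective: mean validation balanced-PR area). A trial whose evaluation
    raises is recorded with a -inf objective and the search continues.
    Reproducible: the same seed yields the same trial sequence.
    """
    rng = np.random.default_rng(seed)
    trials: list[TrialRecord] = []
    for trial_id in range(n_trials):
        assignment = _suggest(space, trials, rng, n_startup, gamma, n_candidates)
        try:
            params, weight_config = space.decode(assignment)
            folds = cross_validate(
                core, addons, feature_cols, weight_config, params, k=k, seed=seed
            )
            trials.append(
                TrialRecord(
                    trial_id=trial_id,
                    assignment=assignment,
                    mean_train_aubprc=float(np.mean([f.train_aubprc for f in folds])),
                    mean_val_aubprc=float(np.mean([f.val_aubprc for f in folds])),
                    fold_results=folds,
                )
            )
        except PathopredError as exc:
            logger.warning("trial %d failed: %s", trial_id, exc)
            trials.append(
                TrialRecord(
                    trial_id=trial_id,
                    assignment=assignment,
                    mean_train_aubprc=-np.inf,
                    mean_val_aubprc=-np.inf,
                    failed=True,
                )
            )
    return trials


def select_final_trial(trials: Sequence[TrialRecord], window: int = 30) -> TrialRecord:
    """Early-stopping trial selection against hyperparameter overfitting.

    Trials are sorted by mean training area ascending (stable: ties keep trial
    order); moving averages of the validation objective over consecutive
    blocks of ``window`` trials (stride 1) are scanned for the first strict
    descent, and the trial with the best validation objective inside that
    window is returned. If no window descends the last window is used; with
    fewer trials than ``window`` the single window is all trials. Failed
    trials carry -inf objectives, sort first, and can never be selected unless
    every trial failed.
    """
    if not trials:
        raise ConfigurationError("no trials to select from")
    ordered = sorted(trials, key=lambda t: t.mean_train_aubprc)
    vals = np.array([t.mean_val_aubprc for t in ordered])
    if len(ordered) <= window:
        block = ordered
    else:
        n_windows = len(ordered) - window + 1
        means = np.array([vals[i : i + window].mean() for i in range(n_windows)])
        chosen = n_windows - 1
        for i in range(1, n_windows):
            if means[i] < means[i - 1]:
                chosen = i
                break
        block = ordered[chosen : chosen + window]
    return max(block, key=lambda t: t.mean_val_aubprc)
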