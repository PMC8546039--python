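"""Moving-window discovery of quality-informative training-set properties.

To decide whether a per-variant property (allele frequency, review stars,
functional-score label confidence, ...) predicts the *training utility* of an
add-on set, the add-on examples are ordered by the property and swept with
overlapping fixed-size windows. Each window's utility is the mean
cross-validated balanced-PR area obtained on the core set when every training
fold is supplemented with that window's examples (unweighted, default
algorithm hyperparameters; validation folds stay core-only). The observed
correlation between window index and utility is then compared against the
correlations from random orderings of the same examples via a Z score; a
property with |Z| > 1 is called informative, the sign giving the direction of
the quality trend.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError
from .metrics import evaluate_binary
from .model import AlgoHyperparams, _stratified_folds, fit, labels01, predict


@dataclass(frozen=True)
class WindowSpec:
    """Half-open slice [start, end) of the property-ordered add-on examples."""

    index: int
    start: int
    end: int


@dataclass
class InformativenessResult:
    """Outcome of a moving-window property screen."""

    property_name: str
    r_observed: float
    random_rs: list[float]
    z: float
    informative: bool
    window_utilities: list[tuple[int, float]]
    degenerate: bool = False


def make_windows(X: int, n_windows: int, fraction: float) -> list[WindowSpec]:
    """Fixed-size overlapping windows over ``X`` ordered examples.

    Window size is ``X * fraction`` rounded to the nearest integer; the step
    between successive window starts is ``floor(X * (1 - fraction) /
    (n_windows - 1))`` clamped to at least 1. Windows are clipped at ``X`` (the
    final windows may hold fewer than ``X * fraction`` examples) and empty
    windows are discarded, so fewer than ``n_windows`` may be returned.
    """
    if X < 2:
        raise ConfigurationError("need at least two examples to window")
    if n_windows < 2:
        raise ConfigurationError("n_windows must be at least 2 (step undefined)")
    if not 0.0 < fraction < 1.0:
        raise ConfigurationError("fraction must lie strictly in (0, 1)")
    size = int(np.floor(X * fraction + 0.5))
    step = max(1, int(np.floor(X * (1.0 - fraction) / (n_windows - 1))))
    windows = []
    for j in range(n_windows):
        start = j * step
        end = min(start + size, X)
        if start >= end:
            continue
        windows.append(WindowSpec(index=len(windows), start=start, end=end))
    return windows


def window_utility(
    core: pd.DataFrame,
    addon_window: pd.DataFrame,
    feature_cols: Sequence[str],
    params: AlgoHyperparams = AlgoHyperparams(),
    k: int = 10,
    seed: int = 0,
) -> float:
    """Mean core-validation balanced-PR area with one add-on window supplementing
    every training fold (unweighted; deterministic given the seed)."""
    y_core = labels01(core)
    folds = _stratified_folds(y_core, k, seed)
    return _window_utility(core, y_core, addon_window, feature_cols, params, folds)


def _window_utility(core, y_core, addon_window, feature_cols, params, folds) -> float:
    y_addon = (
        labels01(addon_window) if len(addon_window) else np.empty(0, dtype=int)
    )
    vals = []
    for train_idx, val_idx in folds:
        X_train = pd.concat(
            [core.iloc[train_idx], addon_window], ignore_index=True
        )
        y_train = np.concatenate([y_core[train_idx], y_addon])
        model = fit(X_train, y_train, None, params, feature_cols)
        lod, _ = predict(model, core.iloc[val_idx])
        vals.append(evaluate_binary(lod, y_core[val_idx]).aubprc_pointwise)
    return float(np.mean(vals))


def _ordering_correlation(
    core, y_core, ordered_addon, windows, feature_cols, params, folds
) -> tuple[float, list[float]]:
    utils = [
        _window_utility(
            core,
            y_core,
            ordered_addon.iloc[w.start : w.end],
            feature_cols,
            params,
            folds,
        )
        for w in windows
    ]
    arr = np.asarray(utils)
    if np.allclose(arr, arr[0]):
        return np.nan, utils
    r, _ = stats.pearsonr(np.arange(len(utils)), arr)
    return float(r), utils


def property_informativeness(
    core: pd.DataFrame,
    addon: pd.DataFrame,
    property_name: str,
    feature_cols: Sequence[str],
    n_windows: int = 100,
    fraction: float = 0.5,
    n_random: int = 10,
    seed: int = 0,
    k: int = 10,
    params: AlgoHyperparams = AlgoHyperparams(),
) -> InformativenessResult:
    """Screen one candidate property of one add-on set (or a concatenation of
    logically related sets) for quality-informativeness.

    Missing property values sort last. The Z score compares the observed
    index-utility Pearson correlation with the mean and standard deviation of
    the correlations from ``n_random`` seeded random orderings; zero variance
    among the random correlations (or constant utilities) flags the result
    degenerate with an undefined Z.
    """
    if property_name not in addon.columns:
        raise ConfigurationError(f"add-on set lacks property {property_name!r}")
    values = addon[property_name]
    if values.nunique(dropna=True) < 2:
        raise ConfigurationError(
            f"property {property_name!r} is constant: ordering degenerate"
        )
    rng = np.random.default_rng(seed)
    y_core = labels01(core)
    folds = _stratified_folds(y_core, k, seed)
    windows = make_windows(len(addon), n_windows, fraction)

    ordered = addon.sort_values(
        property_name, kind="stable", na_position="last"
    ).reset_index(drop=True)
    r_obs, utils = _ordering_correlation(
        core, y_core, ordered, windows, feature_cols, params, folds
    )
    random_rs = []
    for _ in range(n_random):
        perm = addon.iloc[rng.permutation(len(addon))].reset_index(drop=True)
        r, _ = _ordering_correlation(
            core, y_core, perm, windows, feature_cols, params, folds
        )
        random_rs.append(r)
    rand = np.asarray(random_rs, dtype=float)
    degenerate = bool(np.isnan(r_obs) or np.isnan(rand).any())
    sd = rand.std(ddof=1) if not degenerate else np.nan
    if degenerate or sd == 0:
        z = np.nan
        degenerate = True
    else:
        z = float((r_obs - rand.mean()) / sd)
    return InformativenessResult(
        property_name=property_name,
        r_observed=r_obs,
        random_rs=random_rs,
        z=z,
        informative=bool(not degenerate and abs(z) > 1.0),
        window_utilities=[(w.index, u) for w, u in zip(windows, utils)],
        degenerate=degenerate,
    )
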