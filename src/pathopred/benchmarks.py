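"""Standard synthetic benchmark protocols for the framework's two headline
claims: moving-window detection of quality-informative properties, and the
performance gain of tuned variant weighting over unweighted training.

Problem sizes here are desk-scale: the moving-window screen uses a 600-variant
core, one 2,000-variant add-on set, ten windows and five core folds; the
weighting ablation uses a 2,000-variant core, three 3,000-variant add-on sets,
30 search trials and 5 outer / 3 inner folds, with a small-tree search space
and histogram-based tree growth. docs/methods.md discusses these choices.
"""

from __future__ import annotations

import numpy as np

from .model import AlgoHyperparams, nested_cv
from .synthetic import AddonSpec, SyntheticConfig, default_benchmark_config, generate_benchmark
from .tuning import SearchSpace
from .weighting import set_weights
from .windows import property_informativeness

#: Settings for the moving-window screen: enough capacity that label noise in
#: a supplementing window measurably hurts core validation performance.
WINDOW_PARAMS = AlgoHyperparams(n_trees=100, max_depth=4, tree_method="hist")
ABLATION_ALGO_RANGES = {
    "n_trees": ("int", 60, 150),
    "max_depth": ("int", 3, 5),
    "learning_rate": ("loguniform", 0.05, 0.3),
    "min_child_weight": None,
    "subsample": None,
    "colsample": None,
}


def window_screen_config(seed: int, rising_noise: bool = True) -> SyntheticConfig:
    """Scenario for the moving-window screen: one 2,000-example add-on whose
    label-flip probability either rises 0.05 to 0.45 with its quality property
    or stays flat at the same mean level (property-independent noise)."""
    flip = (0.05, 0.45) if rising_noise else (0.25, 0.25)
    return SyntheticConfig(
        n_core=600,
        class_separation=1.5,
        addon_specs=(
            AddonSpec(id="addon", n=2000, source="humsavar",
                      flip_lo=flip[0], flip_hi=flip[1]),
        ),
        seed=seed,
    )


def window_detection_z(seed: int, rising_noise: bool = True):
    """Run the moving-window screen on the scenario above; returns the
    informativeness result (Z < -1 expected when noise rises with the
    property)."""
    config = window_screen_config(seed, rising_noise)
    tables = generate_benchmark(config)
    return property_informativeness(
        tables["core"],
        tables["addon"],
        "uncertainty",
        config.feature_cols,
        n_windows=8,
        fraction=0.25,
        n_random=10,
        seed=seed,
        k=5,
        params=WINDOW_PARAMS,
    )


def weighting_ablation(seed: int, n_trials: int = 30, outer_k: int = 5,
                       inner_k: int = 3) -> dict:
    """Tuned weighted training vs the all-weights-1 ablation, nested CV.

    Both arms tune the learner with the same budget; the weighted arm
    additionally tunes a logistic weight function of the noisy add-on set's
    quality property (the property the moving-window screen flags). Returns
    mean outer-fold balanced-PR areas for both arms plus the mean tuned weight
    of the cleanest and noisiest add-on deciles (by the quality property) under
    the first outer fold's selected configuration.
    """
    config = default_benchmark_config(seed)
    tables = generate_benchmark(config)
    core = tables["core"]
    addons = {k: v for k, v in tables.items() if k != "core"}
    fc = config.feature_cols
    fixed = {"tree_method": "hist"}

    weighted_space = SearchSpace.build(
        {"core": core, **addons},
        weight_props={"addon_noisy": [("uncertainty", "identity")]},
        algo_ranges=ABLATION_ALGO_RANGES,
        fixed_algo=fixed,
    )
    unweighted_space = SearchSpace.build(
        {"core": core, **addons},
        weight_props={},
        algo_ranges=ABLATION_ALGO_RANGES,
        fixed_algo=fixed,
    )
    common = dict(outer_k=outer_k, inner_k=inner_k, n_trials=n_trials,
                  seed=seed, select_window=n_trials)
    weighted = nested_cv(core, addons, fc, weighted_space, **common)
    unweighted = nested_cv(core, addons, fc, unweighted_space, **common)

    noisy = addons["addon_noisy"]
    w_noisy = set_weights(noisy, weighted[0].weight_config.for_set("addon_noisy"))
    prop = noisy["uncertainty"].to_numpy()
    deciles = np.quantile(prop, [0.1, 0.9])
    return {
        "weighted_aubprc": float(np.mean([o.bundle.aubprc_pointwise for o in weighted])),
        "unweighted_aubprc": float(np.mean([o.bundle.aubprc_pointwise for o in unweighted])),
        "weighted_folds": [o.bundle.aubprc_pointwise for o in weighted],
        "unweighted_folds": [o.bundle.aubprc_pointwise for o in unweighted],
        "cleanest_decile_weight": float(w_noisy[prop <= deciles[0]].mean()),
        "noisiest_decile_weight": float(w_noisy[prop >= deciles[1]].mean()),
    }
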