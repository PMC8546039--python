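import numpy as np
import pandas as pd
import pytest

from pathopred.errors import (
    ConfigurationError,
    DegenerateLabelsError,
    SchemaError,
    StratificationError,
)
from pathopred.model import (
    AlgoHyperparams,
    cross_validate,
    fit,
    labels01,
    loo_scores,
    nested_cv,
    predict,
)
from pathopred.tuning import SearchSpace
from pathopred.weighting import LogisticWeightFn, PropertyWeight, WeightConfig

from conftest import small_benchmark

EXACT = AlgoHyperparams(n_trees=20, max_depth=3)  # subsampling off, exact splits


def _xy(rng, n=50, d=3):
    X = pd.DataFrame(rng.normal(size=(n, d)), columns=[f"x{i}" for i in range(d)])
    y = (X["x0"] + 0.5 * rng.normal(size=n) > 0).astype(int).to_numpy()
    return X, y


class TestFitPredict:
    def test_zero_weight_examples_have_no_effect(self, rng):
        X, y = _xy(rng)
        w = np.ones(len(y))
        extra = X.iloc[[0]].assign(x0=99.0)
        X2 = pd.concat([X, extra], ignore_index=True)
        y2 = np.r_[y, 1 - y[0]]
        w2 = np.r_[w, 0.0]
        lod_a, _ = predict(fit(X, y, w, EXACT), X)
        lod_b, _ = predict(fit(X2, y2, w2, EXACT, list(X.columns)), X)
        np.testing.assert_array_equal(lod_a, lod_b)

    def test_weight_two_equals_duplication(self, rng):
        X, y = _xy(rng)
        w = np.ones(len(y))
        w[7] = 2.0
        X_dup = pd.concat([X, X.iloc[[7]]], ignore_index=True)
        y_dup = np.r_[y, y[7]]
        lod_a, _ = predict(fit(X, y, w, EXACT), X)
        lod_b, _ = predict(fit(X_dup, y_dup, None, EXACT, list(X.columns)), X)
        np.testing.assert_array_equal(lod_a, lod_b)

    def test_linearly_separable_single_feature_perfect_training_auroc(self):
        from pathopred.metrics import evaluate_binary

        X = pd.DataFrame({"x": np.linspace(-1, 1, 50)})
        y = (X["x"] > 0).astype(int).to_numpy()
        model = fit(X, y, None, EXACT)
        lod, _ = predict(model, X)
        assert evaluate_binary(lod, y).auroc == 1.0

    def test_score_is_sigmoid_of_lod(self, rng):
        X, y = _xy(rng)
        model = fit(X, y, None, EXACT)
        lod, score = predict(model, X)
        np.testing.assert_allclose(score, 1.0 / (1.0 + np.exp(-lod)), rtol=1e-6)

    def test_zero_trees_gives_constant_base_margin(self, rng):
        X, y = _xy(rng)
        model = fit(X, y, None, AlgoHyperparams(n_trees=0))
        lod, score = predict(model, X)
        np.testing.assert_allclose(lod, 0.0, atol=1e-7)
        np.testing.assert_allclose(score, 0.5, atol=1e-7)

    def test_missing_features_handled_without_imputation(self, rng):
        X, y = _xy(rng, n=80)
        X.loc[::3, "x1"] = np.nan
        model = fit(X, y, None, EXACT)
        lod, _ = predict(model, X)
        assert np.isfinite(lod).all()

    def test_single_class_weight_rejected(self, rng):
        X, y = _xy(rng)
        w = np.where(y == 1, 0.0, 1.0)
        with pytest.raises(DegenerateLabelsError):
            fit(X, y, w, EXACT)

    def test_unknown_feature_name_rejected(self, rng):
        X, y = _xy(rng)
        model = fit(X, y, None, EXACT)
        with pytest.raises(SchemaError):
            predict(model, X.rename(columns={"x0": "q0"}))

    def test_deterministic_given_seed(self, rng):
        X, y = _xy(rng, n=100)
        p = AlgoHyperparams(n_trees=20, max_depth=3, subsample=0.7, seed=11)
        lod_a, _ = predict(fit(X, y, None, p), X)
        lod_b, _ = predict(fit(X, y, None, p), X)
        np.testing.assert_array_equal(lod_a, lod_b)


class TestCrossValidate:
    def _setup(self, seed=0):
        config, tables = small_benchmark(seed=seed)
        core = tables["core"]
        addons = {"addon": tables["addon"]}
        fc = config.feature_cols
        return core, addons, fc

    def test_fold_sizes_stratified_within_one(self):
        core, addons, fc = self._setup()
        from pathopred.model import _stratified_folds

        y = labels01(core)
        folds = _stratified_folds(y, 5, 0)
        for _, val_idx in folds:
            for cls in (0, 1):
                got = (y[val_idx] == cls).sum()
                expected = (y == cls).sum() / 5
                assert abs(got - expected) <= 1

    def test_no_core_leakage_and_addons_always_in_training(self):
        core, addons, fc = self._setup()
        results = cross_validate(
            core, addons, fc, WeightConfig(),
            AlgoHyperparams(n_trees=5, max_depth=2), k=4, seed=0,
        )
        assert [r.fold for r in results] == list(range(4))
        # leakage is structural: held-out indices never appear in the training
        # portion because the fold split partitions the core index set
        from pathopred.model import _stratified_folds

        y = labels01(core)
        for train_idx, val_idx in _stratified_folds(y, 4, 0):
            assert set(train_idx).isdisjoint(val_idx)
            assert len(set(train_idx) | set(val_idx)) == len(core)

    def test_weight_config_changes_results(self):
        core, addons, fc = self._setup()
        params = AlgoHyperparams(n_trees=10, max_depth=3)
        plain = cross_validate(core, addons, fc, WeightConfig(), params, k=3, seed=0)
        weighted = cross_validate(
            core, addons, fc,
            WeightConfig({"addon": [PropertyWeight(
                "uncertainty", "identity", LogisticWeightFn(1.0, 0.5, -15.0))]}),
            params, k=3, seed=0,
        )
        assert any(
            p.val_aubprc != w.val_aubprc for p, w in zip(plain, weighted)
        )

    def test_too_many_folds_rejected(self):
        core, addons, fc = self._setup()
        with pytest.raises(StratificationError):
            cross_validate(core.iloc[:8], {}, fc, WeightConfig(), k=10)


class TestNestedCV:
    def _space(self, core, addons):
        return SearchSpace.build(
            {"core": core, **addons},
            weight_props={"addon": [("uncertainty", "identity")]},
            algo_ranges={
                "n_trees": ("int", 5, 15),
                "max_depth": ("int", 2, 3),
                "learning_rate": ("loguniform", 0.1, 0.3),
                "min_child_weight": None,
                "subsample": None,
                "colsample": None,
            },
            fixed_algo={"tree_method": "hist"},
        )

    def test_smoke_returns_one_bundle_per_outer_fold(self):
        config, tables = small_benchmark(n_core=120, n_addon=150)
        core, addons = tables["core"], {"addon": tables["addon"]}
        outcomes = nested_cv(
            core, addons, config.feature_cols, self._space(core, addons),
            outer_k=3, inner_k=3, n_trials=4, seed=0,
        )
        assert len(outcomes) == 3
        assert all(0.0 <= o.bundle.aubprc_pointwise <= 1.0 for o in outcomes)

    def test_outer_validation_indices_partition_core(self):
        config, tables = small_benchmark(n_core=120, n_addon=150)
        core, addons = tables["core"], {"addon": tables["addon"]}
        outcomes = nested_cv(
            core, addons, config.feature_cols, self._space(core, addons),
            outer_k=3, inner_k=3, n_trials=3, seed=0,
        )
        all_val = np.concatenate([o.val_index for o in outcomes])
        assert sorted(all_val) == list(range(len(core)))  # disjoint and complete


class TestLooScores:
    def test_retrain_count_and_zero_weight_shortcut(self):
        config, tables = small_benchmark(n_core=40, n_addon=30)
        core = tables["core"].iloc[:30].copy()
        core["weight"] = 1.0
        core.loc[core.index[:5], "weight"] = 0.0
        params = AlgoHyperparams(n_trees=5, max_depth=2)
        scored, retrains = loo_scores(core, config.feature_cols, params)
        assert retrains == 25
        full = fit(core, labels01(core), core["weight"].to_numpy(), params,
                   config.feature_cols)
        lod_full, _ = predict(full, core.iloc[:5])
        np.testing.assert_array_equal(scored["lod"].to_numpy()[:5], lod_full)

    def test_deterministic_on_repeat(self):
        config, tables = small_benchmark(n_core=30, n_addon=30)
        core = tables["core"].iloc[:24].copy()
        core["weight"] = 1.0
        params = AlgoHyperparams(n_trees=4, max_depth=2)
        a, _ = loo_scores(core, config.feature_cols, params)
        b, _ = loo_scores(core, config.feature_cols, params)
        pd.testing.assert_frame_equal(a, b)

    def test_leaving_out_changes_scores_of_influential_variants(self):
        config, tables = small_benchmark(n_core=30, n_addon=30)
        core = tables["core"].iloc[:24].copy()
        core["weight"] = 1.0
        params = AlgoHyperparams(n_trees=10, max_depth=3)
        scored, _ = loo_scores(core, config.feature_cols, params)
        full = fit(core, labels01(core), core["weight"].to_numpy(), params,
                   config.feature_cols)
        lod_full, _ = predict(full, core)
        assert (scored["lod"].to_numpy() != lod_full).any()
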