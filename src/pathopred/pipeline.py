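"""End-to-end orchestration of the training workflow from one configuration.

Stage order: simulate (optional) -> label -> split -> windows (optional) ->
tune -> train -> eval. Every artifact lands in the configured output
directory; the manifest records each stage's artifacts together with the
config hash and root seed, and identical configurations reproduce identical
metrics.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import datasets, windows as windows_mod
from .config import RunConfig
from .errors import ConfigurationError, PathopredError
from .metrics import evaluate_binary
from .model import AlgoHyperparams, fit, labels01, predict, stack_training_sets
from .synthetic import AddonSpec, SyntheticConfig, generate_benchmark
from .tuning import SearchSpace, run_search, select_final_trial
from .weighting import apply_weight_config, rebalance

logger = logging.getLogger(__name__)


def _stage_seed(root_seed: int, stage: str) -> int:
    return (root_seed * 1_000_003 + sum(map(ord, stage))) % (2**31 - 1)


def _synthetic_config(cfg: RunConfig) -> SyntheticConfig:
    section = cfg.input.synthetic
    if section is None:
        raise ConfigurationError("simulate stage requires input.synthetic")
    return SyntheticConfig(
        n_core=section.n_core,
        n_features=section.n_features,
        class_separation=section.class_separation,
        missing_rate=section.missing_rate,
        addon_specs=tuple(
            AddonSpec(
                id=a.id,
                n=a.n,
                source=a.source,
                property_name=a.property_name,
                flip_lo=a.flip_lo,
                flip_hi=a.flip_hi,
                covariate_shift=a.covariate_shift,
                shift_axis=a.shift_axis,
            )
            for a in section.addons
        ),
        seed=_stage_seed(cfg.seed, "simulate"),
    )


def _feature_cols(df: pd.DataFrame, cfg: RunConfig) -> list[str]:
    schema = datasets.TableSchema.infer(df.columns, properties=cfg.candidate_properties)
    return schema.feature_cols


def run(config: RunConfig) -> dict:
    """Execute the configured stages; returns the artifact manifest."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    stages = list(config.stages)

    def record(stage: str, **artifacts: str) -> None:
        manifest["stages"][stage] = artifacts
        logger.info("stage %s done: %s", stage, artifacts)

    try:
        variants_path = config.input.variants
        if "simulate" in stages:
            tables = generate_benchmark(_synthetic_config(config))
            merged = pd.concat(tables.values(), ignore_index=True)
            merged = merged.drop(columns=["label", "primary_source", "set_id"])
            variants_path = str(out_dir / "variants.tsv")
            datasets.write_variant_table(merged, variants_path)
            record("simulate", variants=variants_path)
        if variants_path is None:
            raise ConfigurationError("no input variants: provide input.variants "
                                     "or a simulate stage")

        table = datasets.read_variant_table(
            variants_path, properties=config.candidate_properties
        )
        labeled = datasets.assign_labels(table)
        if "label" in stages:
            labeled_path = str(out_dir / "labeled.tsv")
            datasets.write_variant_table(labeled, labeled_path)
            record("label", labeled=labeled_path)

        flavor = datasets.ModelFlavor(name=config.flavor)
        sets = datasets.build_training_sets(labeled, flavor)
        core = sets.pop("core")
        feature_cols = _feature_cols(table, config)
        if "split" in stages:
            split_paths = {}
            for set_id, df in {"core": core, **sets}.items():
                p = str(out_dir / f"set_{set_id}.tsv")
                datasets.write_variant_table(df, p)
                split_paths[set_id] = p
            record("split", **split_paths)

        if "windows" in stages:
            window_artifacts = {}
            for prop in config.candidate_properties:
                for set_id, addon in sets.items():
                    if prop not in addon.columns or addon[prop].notna().sum() == 0:
                        continue
                    if addon[prop].nunique(dropna=True) < 2 or len(addon) < 10:
                        continue
                    res = windows_mod.property_informativeness(
                        core,
                        addon,
                        prop,
                        feature_cols,
                        n_windows=10,
                        k=min(config.folds.cv_k, 5),
                        seed=_stage_seed(config.seed, "windows"),
                        params=AlgoHyperparams(n_trees=40, max_depth=3),
                    )
                    p = str(out_dir / f"windows_{set_id}_{prop}.json")
                    with open(p, "w") as fh:
                        json.dump(
                            {
                                "property": res.property_name,
                                "set_id": set_id,
                                "r_observed": res.r_observed,
                                "z": None if np.isnan(res.z) else res.z,
                                "informative": res.informative,
                                "window_utilities": res.window_utilities,
                            },
                            fh,
                            indent=2,
                        )
                    window_artifacts[f"{set_id}:{prop}"] = p
            record("windows", **window_artifacts)

        weight_props = {
            set_id: [(w.property, w.transform) for w in props]
            for set_id, props in config.weight_props.items()
            if set_id == "core" or set_id in sets
        }
        algo_ranges = {}
        for name in ("n_trees", "max_depth", "learning_rate"):
            bounds = getattr(config.search, name)
            if bounds is not None:
                kind = "loguniform" if name == "learning_rate" else "int"
                algo_ranges[name] = (kind, bounds[0], bounds[1])
        space = SearchSpace.build(
            {"core": core, **sets}, weight_props, algo_ranges or None
        )

        if "tune" in stages:
            trials = run_search(
                space,
                core,
                sets,
                feature_cols,
                n_trials=config.search.n_trials,
                k=config.folds.cv_k,
                seed=_stage_seed(config.seed, "tune"),
            )
            best = select_final_trial(trials, window=config.search.select_window)
            trials_path = str(out_dir / "trials.tsv")
            pd.DataFrame(
                [
                    {
                        "trial_id": t.trial_id,
                        "mean_train_aubprc": t.mean_train_aubprc,
                        "mean_val_aubprc": t.mean_val_aubprc,
                        "failed": t.failed,
                        **t.assignment,
                    }
                    for t in trials
                ]
            ).to_csv(trials_path, sep="\t", index=False)
            selected_path = str(out_dir / "selected_trial.json")
            with open(selected_path, "w") as fh:
                json.dump(
                    {"trial_id": best.trial_id, "assignment": best.assignment,
                     "mean_val_aubprc": best.mean_val_aubprc},
                    fh,
                    indent=2,
                )
            record("tune", trials=trials_path, selected=selected_path)
            params, weight_config = space.decode(best.assignment)
        else:
            params, weight_config = space.decode(
                {d.name: (d.lo + d.hi) / 2 for d in space.dims}
            )

        model = None
        train_table = None
        if "train" in stages:
            all_sets = {"core": core, **sets}
            wmap = apply_weight_config(all_sets, weight_config)
            train_table = stack_training_sets(all_sets, wmap)
            y = labels01(train_table)
            w = rebalance(train_table["weight"].to_numpy(), y)
            train_table["weight"] = w
            model = fit(train_table, y, w, params, feature_cols)
            model_path = str(out_dir / "model.ubj.json")
            model.booster.save_model(model_path)
            meta_path = str(out_dir / "model_meta.json")
            with open(meta_path, "w") as fh:
                json.dump(
                    {"feature_cols": feature_cols, "params": vars(params).copy()},
                    fh,
                    indent=2,
                )
            weights_path = str(out_dir / "training_weights.tsv")
            train_table[
                ["protein_id", "position", "ref_aa", "alt_aa", "set_id", "weight"]
            ].to_csv(weights_path, sep="\t", index=False)
            record("train", model=model_path, meta=meta_path, weights=weights_path)

        if "eval" in stages:
            if model is None:
                raise ConfigurationError("eval stage requires the train stage")
            lod, _ = predict(model, core)
            bundle = evaluate_binary(lod, labels01(core))
            metrics_path = str(out_dir / "metrics.json")
            with open(metrics_path, "w") as fh:
                json.dump(
                    {
                        "prior": bundle.prior,
                        "auroc": bundle.auroc,
                        "auprc": bundle.auprc,
                        "aubprc_pointwise": bundle.aubprc_pointwise,
                        "aubprc_eq7": bundle.aubprc_eq7,
                        "r90bp": bundle.r90bp,
                        "note": "training-set evaluation on the core set",
                    },
                    fh,
                    indent=2,
                )
            record("eval", metrics=metrics_path)
    except PathopredError as exc:
        manifest["error"] = {"stage": "pipeline", "message": str(exc)}
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2))
        raise

    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    manifest["manifest_path"] = str(manifest_path)
    return manifest
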