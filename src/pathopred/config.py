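"""Declarative run configuration, validated before any compute.

The configuration is a single YAML document; unknown keys anywhere are
rejected with an error naming the key. All randomness in a run flows from the
one root seed, expanded deterministically per stage.
"""

from __future__ import annotations

import hashlib
import json
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigurationError


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class AddonSpecConfig(_StrictModel):
    id: str
    n: int = 3000
    source: str = "humsavar"
    property_name: str = "uncertainty"
    flip_lo: float = 0.05
    flip_hi: float = 0.45
    covariate_shift: float = 0.0
    shift_axis: Literal["random", "class"] = "random"


class SyntheticSection(_StrictModel):
    n_core: int = 2000
    n_features: int = 6
    class_separation: float = 2.0
    missing_rate: float = 0.0
    addons: list[AddonSpecConfig] = Field(default_factory=list)


class InputSection(_StrictModel):
    variants: Optional[str] = None  # path to a variant TSV
    synthetic: Optional[SyntheticSection] = None


class WeightPropConfig(_StrictModel):
    property: str
    transform: Literal["identity", "neg_log10"] = "identity"


class SearchSection(_StrictModel):
    n_trials: int = 300
    select_window: int = 30
    n_trees: Optional[list[int]] = None
    max_depth: Optional[list[int]] = None
    learning_rate: Optional[list[float]] = None


class FoldsSection(_StrictModel):
    cv_k: int = 10
    outer_k: int = 10
    inner_k: int = 10


class RunConfig(_StrictModel):
    """Top-level declarative configuration of a full pipeline run."""

    flavor: Literal["R", "ER"] = "R"
    input: InputSection = Field(default_factory=InputSection)
    candidate_properties: list[str] = Field(default_factory=list)
    weight_props: dict[str, list[WeightPropConfig]] = Field(default_factory=dict)
    search: SearchSection = Field(default_factory=SearchSection)
    folds: FoldsSection = Field(default_factory=FoldsSection)
    stages: list[
        Literal["simulate", "label", "split", "windows", "tune", "train", "eval"]
    ] = Field(default_factory=lambda: ["simulate", "label", "split", "tune", "train", "eval"])
    seed: int = 0
    output_dir: str = "pathopred_run"

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        try:
            return cls.model_validate(raw)
        except ValidationError as exc:
            locs = ", ".join(
                ".".join(str(p) for p in err["loc"]) or "<root>"
                for err in exc.errors()
            )
            raise ConfigurationError(f"invalid run configuration at: {locs}") from exc
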