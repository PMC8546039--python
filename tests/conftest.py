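import numpy as np
import pandas as pd
import pytest

from pathopred import AlgoHyperparams, fit
from pathopred.synthetic import AddonSpec, SyntheticConfig, generate_benchmark


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def variant_tsv_text():
    """A small variant table exercising every annotation source and missing cells."""
    rows = [
        "protein_id\tposition\tref_aa\talt_aa\tmaf\tclinvar_assertion\tclinvar_stars"
        "\thgmd_present\thumsavar_assertion\tmave_score\tgnomad_hom\tgnomad_af"
        "\tfeature_1\tfeature_2",
        "P1\t10\tA\tV\t0.0001\tpathogenic\t2\tNA\tNA\tNA\tNA\tNA\t0.5\t-1.2",
        "P1\t11\tR\tH\tNA\tNA\tNA\t1\tNA\tNA\tNA\tNA\t0.1\tNA",
        "P2\t5\tL\tP\t0.01\tbenign\t1\tNA\tpolymorphism\tNA\t3\t0.01\tnot_a_number\t2.0",
        "P2\t6\tG\tE\t0.002\tNA\tNA\tNA\tdeleterious\tNA\tNA\tNA\t-0.3\t0.8",
        "P3\t1\tW\tR\t1e-7\tNA\tNA\tNA\tNA\t0.7\tNA\tNA\t0.0\t0.0",
    ]
    return "\n".join(rows) + "\n"


def small_benchmark(seed=0, n_core=200, n_addon=300, flip=(0.05, 0.45)):
    """A miniature core + one-noisy-add-on scenario for model-level tests."""
    config = SyntheticConfig(
        n_core=n_core,
        n_features=4,
        class_separation=2.0,
        addon_specs=(
            AddonSpec(id="addon", n=n_addon, source="humsavar",
                      flip_lo=flip[0], flip_hi=flip[1]),
        ),
        seed=seed,
    )
    return config, generate_benchmark(config)


@pytest.fixture
def tiny_model(rng):
    """A small fitted ensemble plus its training frame (5 features)."""
    n, d = 60, 5
    X = pd.DataFrame(rng.normal(size=(n, d)), columns=[f"x{i}" for i in range(d)])
    y = (X.sum(axis=1) + rng.normal(0, 0.5, n) > 0).astype(int).to_numpy()
    model = fit(X, y, None, AlgoHyperparams(n_trees=4, max_depth=3), list(X.columns))
    return model, X, y
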