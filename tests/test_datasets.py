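import io

import numpy as np
import pandas as pd
import pytest

from pathopred import datasets
from pathopred.datasets import (
    DEFAULT_PRECEDENCE,
    ModelFlavor,
    assign_labels,
    build_training_sets,
    label_variant,
    rarity_band,
    read_variant_table,
    roundtrip,
)
from pathopred.errors import (
    ConfigurationError,
    DuplicateVariantError,
    SchemaError,
)


def _read(text, **kw):
    return read_variant_table(io.StringIO(text), **kw)


class TestReadVariantTable:
    def test_header_only_gives_empty_table(self):
        df = _read("protein_id\tposition\tref_aa\talt_aa\tmaf\n")
        assert len(df) == 0

    def test_missing_required_column_names_it(self):
        with pytest.raises(SchemaError, match="maf"):
            _read("protein_id\tposition\tref_aa\talt_aa\n")

    def test_na_and_unparseable_cells_become_missing(self, variant_tsv_text):
        df = _read(variant_tsv_text)
        assert np.isnan(df.loc[1, "maf"])
        assert np.isnan(df.loc[2, "feature_1"])  # "not_a_number"

    def test_roundtrip_preserves_fields(self, variant_tsv_text):
        df = _read(variant_tsv_text)
        again = roundtrip(df)
        pd.testing.assert_frame_equal(df, again, check_dtype=False)

    def test_conflicting_duplicates_raise_with_keys(self):
        text = (
            "protein_id\tposition\tref_aa\talt_aa\tmaf\n"
            "P1\t1\tA\tV\t0.1\n"
            "P1\t1\tA\tV\t0.2\n"
        )
        with pytest.raises(DuplicateVariantError) as exc:
            _read(text)
        assert ("P1", 1, "A", "V") in exc.value.keys

    def test_identical_duplicates_collapse(self):
        text = (
            "protein_id\tposition\tref_aa\talt_aa\tmaf\n"
            "P1\t1\tA\tV\t0.1\n"
            "P1\t1\tA\tV\t0.1\n"
        )
        assert len(_read(text)) == 1

    @pytest.mark.parametrize(
        "row", ["P1\t0\tA\tV\t0.1", "P1\t1\tA\tA\t0.1", "P1\t1\tX\tV\t0.1"]
    )
    def test_identity_invariants_enforced(self, row):
        text = "protein_id\tposition\tref_aa\talt_aa\tmaf\n" + row + "\n"
        with pytest.raises(SchemaError):
            _read(text)


class TestLabeling:
    def test_clinvar_likely_pathogenic_is_positive(self):
        lab, src = label_variant({"clinvar_assertion": "likely pathogenic"})
        assert (lab, src) == ("positive", "clinvar")

    def test_precedence_clinvar_over_hgmd(self):
        lab, src = label_variant({"clinvar_assertion": "benign", "hgmd_present": 1})
        assert (lab, src) == ("negative", "clinvar")

    def test_mave_score_above_half_is_negative(self):
        lab, src = label_variant({"mave_score": 0.7})
        assert (lab, src) == ("negative", "mave")

    def test_mave_boundary_half_goes_negative(self):
        assert label_variant({"mave_score": 0.5})[0] == "negative"

    def test_gnomad_without_homozygotes_stays_unknown(self):
        assert label_variant({"gnomad_hom": 0}) == ("unknown", None)

    def test_gnomad_unobserved_flag_turns_them_negative(self):
        lab, src = label_variant({"gnomad_hom": 0}, gnomad_unobserved_negative=True)
        assert (lab, src) == ("negative", "gnomad")

    def test_unrecognized_assertion_warns_and_is_unknown(self):
        with pytest.warns(UserWarning, match="unrecognized"):
            lab, _ = label_variant({"clinvar_assertion": "conflicting"})
        assert lab == "unknown"

    def test_precedence_decides_not_annotation_order(self):
        row = {"mave_score": 0.9, "humsavar_assertion": "deleterious"}
        for precedence in (DEFAULT_PRECEDENCE, tuple(reversed(DEFAULT_PRECEDENCE))):
            lab, src = label_variant(row, precedence)
            expected = ("positive", "humsavar") if precedence[0] != "gnomad" else ("negative", "mave")
            assert (lab, src) == expected

    def test_assign_labels_columns(self, variant_tsv_text):
        df = assign_labels(_read(variant_tsv_text))
        assert list(df["label"]) == [
            "positive", "positive", "negative", "positive", "negative"
        ]
        assert list(df["primary_source"]) == [
            "clinvar", "hgmd", "clinvar", "humsavar", "mave"
        ]


class TestRarityAndSets:
    @pytest.mark.parametrize(
        "maf,band",
        [
            (0.01, "common"),
            (0.005, "moderately_rare"),  # boundary stays below "common"
            (1e-4, "moderately_rare"),
            (1e-6, "moderately_rare"),  # boundary stays out of "extremely rare"
            (1e-7, "extremely_rare"),
            (np.nan, "extremely_rare"),  # undetected allele counts as 0
            (0.0, "extremely_rare"),
        ],
    )
    def test_rarity_bands(self, maf, band):
        assert rarity_band(maf) == band

    def test_bands_exhaustive_and_exclusive(self, rng):
        mafs = np.concatenate([rng.uniform(0, 1, 200), [np.nan, 0.0, 1.0]])
        for maf in mafs:
            assert rarity_band(maf) in {"common", "moderately_rare", "extremely_rare"}

    def _labeled(self):
        text = (
            "protein_id\tposition\tref_aa\talt_aa\tmaf\tclinvar_assertion"
            "\thgmd_present\thumsavar_assertion\tmave_score\tgnomad_hom\n"
            "P1\t1\tA\tV\t1e-4\tpathogenic\tNA\tNA\tNA\tNA\n"       # clinvar MR
            "P1\t2\tA\tV\t1e-8\tbenign\tNA\tNA\tNA\tNA\n"            # clinvar ER
            "P1\t3\tA\tV\t0.05\tpathogenic\tNA\tNA\tNA\tNA\n"        # clinvar common
            "P1\t4\tA\tV\t0.001\tNA\tNA\tNA\tNA\t2\n"                # gnomad rare neg
            "P1\t5\tA\tV\t0.02\tNA\tNA\tNA\tNA\t1\n"                 # gnomad common neg
            "P1\t6\tA\tV\t1e-4\tNA\t1\tNA\tNA\tNA\n"                 # hgmd pos
            "P1\t7\tA\tV\t1e-4\tNA\tNA\tsomething\tNA\tNA\n"         # unknown
            "P1\t8\tA\tV\t1e-4\tNA\tNA\tNA\t0.8\tNA\n"               # mave neg
        )
        with pytest.warns(UserWarning):
            return assign_labels(_read(text))

    def test_flavor_r_core_and_addons(self):
        sets = build_training_sets(self._labeled(), ModelFlavor(name="R"))
        assert len(sets["core"]) == 2  # moderately + extremely rare clinvar
        assert len(sets["clinvar_common_positive"]) == 1
        assert len(sets["gnomad_rare_negative"]) == 1
        assert len(sets["gnomad_common_negative"]) == 1
        assert len(sets["hgmd_positive"]) == 1
        assert len(sets["mave_negative"]) == 1

    def test_flavor_er_demotes_moderately_rare_to_addon(self):
        sets = build_training_sets(self._labeled(), ModelFlavor(name="ER"))
        assert len(sets["core"]) == 1  # extremely rare only
        assert len(sets["clinvar_moderate_positive"]) == 1

    def test_partition_property(self):
        labeled = self._labeled()
        sets = build_training_sets(labeled, ModelFlavor(name="R"))
        total = sum(len(v) for v in sets.values())
        n_labeled = (labeled["label"] != "unknown").sum()
        assert total == n_labeled
        keys = pd.concat(sets.values())[["protein_id", "position"]]
        assert not keys.duplicated().any()

    def test_unknown_records_excluded(self):
        sets = build_training_sets(self._labeled(), ModelFlavor(name="R"))
        stacked = pd.concat(sets.values())
        assert (stacked["label"] != "unknown").all()

    def test_empty_core_raises(self):
        text = (
            "protein_id\tposition\tref_aa\talt_aa\tmaf\tclinvar_assertion\thgmd_present\n"
            "P1\t1\tA\tV\t1e-4\tNA\t1\n"
        )
        with pytest.raises(ConfigurationError, match="core"):
            build_training_sets(assign_labels(_read(text)), ModelFlavor(name="R"))

    def test_flavor_validation(self):
        with pytest.raises(ConfigurationError):
            ModelFlavor(name="X")
        with pytest.raises(ConfigurationError):
            ModelFlavor(rare_threshold=1e-7, extreme_threshold=1e-6)
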