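"""Variant tables: I/O, multi-source label harmonization, core/add-on set construction.

A variant is identified by (protein_id, position, ref_aa, alt_aa). Tables are
tab-separated with a header row; ``NA`` or an empty cell denotes a missing value.
Each row carries the variant identity, a minor allele frequency (MAF), flattened
per-source annotation columns, and arbitrary named numeric feature / property
columns. Labels are harmonized across sources (clinical assertions, literature
annotations, multiplexed functional-assay scores, population homozygote counts)
with a fixed but user-configurable source precedence, and labeled variants are
partitioned into one high-confidence "core" training set plus several "add-on"
sets keyed by source, label and rarity.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DuplicateVariantError, SchemaError

logger = logging.getLogger(__name__)

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

SOURCES = ("clinvar", "hgmd", "humsavar", "mave", "gnomad")
#: Default precedence when a variant appears in several databases; the order is
#: a judgement call (clinical assertions first, population evidence last) and
#: can be overridden wherever a ``precedence`` argument is accepted.
DEFAULT_PRECEDENCE = ("clinvar", "hgmd", "humsavar", "mave", "gnomad")

KEY_COLUMNS = ("protein_id", "position", "ref_aa", "alt_aa")
REQUIRED_COLUMNS = KEY_COLUMNS + ("maf",)
ANNOTATION_COLUMNS = (
    "clinvar_assertion",
    "clinvar_stars",
    "hgmd_present",
    "humsavar_assertion",
    "mave_score",
    "gnomad_hom",
    "gnomad_af",
)
DERIVED_COLUMNS = ("label", "primary_source", "set_id", "weight")

_CLINVAR_POSITIVE = {"pathogenic", "likely pathogenic", "pathogenic/likely pathogenic"}
_CLINVAR_NEGATIVE = {"benign", "likely benign", "benign/likely benign"}
_HUMSAVAR_POSITIVE = {"deleterious"}
_HUMSAVAR_NEGATIVE = {"polymorphism"}


@dataclass(frozen=True)
class ModelFlavor:
    """Which rarity stratum forms the core training set.

    ``R`` targets rare variants (core = moderately rare + extremely rare
    clinical-assertion variants, MAF < ``rare_threshold``); ``ER`` targets
    extremely rare variants only (core MAF < ``extreme_threshold``).
    """

    name: str = "R"
    rare_threshold: float = 0.005
    extreme_threshold: float = 1e-6

    def __post_init__(self) -> None:
        if self.name not in ("R", "ER"):
            raise ConfigurationError(f"unknown model flavor {self.name!r}")
        if not self.extreme_threshold < self.rare_threshold:
            raise ConfigurationError("extreme_threshold must be below rare_threshold")


@dataclass
class TableSchema:
    """Maps the columns of a variant TSV onto roles.

    Anything that is not a required identity column, a known annotation column,
    a derived column, or a declared property is treated as a feature.
    """

    feature_cols: list[str] = field(default_factory=list)
    property_cols: list[str] = field(default_factory=list)

    @classmethod
    def infer(cls, columns: Iterable[str], properties: Sequence[str] = ()) -> "TableSchema":
        reserved = set(REQUIRED_COLUMNS) | set(ANNOTATION_COLUMNS) | set(DERIVED_COLUMNS)
        props = [c for c in columns if c in set(properties)]
        feats = [c for c in columns if c not in reserved and c not in set(properties)]
        return cls(feature_cols=feats, property_cols=props)


def read_variant_table(
    source: str | IO[str],
    schema: TableSchema | None = None,
    properties: Sequence[str] = (),
) -> pd.DataFrame:
    """Read a variant TSV into a DataFrame, validating the required columns.

    Unparseable numeric cells become missing values. Duplicate variant keys
    with identical rows are collapsed; conflicting duplicates raise
    :class:`DuplicateVariantError`.
    """
    df = pd.read_csv(
        source,
        sep="\t",
        dtype={"protein_id": str, "ref_aa": str, "alt_aa": str},
        na_values=["NA"],
        keep_default_na=True,
    )
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} is missing")
    if schema is None:
        schema = TableSchema.infer(df.columns, properties)
    numeric_cols = (
        ["position", "maf", "clinvar_stars", "mave_score", "gnomad_hom", "gnomad_af"]
        + schema.feature_cols
        + schema.property_cols
    )
    for col in numeric_cols:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if len(df):
        df["position"] = df["position"].astype("int64")
        bad_pos = df["position"] < 1
        if bad_pos.any():
            raise SchemaError("position must be a 1-based index >= 1")
        bad_aa = ~(df["ref_aa"].isin(AMINO_ACIDS) & df["alt_aa"].isin(AMINO_ACIDS))
        if bad_aa.any():
            raise SchemaError(
                f"unknown amino acid code in rows {df.index[bad_aa].tolist()[:5]}"
            )
        if (df["ref_aa"] == df["alt_aa"]).any():
            raise SchemaError("ref_aa must differ from alt_aa for a missense variant")
        dup = df.duplicated(subset=list(KEY_COLUMNS), keep=False)
        if dup.any():
            deduped = df.drop_duplicates()
            still = deduped.duplicated(subset=list(KEY_COLUMNS), keep=False)
            if still.any():
                keys = [
                    tuple(r)
                    for r in deduped.loc[still, list(KEY_COLUMNS)].itertuples(index=False)
                ]
                raise DuplicateVariantError(sorted(set(keys)))
            df = deduped.reset_index(drop=True)
    df.attrs["schema"] = schema
    return df


def write_variant_table(df: pd.DataFrame, target: str | IO[str]) -> None:
    """Write a variant table as TSV with ``NA`` for missing values."""
    df.to_csv(target, sep="\t", index=False, na_rep="NA")


def roundtrip(df: pd.DataFrame, schema: TableSchema | None = None) -> pd.DataFrame:
    """Write then re-read a table in memory (round-trip identity helper)."""
    buf = io.StringIO()
    write_variant_table(df, buf)
    buf.seek(0)
    return read_variant_table(buf, schema=schema)


def _source_label(source: str, row: Mapping, gnomad_unobserved_negative: bool) -> str:
    """Label contributed by one source for one variant row; 'unknown' if the
    source has nothing to say. Unrecognized assertion strings warn and yield
    'unknown'."""
    if source == "clinvar":
        assertion = row.get("clinvar_assertion")
        if assertion is None or (isinstance(assertion, float) and np.isnan(assertion)):
            return "unknown"
        text = str(assertion).strip().lower()
        if text in _CLINVAR_POSITIVE:
            return "positive"
        if text in _CLINVAR_NEGATIVE:
            return "negative"
        if text:
            warnings.warn(f"unrecognized ClinVar assertion {assertion!r}", stacklevel=3)
        return "unknown"
    if source == "hgmd":
        present = row.get("hgmd_present")
        if present is None or (isinstance(present, float) and np.isnan(present)):
            return "unknown"
        return "positive" if bool(int(present)) else "unknown"
    if source == "humsavar":
        assertion = row.get("humsavar_assertion")
        if assertion is None or (isinstance(assertion, float) and np.isnan(assertion)):
            return "unknown"
        text = str(assertion).strip().lower()
        if text in _HUMSAVAR_POSITIVE:
            return "positive"
        if text in _HUMSAVAR_NEGATIVE:
            return "negative"
        if text:
            warnings.warn(f"unrecognized HumsaVar annotation {assertion!r}", stacklevel=3)
        return "unknown"
    if source == "mave":
        score = row.get("mave_score")
        if score is None or (isinstance(score, float) and np.isnan(score)):
            return "unknown"
        # Rescaled functional score: 1 ~ synonymous-like (benign), 0 ~
        # nonsense-like (damaging). A score of exactly 0.5 falls to negative.
        return "negative" if float(score) >= 0.5 else "positive"
    if source == "gnomad":
        hom = row.get("gnomad_hom")
        if hom is None or (isinstance(hom, float) and np.isnan(hom)):
            return "unknown"
        if int(hom) >= 1:
            return "negative"
        return "negative" if gnomad_unobserved_negative else "unknown"
    raise ConfigurationError(f"unknown annotation source {source!r}")


def label_variant(
    row: Mapping,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
    gnomad_unobserved_negative: bool = False,
) -> tuple[str, str | None]:
    """Harmonize one variant's annotations into (label, primary_source).

    The first source in ``precedence`` contributing a non-unknown label wins;
    a variant no source can label is ('unknown', None).
    """
    for source in precedence:
        if source not in SOURCES:
            raise ConfigurationError(f"unknown source {source!r} in precedence")
        lab = _source_label(source, row, gnomad_unobserved_negative)
        if lab != "unknown":
            return lab, source
    return "unknown", None


def assign_labels(
    df: pd.DataFrame,
    precedence: Sequence[str] = DEFAULT_PRECEDENCE,
    gnomad_unobserved_negative: bool = False,
) -> pd.DataFrame:
    """Add ``label`` and ``primary_source`` columns to a variant table.

    ``gnomad_unobserved_negative=True`` additionally admits population variants
    never seen homozygous as putatively benign (used by the unweighted
    degradation experiment); by default they stay unlabeled.
    """
    out = df.copy()
    labels, sources = [], []
    for row in df.to_dict("records"):
        lab, src = label_variant(row, precedence, gnomad_unobserved_negative)
        labels.append(lab)
        sources.append(src)
    out["label"] = labels
    out["primary_source"] = sources
    return out


def rarity_band(maf: float | None, flavor: ModelFlavor = ModelFlavor()) -> str:
    """Rarity stratum of a MAF value; a missing MAF counts as 0 (undetected).

    common: maf > rare_threshold; moderately_rare: extreme_threshold <= maf <=
    rare_threshold; extremely_rare: maf < extreme_threshold. Band boundaries
    resolve so that "common" stays strictly above the rare threshold.
    """
    x = 0.0 if maf is None or (isinstance(maf, float) and np.isnan(maf)) else float(maf)
    if x > flavor.rare_threshold:
        return "common"
    if x >= flavor.extreme_threshold:
        return "moderately_rare"
    return "extremely_rare"


def build_training_sets(
    df: pd.DataFrame, flavor: ModelFlavor = ModelFlavor()
) -> dict[str, pd.DataFrame]:
    """Partition labeled variants into one core set and add-on sets.

    Unknown-label records are dropped. Clinical-assertion (clinvar) records are
    stratified by rarity: flavor R pools moderately+extremely rare ones into
    the core, leaving common ones as add-ons; flavor ER keeps only extremely
    rare ones in the core and turns common and moderately rare ones into
    add-ons. Every other add-on set is keyed by (source, label), and negative
    add-on sets except the functional-assay one are further split at the rare
    threshold. The emitted sets partition the labeled input.
    """
    if "label" not in df.columns or "primary_source" not in df.columns:
        raise SchemaError("run assign_labels before build_training_sets")
    labeled = df[df["label"].isin(["positive", "negative"])].copy()
    dropped = len(df) - len(labeled)
    if dropped:
        logger.info("dropped %d unlabeled records", dropped)
    bands = labeled["maf"].map(lambda m: rarity_band(m, flavor))

    set_ids = pd.Series(index=labeled.index, dtype=object)
    is_clinvar = labeled["primary_source"] == "clinvar"
    if flavor.name == "R":
        core_mask = is_clinvar & bands.isin(["moderately_rare", "extremely_rare"])
    else:
        core_mask = is_clinvar & (bands == "extremely_rare")
    set_ids[core_mask] = "core"
    band_short = {"common": "common", "moderately_rare": "moderate"}
    for idx in labeled.index[is_clinvar & ~core_mask]:
        set_ids[idx] = f"clinvar_{band_short[bands[idx]]}_{labeled.at[idx, 'label']}"
    for idx in labeled.index[~is_clinvar]:
        src = labeled.at[idx, "primary_source"]
        lab = labeled.at[idx, "label"]
        if lab == "negative" and src != "mave":
            rarity = "common" if bands[idx] == "common" else "rare"
            set_ids[idx] = f"{src}_{rarity}_negative"
        else:
            set_ids[idx] = f"{src}_{lab}"
    labeled["set_id"] = set_ids

    if not core_mask.any():
        raise ConfigurationError(
            f"core set is empty for flavor {flavor.name}: no qualifying "
            "clinical-assertion variants in the core rarity band"
        )
    return {
        set_id: grp.reset_index(drop=True) for set_id, grp in labeled.groupby("set_id")
    }
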