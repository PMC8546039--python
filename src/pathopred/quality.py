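"""Formula-defined quality-informative properties of training variants.

Two properties are computed here, both used to down-weight questionable
training examples:

* **mutational accessibility** — the probability mass of single-nucleotide
  codon edits producing a given amino acid change, under a codon-usage model.
  Each sense codon has exactly nine possible single-nucleotide edits, each
  assigned probability ``usage(codon) / 9``; amino acid changes reachable only
  through two or more edits within one codon get mass exactly 0. Variants from
  saturation mutagenesis experiments can carry amino acid changes that almost
  never arise in humans by a single nucleotide change, and those examples are
  less representative of clinically observed variation.

* **label confidence** — how far a rescaled functional-assay score sits from
  the 0.5 labeling threshold: the score itself below 0.5, one minus the score
  above it. Scores near the threshold produce unreliable labels.

Allele frequency, review stars and homozygote counts are quality properties
too, but they are carried through variant tables unchanged; only the derived
properties live here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import IO, Mapping

import pandas as pd
from Bio.Data import CodonTable

from .errors import ConfigurationError, SchemaError

_BASES = "ACGT"
_TABLE = CodonTable.unambiguous_dna_by_id[1]

#: Standard genetic code, all 64 codons; '*' marks a stop.
GENETIC_CODE: dict[str, str] = dict(_TABLE.forward_table)
GENETIC_CODE.update({codon: "*" for codon in _TABLE.stop_codons})

SENSE_CODONS = tuple(sorted(c for c, aa in GENETIC_CODE.items() if aa != "*"))

_CODONS_FOR_AA: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    _CODONS_FOR_AA.setdefault(GENETIC_CODE[_codon], ())
    _CODONS_FOR_AA[GENETIC_CODE[_codon]] += (_codon,)


def single_edits(codon: str) -> list[str]:
    """The nine codons one nucleotide edit away from ``codon``."""
    return [
        codon[:i] + b + codon[i + 1 :]
        for i in range(3)
        for b in _BASES
        if b != codon[i]
    ]


@dataclass(frozen=True)
class CodonUsageTable:
    """Relative synonymous codon usage: per amino acid, usages sum to 1.

    The table may be loaded from genome-wide frequencies (e.g. counts per
    thousand); normalization to per-amino-acid relative usage happens at
    construction so single-codon amino acids (Met, Trp) always carry usage 1.
    """

    usage: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(SENSE_CODONS) - set(self.usage)
        if missing:
            raise SchemaError(f"codon usage table lacks sense codons: {sorted(missing)}")
        for aa, codons in _CODONS_FOR_AA.items():
            total = sum(self.usage[c] for c in codons)
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ConfigurationError(
                    f"relative usage for {aa} sums to {total}, expected 1"
                )

    @classmethod
    def from_frequencies(cls, frequencies: Mapping[str, float]) -> "CodonUsageTable":
        """Normalize arbitrary non-negative codon frequencies per amino acid."""
        usage = {}
        for aa, codons in _CODONS_FOR_AA.items():
            total = sum(float(frequencies[c]) for c in codons)
            if total <= 0:
                raise ConfigurationError(f"zero total codon frequency for {aa}")
            for c in codons:
                usage[c] = float(frequencies[c]) / total
        return cls(usage)

    @classmethod
    def from_tsv(cls, source: str | IO[str]) -> "CodonUsageTable":
        """Load a TSV with columns codon, amino_acid, relative_usage."""
        df = pd.read_csv(source, sep="\t")
        for col in ("codon", "amino_acid", "relative_usage"):
            if col not in df.columns:
                raise SchemaError(f"codon usage table lacks column {col!r}")
        freq = {}
        for row in df.itertuples(index=False):
            codon = str(row.codon).upper()
            if codon not in GENETIC_CODE:
                raise SchemaError(f"unknown codon {row.codon!r}")
            if GENETIC_CODE[codon] != str(row.amino_acid).upper():
                raise SchemaError(
                    f"codon {codon} does not encode {row.amino_acid!r}"
                )
            freq[codon] = float(row.relative_usage)
        return cls.from_frequencies(freq)

    @classmethod
    def human_default(cls) -> "CodonUsageTable":
        """The bundled human relative codon-usage table."""
        ref = resources.files("pathopred.data") / "human_codon_usage.tsv"
        with ref.open("r") as fh:
            return cls.from_tsv(fh)

    @classmethod
    def uniform(cls) -> "CodonUsageTable":
        """Equal usage among synonymous codons (handy for exact arithmetic)."""
        return cls.from_frequencies({c: 1.0 for c in SENSE_CODONS})


def mutational_accessibility(
    ref_aa: str, alt_aa: str, usage: CodonUsageTable | None = None
) -> float:
    """Probability that a single-nucleotide edit of a ``ref_aa`` codon yields
    ``alt_aa`` (use ``"*"`` for stop), under relative codon usage.

    Each codon contributes ``usage/9`` per qualifying edit, so summing over all
    20 amino acids plus stop (and the synonymous mass for ``alt_aa == ref_aa``)
    conserves total mass 1 per reference amino acid.
    """
    if usage is None:
        usage = CodonUsageTable.human_default()
    ref_aa, alt_aa = ref_aa.upper(), alt_aa.upper()
    if ref_aa not in _CODONS_FOR_AA:
        raise SchemaError(f"unknown or non-sense reference amino acid {ref_aa!r}")
    if alt_aa != "*" and alt_aa not in _CODONS_FOR_AA:
        raise SchemaError(f"unknown alternate amino acid {alt_aa!r}")
    total = 0.0
    for codon in _CODONS_FOR_AA[ref_aa]:
        share = usage.usage[codon] / 9.0
        for edited in single_edits(codon):
            if GENETIC_CODE[edited] == alt_aa:
                total += share
    return total


def label_confidence(mave_score: float) -> float:
    """Confidence of a functional-assay label: distance of the rescaled score
    from the 0.5 threshold, clamped below at 0. Missing scores stay missing."""
    if mave_score is None or (isinstance(mave_score, float) and math.isnan(mave_score)):
        return math.nan
    s = float(mave_score)
    return max(0.0, min(s, 1.0 - s))


def add_derived_properties(df: pd.DataFrame, usage: CodonUsageTable | None = None) -> pd.DataFrame:
    """Attach ``mutational_accessibility`` and ``label_confidence`` columns to
    a variant table (the latter only where a functional score is present)."""
    if usage is None:
        usage = CodonUsageTable.human_default()
    out = df.copy()
    out["mutational_accessibility"] = [
        mutational_accessibility(r, a, usage)
        for r, a in zip(df["ref_aa"], df["alt_aa"])
    ]
    if "mave_score" in df.columns:
        out["label_confidence"] = df["mave_score"].map(label_confidence)
    return out
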