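"""Amino-acid hydrophobicity categories and edit conversion accounting.

Non-silent edits in plant organelles overwhelmingly convert hydrophilic or
neutral residues toward hydrophobic ones, consistent with the membrane-bound
nature of most organellar proteins.  This module classifies residues on a
numeric hydropathy index at pH 7 and tabulates the 4x4 category conversion
matrix over non-silent amino-acid changes.

The default index is Kyte-Doolittle with category cut-points: index >= 2.5
very hydrophobic; (0, 2.5) hydrophobic; [-1.5, 0] neutral; < -1.5
hydrophilic.  The scale is pluggable (TSV: residue, index, category) since
published hydrophobicity scales differ.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

CATEGORIES = ("hydrophilic", "neutral", "hydrophobic", "very hydrophobic")
UNCLASSIFIED = "unclassified"
_RANK = {c: i for i, c in enumerate(CATEGORIES)}


def _default_category(index: float) -> str:
    if index >= 2.5:
        return "very hydrophobic"
    if index > 0:
        return "hydrophobic"
    if index >= -1.5:
        return "neutral"
    return "hydrophilic"


@dataclass(frozen=True)
class HydropathyScale:
    """Residue -> (numeric index, ordered category) mapping."""

    index: dict
    category: dict

    @classmethod
    def default(cls) -> "HydropathyScale":
        index = dict(KYTE_DOOLITTLE)
        return cls(index=index, category={aa: _default_category(v) for aa, v in index.items()})

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HydropathyScale":
        df = pd.read_csv(path, sep="\t")
        index = dict(zip(df["residue"], df["index"].astype(float)))
        category = dict(zip(df["residue"], df["category"]))
        bad = set(category.values()) - set(CATEGORIES)
        if bad:
            raise ValueError(f"unknown hydropathy categories {sorted(bad)} in {path}")
        return cls(index=index, category=category)

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"residue": aa, "index": self.index[aa], "category": self.category[aa]}
            for aa in sorted(self.index)
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def categorize(amino_acid: str, scale: HydropathyScale | None = None) -> str:
    """Ordered hydrophobicity category of a one-letter residue.

    The stop symbol (and anything absent from the scale) is "unclassified"
    and excluded from conversion matrices.
    """
    scale = scale or HydropathyScale.default()
    return scale.category.get(amino_acid, UNCLASSIFIED)


@dataclass
class ConversionMatrix:
    """4x4 (category before -> after) counts over non-silent edits."""

    counts: pd.DataFrame
    unclassifiable: int
    silent: int

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def toward_hydrophobic_fraction(self) -> float:
        """Fraction of classifiable conversions that strictly increase
        hydrophobicity."""
        up = sum(
            self.counts.loc[a, b]
            for a in CATEGORIES
            for b in CATEGORIES
            if _RANK[b] > _RANK[a]
        )
        return up / self.total if self.total else float("nan")


def conversion_counts(
    records: Iterable, scale: HydropathyScale | None = None
) -> ConversionMatrix:
    """Tally hydrophobicity conversions over consequence records.

    One increment per non-silent record (``ref_aa != edited_aa``); silent
    records and records involving a stop or unclassifiable residue contribute
    to their own tallies instead.
    """
    scale = scale or HydropathyScale.default()
    counts = pd.DataFrame(0, index=list(CATEGORIES), columns=list(CATEGORIES))
    unclassifiable = 0
    silent = 0
    for rec in records:
        if rec.ref_aa == rec.edited_aa:
            silent += 1
            continue
        a = categorize(rec.ref_aa, scale)
        b = categorize(rec.edited_aa, scale)
        if a == UNCLASSIFIED or b == UNCLASSIFIED:
            unclassifiable += 1
            continue
        counts.loc[a, b] += 1
    return ConversionMatrix(counts=counts, unclassifiable=unclassifiable, silent=silent)


def conversion_counts_for_sites(
    sites: Sequence, scale: HydropathyScale | None = None
) -> ConversionMatrix:
    """Conversion matrix over annotated editing sites, one tally per affected
    codon (joint edited codon), matching the summary's codon accounting."""
    codons = {}
    for s in sites:
        rec = s.consequence
        if rec is None:
            raise ValueError(f"site {s.gene_id}:{s.pos0 + 1} not annotated")
        codons[(rec.gene_id, rec.codon_index)] = rec
    return conversion_counts(codons.values(), scale)


def annotate_hydropathy(sites: Sequence, scale: HydropathyScale | None = None) -> None:
    """Fill each annotated site's hydropathy_from/to fields in place."""
    scale = scale or HydropathyScale.default()
    for s in sites:
        if s.consequence is None:
            continue
        s.hydropathy_from = categorize(s.consequence.ref_aa, scale)
        s.hydropathy_to = categorize(s.consequence.edited_aa, scale)
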