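"""Core domain types: gene models, truth editomes, called editing sites.

Coordinate conventions
----------------------
Internal coordinates are 0-based, half-open throughout the package.  Public
file formats (GFF3, the edit-table TSV) are 1-based, inclusive; conversion
happens only at the I/O boundary (:mod:`editome.io`).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

_COMPLEMENT = str.maketrans("ACGTNRYKMSWBDHV", "TGCANYRMKSWVHDB")

# Edit-type labels used throughout.  C-to-U and U-to-C are genuine plant
# organellar editing; A-to-G / G-to-A mismatches are sequencing/mapping
# artifacts ("suspect" events), never merged into editome totals.
CU = "C-to-U"
UC = "U-to-C"
EDIT_TYPES = (CU, UC)
SUSPECT_TYPES = ("A-to-G", "G-to-A", "other")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def classify_edit(ref: str, alt: str) -> str:
    """Edit-type label from a coding-strand ref/alt base pair."""
    pair = (ref, alt)
    if pair == ("C", "T"):
        return CU
    if pair == ("T", "C"):
        return UC
    if pair == ("A", "G"):
        return "A-to-G"
    if pair == ("G", "A"):
        return "G-to-A"
    return "other"


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene on an organellar contig.

    ``exons`` are genomic 0-based half-open intervals in ascending genomic
    order, regardless of strand; transcription order for minus-strand genes
    is the reverse.
    """

    gene_id: str
    seq_id: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    genome: str = "mitogenome"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        prev_end = -1
        for start, end in self.exons:
            if start >= end or start < prev_end:
                raise ValueError(
                    f"exons of {self.gene_id} must be sorted, non-overlapping"
                )
            prev_end = end

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def spliced_cds(self, contig_seq: str) -> str:
        """Spliced CDS in coding orientation (reverse-complemented for '-')."""
        cat = "".join(contig_seq[s:e] for s, e in self.exons)
        return revcomp(cat) if self.strand == "-" else cat

    def cds_offset(self, genomic_pos: int) -> Optional[int]:
        """Map a genomic position to its 0-based spliced-CDS offset.

        Returns None for positions outside the exons (introns/flanks).
        """
        acc = 0
        for s, e in self.exons:
            if s <= genomic_pos < e:
                fwd = acc + (genomic_pos - s)
                if self.strand == "+":
                    return fwd
                return self.cds_length - 1 - fwd
            acc += e - s
        return None

    def genomic_pos(self, cds_offset: int) -> int:
        """Inverse of :meth:`cds_offset`."""
        if not 0 <= cds_offset < self.cds_length:
            raise IndexError(f"CDS offset {cds_offset} out of range")
        fwd = cds_offset if self.strand == "+" else self.cds_length - 1 - cds_offset
        for s, e in self.exons:
            if fwd < e - s:
                return s + fwd
            fwd -= e - s
        raise AssertionError("unreachable")

    def transcript_to_genome(self) -> list[int]:
        """Genomic coordinate of every spliced-CDS offset, in CDS order."""
        fwd = [p for s, e in self.exons for p in range(s, e)]
        return fwd[::-1] if self.strand == "-" else fwd

    def exon_boundaries_internal(self) -> list[int]:
        """Genomic coordinates flanking introns (exon ends/starts), if any."""
        bounds: list[int] = []
        for i, (s, e) in enumerate(self.exons):
            if i > 0:
                bounds.append(s)
            if i < len(self.exons) - 1:
                bounds.append(e - 1)
        return bounds


@dataclass(frozen=True)
class TruthSite:
    """One planted ground-truth site of a simulation.

    ``ref``/``alt`` are coding-strand bases; ``pos0`` is 0-based genomic.
    ``codon_pos`` is 1/2/3 inside the CDS, or "noncoding".
    """

    gene_id: str
    pos0: int
    ref: str
    alt: str
    type: str  # C-to-U | U-to-C | artifact | heteroplasmy
    fraction: float
    codon_pos: object


@dataclass
class TruthEditome:
    """Planted ground truth: editing + artifact records, heteroplasmic sites."""

    records: list[TruthSite] = field(default_factory=list)
    heteroplasmic: list[TruthSite] = field(default_factory=list)

    @property
    def editing_records(self) -> list[TruthSite]:
        return [r for r in self.records if r.type in EDIT_TYPES]

    @property
    def artifact_records(self) -> list[TruthSite]:
        return [r for r in self.records if r.type == "artifact"]

    def by_gene(self) -> dict[str, list[TruthSite]]:
        out: dict[str, list[TruthSite]] = {}
        for r in self.records:
            out.setdefault(r.gene_id, []).append(r)
        return out


@dataclass
class ConsequenceRecord:
    """Protein-level consequence of all accepted edits within one codon."""

    gene_id: str
    cds_offset: int  # offset of the edited site this record annotates
    codon_index: int
    codon_pos: int  # 1..3
    ref_codon: str
    edited_codon: str  # all accepted edits in the codon applied jointly
    ref_aa: str
    edited_aa: str
    effect: str  # silent | non-silent | start-creation | stop-creation | stop-removal
    is_terminal: bool = False
    provisional_effect: Optional[str] = None  # this edit alone, for transparency


@dataclass
class EditingSite:
    """One accepted (or suspect) DNA:RNA mismatch after the filter cascade.

    ``ref``/``alt`` are coding-strand bases; counts are end-exclusion-adjusted.
    """

    gene_id: str
    seq_id: str
    pos0: int
    ref: str
    alt: str
    type: str
    depth: int
    alt_reads: int
    frequency: float
    alt_fwd: int = 0
    alt_rev: int = 0
    other_fwd: int = 0
    other_rev: int = 0
    variant_p: float = 1.0
    strand_bias_p: float = 1.0
    consequence: Optional[ConsequenceRecord] = None
    hydropathy_from: Optional[str] = None
    hydropathy_to: Optional[str] = None

    def with_consequence(self, rec: ConsequenceRecord) -> "EditingSite":
        return replace(self, consequence=rec)


def sites_by_gene(sites: Iterable[EditingSite]) -> dict[str, list[EditingSite]]:
    out: dict[str, list[EditingSite]] = {}
    for s in sites:
        out.setdefault(s.gene_id, []).append(s)
    return out
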