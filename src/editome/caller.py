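"""DNA:RNA mismatch pileup and the editing-site filter cascade.

A position becomes an editing site iff it survives, in this fixed order:

1. heteroplasmy mask (DNA non-reference fraction >= 0.25),
2. read-end exclusion (bases < 6 nt from the nearer read end dropped from
   both alt and depth tallies) leaving usable depth,
3. >= 3 supporting reads (inclusive),
4. variant frequency >= 4.6% (inclusive),
5. binomial variant significance p <= 1e-6 under a flat assumed error rate,
6. two-sided Fisher strand-bias p >= 1e-5,
7. exon/intron junction mismapping check.

Edit type is assigned on the coding strand (a genomic G with RNA A on a
minus-strand gene is a coding-strand C-to-U).  A:G/G:A mismatches are
"suspect" artifacts, reported separately and never merged into editome
totals.  The rejection order above also fixes manifest fate attribution
(first failing rule wins) so per-rule counts are reproducible.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Optional, Sequence

import edlib
from scipy.stats import binom

from .config import CallerConfig
from .errors import InputError
from .models import (
    EDIT_TYPES,
    EditingSite,
    GeneModel,
    classify_edit,
    complement,
    revcomp,
)

log = logging.getLogger(__name__)

FILTER_ORDER = (
    "masked",
    "no_usable_depth",
    "min_alt_reads",
    "min_variant_frequency",
    "variant_p",
    "strand_bias",
    "junction",
    "multiallelic",
)


@dataclass
class PileupColumn:
    """Per-position base observations split by strand with read-end offsets.

    ``obs[base]`` holds ``(is_reverse, offset_from_nearer_read_end)`` pairs;
    ``alt_read_seqs[base]`` keeps the query sequences of non-reference
    observations (needed by the junction mismapping check).
    """

    pos: int
    ref_base: str
    obs: dict[str, list[tuple[bool, int]]] = field(default_factory=dict)
    alt_read_seqs: dict[str, list[str]] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return sum(len(v) for v in self.obs.values())

    def add(self, base: str, is_reverse: bool, end_offset: int, read_seq: Optional[str]) -> None:
        self.obs.setdefault(base, []).append((is_reverse, end_offset))
        if read_seq is not None and base != self.ref_base:
            self.alt_read_seqs.setdefault(base, []).append(read_seq)


class Pileup:
    """Sparse pileup over one reference sequence."""

    def __init__(self, seq_id: str, reference: str):
        self.seq_id = seq_id
        self.reference = reference
        self.columns: dict[int, PileupColumn] = {}
        self.max_read_length = 0

    def column(self, pos: int) -> Optional[PileupColumn]:
        return self.columns.get(pos)

    def _column(self, pos: int) -> PileupColumn:
        col = self.columns.get(pos)
        if col is None:
            col = self.columns[pos] = PileupColumn(pos, self.reference[pos])
        return col


def build_pileup(
    reads: Iterable,
    seq_id: str,
    reference: str,
    region: Optional[tuple[int, int]] = None,
    collect_read_seqs: bool = True,
) -> Pileup:
    """Pile aligned reads onto ``reference``; skips and clips contribute nothing.

    ``reads`` are pysam AlignedSegment records (already filtered to mapped,
    primary, non-duplicate by :func:`editome.io.read_alignments`).  The
    offset recorded per base is its 0-based distance to the nearer end of the
    full query sequence (soft clips included), which is what the read-end
    exclusion filter operates on.
    """
    pile = Pileup(seq_id, reference)
    for rec in reads:
        if rec.reference_name != seq_id:
            raise InputError(
                f"read {rec.query_name} aligned to {rec.reference_name}, expected {seq_id}"
            )
        qseq = rec.query_sequence
        qlen = len(qseq)
        pile.max_read_length = max(pile.max_read_length, qlen)
        for qpos, rpos in rec.get_aligned_pairs(matches_only=True):
            if region is not None and not (region[0] <= rpos < region[1]):
                continue
            base = qseq[qpos]
            if base == "N":
                continue
            end_offset = min(qpos, qlen - 1 - qpos)
            pile._column(rpos).add(
                base,
                rec.is_reverse,
                end_offset,
                qseq if collect_read_seqs else None,
            )
    return pile


# ---------------------------------------------------------------------------
# individual filters
# ---------------------------------------------------------------------------

def mask_heteroplasmy(dna_pileup: Pileup, config: CallerConfig) -> set[int]:
    """Positions whose DNA non-reference fraction reaches the heteroplasmy
    threshold (genomic ambiguous sites); monotone non-increasing in the
    threshold.  Reference ambiguity codes are masked unconditionally."""
    masked: set[int] = set()
    for pos, col in dna_pileup.columns.items():
        if col.ref_base not in "ACGT":
            masked.add(pos)
            continue
        depth = col.depth
        if depth == 0:
            continue
        non_ref = depth - len(col.obs.get(col.ref_base, ()))
        if non_ref / depth >= config.heteroplasmy_min_frequency:
            masked.add(pos)
    for pos, base in enumerate(dna_pileup.reference):
        if base not in "ACGT":
            masked.add(pos)
    return masked


def end_exclusion_filter(
    column: PileupColumn, config: CallerConfig
) -> dict[str, tuple[int, int]]:
    """Adjusted per-base (forward, reverse) counts after dropping bases whose
    0-based distance to the nearer read end is < ``read_end_exclusion``."""
    out: dict[str, tuple[int, int]] = {}
    for base, entries in column.obs.items():
        fwd = sum(1 for rev, off in entries if not rev and off >= config.read_end_exclusion)
        rev = sum(1 for rev_, off in entries if rev_ and off >= config.read_end_exclusion)
        if fwd or rev:
            out[base] = (fwd, rev)
    return out


def variant_significance(alt_reads: int, depth: int, error_rate: float) -> float:
    """Upper-tail binomial P(X >= k | n, e): chance that sequencing error
    alone produces at least this much alternate support."""
    if depth == 0:
        raise ValueError("variant significance undefined at zero depth")
    if alt_reads <= 0:
        return 1.0
    return float(binom.sf(alt_reads - 1, depth, error_rate))


def strand_bias_test(alt_fwd: int, alt_rev: int, other_fwd: int, other_rev: int) -> float:
    """Two-sided Fisher exact p for the 2x2 strand table, computed by exact
    integer enumeration.

    Hypergeometric point masses share the denominator C(n, c1), so tables are
    compared by their integer numerators C(r1, x) * C(r2, c1-x); the two-sided
    p sums every table whose mass is <= the observed one.  Exact integer
    comparison makes tie handling reproducible at any table size.
    """
    r1, r2 = alt_fwd + alt_rev, other_fwd + other_rev
    c1 = alt_fwd + other_fwd
    n = r1 + r2
    if n == 0:
        raise ValueError("empty 2x2 table")
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    obs = math.comb(r1, alt_fwd) * math.comb(r2, other_fwd)
    total = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        mass = math.comb(r1, x) * math.comb(r2, c1 - x)
        if mass <= obs:
            total += mass
    return float(Fraction(total, math.comb(n, c1)))


def junction_artifact_check(
    alt_read_seqs: Sequence[str],
    gene: GeneModel,
    contig: str,
    pos: int,
    config: CallerConfig,
    observed_read_length: int,
) -> bool:
    """True if the candidate survives the exon/intron junction check.

    For candidates within ``junction_window`` of an internal exon boundary,
    the spliced transcript is reconstructed; if every alt-supporting read is
    fully explained by the spliced sequence without the mismatch (edit
    distance 0 in infix mode, either orientation), the candidate is a
    mismapping artifact and is rejected.  Mid-exon candidates pass untouched.
    """
    window = config.junction_window
    if window is None:
        window = observed_read_length
    bounds = gene.exon_boundaries_internal()
    if not bounds or all(abs(pos - b) > window for b in bounds):
        return True
    if not alt_read_seqs:
        log.warning(
            "junction check at %s:%d skipped: no alt read sequences collected",
            gene.seq_id,
            pos + 1,
        )
        return True
    tx = gene.spliced_cds(contig)
    tx_rc = revcomp(tx)
    for seq in alt_read_seqs:
        d_f = edlib.align(seq, tx, mode="HW")["editDistance"]
        d_r = edlib.align(seq, tx_rc, mode="HW")["editDistance"]
        if min(d_f, d_r) != 0:
            return True  # at least one alt read is not explained by splicing
    return False


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------

@dataclass
class CallResult:
    """Accepted editome, suspect A:G/G:A events, and per-rule filter counts."""

    sites: list[EditingSite] = field(default_factory=list)
    suspects: list[EditingSite] = field(default_factory=list)
    stats: dict[str, int] = field(
        default_factory=lambda: {"candidates": 0, "accepted": 0, **{k: 0 for k in FILTER_ORDER}}
    )

    def check_conservation(self) -> None:
        s = self.stats
        fates = s["accepted"] + sum(s[k] for k in FILTER_ORDER)
        if fates != s["candidates"]:
            raise AssertionError(
                f"filter fate conservation violated: {fates} != {s['candidates']}"
            )


def _coding_pair(ref: str, alt: str, strand: str) -> tuple[str, str]:
    if strand == "-":
        return complement(ref), complement(alt)
    return ref, alt


def call_sites(
    rna_pileup: Pileup,
    dna_mask: set[int],
    contig: str,
    genes: Sequence[GeneModel],
    config: CallerConfig,
    result: Optional[CallResult] = None,
) -> CallResult:
    """Run the filter cascade over every candidate position of ``genes``.

    Only positions inside annotated CDS exons are considered (set
    ``config.call_introns`` to extend over the genes' full spans for
    diagnostics).  Multi-allelic columns: each alternate base is evaluated
    independently, at most one accepted per position (highest adjusted
    frequency wins; exact ties reject both, logged).
    """
    res = result if result is not None else CallResult()
    for gene in genes:
        if config.call_introns:
            span = gene.span
            positions: Iterable[int] = range(span[0], span[1])
        else:
            positions = (p for s, e in gene.exons for p in range(s, e))
        for pos in positions:
            col = rna_pileup.column(pos)
            if col is None:
                continue
            alts = [b for b in col.obs if b != col.ref_base]
            if not alts:
                continue
            accepted_here: list[EditingSite] = []
            for alt in alts:
                res.stats["candidates"] += 1
                site = _evaluate_candidate(
                    col, alt, gene, contig, dna_mask, config, rna_pileup.max_read_length, res
                )
                if site is not None:
                    accepted_here.append(site)
            if len(accepted_here) > 1:
                accepted_here.sort(key=lambda s: s.frequency, reverse=True)
                if accepted_here[0].frequency == accepted_here[1].frequency:
                    log.warning(
                        "multi-allelic tie at %s:%d, rejecting all alleles",
                        rna_pileup.seq_id,
                        pos + 1,
                    )
                    res.stats["multiallelic"] += len(accepted_here)
                    continue
                res.stats["multiallelic"] += len(accepted_here) - 1
                accepted_here = accepted_here[:1]
            for site in accepted_here:
                res.stats["accepted"] += 1
                if site.type in EDIT_TYPES:
                    res.sites.append(site)
                else:
                    res.suspects.append(site)
    res.check_conservation()
    return res


def _evaluate_candidate(
    col: PileupColumn,
    alt: str,
    gene: GeneModel,
    contig: str,
    dna_mask: set[int],
    config: CallerConfig,
    observed_read_length: int,
    res: CallResult,
) -> Optional[EditingSite]:
    def reject(rule: str) -> None:
        res.stats[rule] += 1

    if col.pos in dna_mask:
        reject("masked")
        return None
    adjusted = end_exclusion_filter(col, config)
    depth_adj = sum(f + r for f, r in adjusted.values())
    if depth_adj == 0:
        reject("no_usable_depth")
        return None
    alt_fwd, alt_rev = adjusted.get(alt, (0, 0))
    alt_adj = alt_fwd + alt_rev
    if alt_adj < config.min_alt_reads:
        reject("min_alt_reads")
        return None
    freq = alt_adj / depth_adj
    if freq < config.min_variant_frequency:
        reject("min_variant_frequency")
        return None
    p_var = variant_significance(alt_adj, depth_adj, config.assumed_error_rate)
    if p_var > config.max_variant_p:
        reject("variant_p")
        return None
    other_fwd = sum(f for b, (f, r) in adjusted.items() if b != alt)
    other_rev = sum(r for b, (f, r) in adjusted.items() if b != alt)
    p_sb = strand_bias_test(alt_fwd, alt_rev, other_fwd, other_rev)
    if p_sb < config.min_strand_bias_p:
        reject("strand_bias")
        return None
    if not junction_artifact_check(
        col.alt_read_seqs.get(alt, ()), gene, contig, col.pos, config, observed_read_length
    ):
        reject("junction")
        return None
    ref_c, alt_c = _coding_pair(col.ref_base, alt, gene.strand)
    return EditingSite(
        gene_id=gene.gene_id,
        seq_id=gene.seq_id,
        pos0=col.pos,
        ref=ref_c,
        alt=alt_c,
        type=classify_edit(ref_c, alt_c),
        depth=depth_adj,
        alt_reads=alt_adj,
        frequency=freq,
        alt_fwd=alt_fwd,
        alt_rev=alt_rev,
        other_fwd=other_fwd,
        other_rev=other_rev,
        variant_p=p_var,
        strand_bias_p=p_sb,
    )


def consensus_rna(
    gene: GeneModel,
    contig: str,
    sites: Sequence[EditingSite],
    config: CallerConfig,
) -> str:
    """Mature (edited) coding sequence: spliced CDS with every accepted site
    at frequency >= ``consensus_threshold`` replaced by its edited base.
    Sub-threshold sites stay in the table but do not touch the consensus."""
    cds = list(gene.spliced_cds(contig))
    for s in sites:
        if s.gene_id != gene.gene_id or s.frequency < config.consensus_threshold:
            continue
        off = gene.cds_offset(s.pos0)
        if off is None:
            continue
        cds[off] = s.alt  # coding-strand alt by construction
    return "".join(cds)
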