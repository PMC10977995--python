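"""Codon-space mapping and protein-level classification of editing sites.

Each accepted site is mapped through spliced, strand-aware coordinates to a
CDS offset; all accepted edits within one codon are applied jointly and the
genomic and edited codons translated under a configurable genetic code
(default: the standard code, table 1, as used for land-plant organelles).

Effect label precedence: the special categories (start-creation,
stop-creation, stop-removal) take precedence over silent/non-silent in the
single ``effect`` label; for the summary roll-up a codon is silent iff the
translated meaning (amino acid or stop) is unchanged, so silent + non-silent
always equals the number of affected codons.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Data import CodonTable

from .errors import EditomeError, InputError
from .models import CU, UC, ConsequenceRecord, EditingSite, GeneModel

STOP = "*"


def _codon_to_aa(table_id: int) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    out = dict(table.forward_table)
    for codon in table.stop_codons:
        out[codon] = STOP
    return out


class AnnotationError(EditomeError):
    pass


def map_to_cds(site: EditingSite, gene: GeneModel) -> tuple[int, int, int]:
    """(CDS offset, codon index, codon position 1-3) of a site; strand-aware.

    Codons spanning exon junctions are handled naturally because offsets are
    measured on the spliced CDS.  Intronic sites are not mappable.
    """
    off = gene.cds_offset(site.pos0)
    if off is None:
        raise AnnotationError(
            f"site {site.seq_id}:{site.pos0 + 1} is not inside an exon of {site.gene_id}"
        )
    return off, off // 3, off % 3 + 1


def annotate_codon(
    genomic_codon: str,
    edits: Sequence[tuple[int, str]],
    codon_index: int,
    is_terminal: bool = False,
    table_id: int = 1,
) -> tuple[str, str, str, str]:
    """Apply edits (codon-internal position 0-2, coding-strand alt) jointly.

    Returns (edited codon, ref aa, edited aa, effect).  Effect rules:
    start-creation iff codon index 0 and a non-ATG genomic codon becomes ATG;
    stop-creation iff a non-stop codon becomes a stop; stop-removal iff a
    genomic stop becomes a non-stop; otherwise silent iff the amino acid is
    unchanged.
    """
    if len(genomic_codon) != 3 or any(b not in "ACGT" for b in genomic_codon):
        raise AnnotationError(f"cannot annotate codon {genomic_codon!r}")
    if not 1 <= len(edits) <= 3:
        raise AnnotationError(f"expected 1-3 edits in codon, got {len(edits)}")
    aa_of = _codon_to_aa(table_id)
    edited = list(genomic_codon)
    for pos, alt in edits:
        if alt not in "ACGT":
            raise AnnotationError(f"non-ACGT edited base {alt!r}")
        edited[pos] = alt
    edited_codon = "".join(edited)
    if edited_codon == genomic_codon:
        raise AnnotationError("edited codon equals genomic codon")
    ref_aa = aa_of[genomic_codon]
    edited_aa = aa_of[edited_codon]
    if codon_index == 0 and genomic_codon != "ATG" and edited_codon == "ATG":
        effect = "start-creation"
    elif ref_aa != STOP and edited_aa == STOP:
        effect = "stop-creation"
    elif ref_aa == STOP and edited_aa != STOP:
        effect = "stop-removal"
    elif ref_aa == edited_aa:
        effect = "silent"
    else:
        effect = "non-silent"
    return edited_codon, ref_aa, edited_aa, effect


def annotate_sites(
    sites: Sequence[EditingSite],
    genes: Sequence[GeneModel],
    genomes: dict[str, str],
    table_id: int = 1,
) -> list[EditingSite]:
    """Fill the consequence annotation of every site (codon-jointly).

    Sites sharing a codon share its jointly edited codon and effect; each
    site's record additionally carries the provisional effect of that edit
    alone, for transparency.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    by_codon: dict[tuple[str, int], list[tuple[EditingSite, int]]] = {}
    mapped: dict[int, tuple[int, int, int]] = {}
    for i, s in enumerate(sites):
        gene = gene_by_id.get(s.gene_id)
        if gene is None:
            raise InputError(f"no gene model for {s.gene_id}")
        off, ci, cp = map_to_cds(s, gene)
        mapped[i] = (off, ci, cp)
        by_codon.setdefault((s.gene_id, ci), []).append((s, i))

    out: list[EditingSite] = list(sites)
    for (gid, ci), members in by_codon.items():
        gene = gene_by_id[gid]
        cds = gene.spliced_cds(genomes[gene.seq_id])
        n_codons = len(cds) // 3
        codon = cds[ci * 3 : ci * 3 + 3]
        edits = [(mapped[i][0] % 3, s.alt) for s, i in members]
        edited_codon, ref_aa, edited_aa, effect = annotate_codon(
            codon, edits, ci, is_terminal=(ci == n_codons - 1), table_id=table_id
        )
        for s, i in members:
            off, _, cp = mapped[i]
            prov = annotate_codon(
                codon, [(off % 3, s.alt)], ci, is_terminal=(ci == n_codons - 1), table_id=table_id
            )[3]
            rec = ConsequenceRecord(
                gene_id=gid,
                cds_offset=off,
                codon_index=ci,
                codon_pos=cp,
                ref_codon=codon,
                edited_codon=edited_codon,
                ref_aa=ref_aa,
                edited_aa=edited_aa,
                effect=effect,
                is_terminal=(ci == n_codons - 1),
                provisional_effect=prov,
            )
            out[i] = s.with_consequence(rec)
    return out


@dataclass
class EditomeSummary:
    """Editome abundance accounting (one genome or one gene scope).

    Invariants (checked by :meth:`validate`): C-to-U + U-to-C = total;
    codon-position counts sum to total; silent + non-silent = affected codons.
    """

    scope: str
    total: int = 0
    c_to_u: int = 0
    u_to_c: int = 0
    codon_position: dict[int, int] = field(default_factory=lambda: {1: 0, 2: 0, 3: 0})
    start_creation: int = 0
    stop_creation: int = 0
    stop_removal: int = 0
    affected_codons: int = 0
    silent: int = 0
    non_silent: int = 0

    def validate(self) -> None:
        if self.c_to_u + self.u_to_c != self.total:
            raise AssertionError(f"{self.scope}: type counts do not sum to total")
        if sum(self.codon_position.values()) != self.total:
            raise AssertionError(f"{self.scope}: codon-position counts do not sum to total")
        if self.silent + self.non_silent != self.affected_codons:
            raise AssertionError(
                f"{self.scope}: silent + non-silent != affected codons"
            )

    def as_dict(self) -> dict:
        return {
            "scope": self.scope,
            "total": self.total,
            "C-to-U": self.c_to_u,
            "U-to-C": self.u_to_c,
            "codon_position_1": self.codon_position[1],
            "codon_position_2": self.codon_position[2],
            "codon_position_3": self.codon_position[3],
            "start_creation": self.start_creation,
            "stop_creation": self.stop_creation,
            "stop_removal": self.stop_removal,
            "affected_codons": self.affected_codons,
            "silent": self.silent,
            "non_silent": self.non_silent,
        }


def summarize(sites: Sequence[EditingSite], scope: str = "genome") -> EditomeSummary:
    """Roll one scope's annotated sites up into an abundance summary."""
    s = EditomeSummary(scope=scope)
    codons: dict[tuple[str, int], ConsequenceRecord] = {}
    for site in sites:
        rec = site.consequence
        if rec is None:
            raise InputError(f"site {site.gene_id}:{site.pos0 + 1} not annotated")
        if site.type == CU:
            s.c_to_u += 1
        elif site.type == UC:
            s.u_to_c += 1
        else:
            raise InputError(f"suspect site {site.gene_id}:{site.pos0 + 1} in editome summary")
        s.total += 1
        s.codon_position[rec.codon_pos] += 1
        codons[(site.gene_id, rec.codon_index)] = rec
    for rec in codons.values():
        s.affected_codons += 1
        if rec.ref_aa == rec.edited_aa:
            s.silent += 1
        else:
            s.non_silent += 1
        if rec.effect == "start-creation":
            s.start_creation += 1
        elif rec.effect == "stop-creation":
            s.stop_creation += 1
        elif rec.effect == "stop-removal":
            s.stop_removal += 1
    s.validate()
    return s


def summarize_per_gene(sites: Sequence[EditingSite]) -> dict[str, EditomeSummary]:
    by_gene: dict[str, list[EditingSite]] = {}
    for site in sites:
        by_gene.setdefault(site.gene_id, []).append(site)
    return {gid: summarize(ss, scope=gid) for gid, ss in sorted(by_gene.items())}
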