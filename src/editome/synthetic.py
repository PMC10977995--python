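"""Synthetic organellar data with planted, known truth.

Generates reference protein-coding genes (optionally intron-containing, on
either strand), plants a C-to-U / U-to-C editome plus heteroplasmic DNA sites
and A:G/G:A artifact mismatches, and emits aligned DNA and RNA reads so the
whole calling pipeline is testable without any external data or aligner.

Randomness: one :class:`numpy.random.Generator` family seeded from
``config.seed``; each stage uses an independent sub-stream derived by a fixed
offset (``default_rng([seed, k])`` with k = 0 reference, 1 editome, 2 reads,
3 clade helpers), so regenerating any stage is reproducible in isolation.

Reads are emitted already aligned: DNA reads as full-match records on the
contig, RNA reads drawn from the spliced transcript with intron skips encoded
as ``N`` CIGAR operations, so no external aligner is needed at desk scale.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .config import SimulationConfig
from .errors import GenerationError
from .models import CU, UC, GeneModel, TruthEditome, TruthSite, complement, revcomp

STOPS = ("TAA", "TAG", "TGA")
BASES = np.array(list("ACGT"))


@dataclass
class SimRead:
    """One aligned synthetic read (coordinates genome-forward)."""

    qname: str
    seq_id: str
    pos: int  # 0-based leftmost
    cigar: str
    seq: str
    is_reverse: bool


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    return "".join(rng.choice(BASES, size=n, p=_base_probs(gc)))


def _random_codon(rng: np.random.Generator, gc: float) -> str:
    p = _base_probs(gc)
    while True:
        codon = "".join(rng.choice(BASES, size=3, p=p))
        if codon not in STOPS:
            return codon


def generate_reference(
    config: SimulationConfig,
) -> tuple[dict[str, str], list[GeneModel]]:
    """Generate one contig per gene, each carrying a single coding gene.

    Every CDS starts with ATG, ends with exactly one in-frame stop and has no
    internal in-frame stop.  Genes land on either strand with equal
    probability; introns (when drawn) may split codons.  Deterministic for a
    fixed ``config.seed``.
    """
    rng = _rng(config, 0)
    genomes: dict[str, str] = {}
    genes: list[GeneModel] = []
    for i in range(config.n_genes):
        gid = f"g{i + 1:03d}"
        sid = f"ctg{i + 1:03d}"
        lo, hi = config.cds_length_range
        n_codons = int(rng.integers(lo, hi + 1))
        body = "".join(_random_codon(rng, config.gc_target) for _ in range(n_codons - 2))
        stop = STOPS[int(rng.integers(0, 3))]
        cds = "ATG" + body + stop

        intron_at: list[int] = []
        if rng.random() < config.intron_probability:
            n_introns = int(rng.integers(1, 3))
            intron_at = sorted(
                int(x)
                for x in rng.choice(
                    np.arange(3, len(cds) - 3), size=n_introns, replace=False
                )
            )
        ilo, ihi = config.intron_length_range
        introns = [
            "GT" + _random_seq(rng, int(rng.integers(ilo, ihi + 1)) - 4, config.gc_target) + "AG"
            for _ in intron_at
        ]

        # assemble sense-orientation contig and exon intervals
        pieces: list[str] = []
        exons_sense: list[tuple[int, int]] = []
        cursor = config.flank
        prev = 0
        flank_l = _random_seq(rng, config.flank, config.gc_target)
        flank_r = _random_seq(rng, config.flank, config.gc_target)
        pieces.append(flank_l)
        for cut, intron in zip(intron_at + [len(cds)], introns + [None]):
            exon_seq = cds[prev:cut]
            pieces.append(exon_seq)
            exons_sense.append((cursor, cursor + len(exon_seq)))
            cursor += len(exon_seq)
            if intron is not None:
                pieces.append(intron)
                cursor += len(intron)
            prev = cut
        pieces.append(flank_r)
        sense = "".join(pieces)

        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            contig = sense
            exons = tuple(exons_sense)
        else:
            n = len(sense)
            contig = revcomp(sense)
            exons = tuple(sorted((n - e, n - s) for s, e in exons_sense))
        genomes[sid] = contig
        gene = GeneModel(gid, sid, strand, exons, genome=config.genome)
        assert gene.spliced_cds(contig) == cds
        genes.append(gene)
    return genomes, genes


def _eligible(
    genes: Sequence[GeneModel],
    genomes: dict[str, str],
    bases: str,
    used: set[tuple[str, int]],
) -> list[tuple[GeneModel, int, str]]:
    """(gene, cds_offset, base) for coding-strand positions carrying `bases`.

    The start codon (offsets 0-2) is never touched.
    """
    out = []
    for g in genes:
        cds = g.spliced_cds(genomes[g.seq_id])
        for off in range(3, len(cds)):
            if cds[off] in bases and (g.gene_id, off) not in used:
                out.append((g, off, cds[off]))
    return out


def plant_editome(
    genes: Sequence[GeneModel],
    genomes: dict[str, str],
    config: SimulationConfig,
) -> TruthEditome:
    """Plant the ground-truth editome, artifact sites and heteroplasmy.

    Codon positions of editing sites follow ``codon_position_weights``
    (multinomial); edits, artifacts and heteroplasmic sites occupy disjoint
    positions unless ``allow_overlap`` is set.
    """
    rng = _rng(config, 1)
    used: set[tuple[str, int]] = set()
    truth = TruthEditome()

    def take(pool, k, what):
        if len(pool) < k:
            names = sorted({g.gene_id for g, _, _ in pool}) or [g.gene_id for g in genes]
            raise GenerationError(
                f"not enough eligible positions for {what}: need {k}, have "
                f"{len(pool)} (genes {', '.join(names[:5])}...)"
            )
        idx = rng.choice(len(pool), size=k, replace=False)
        return [pool[int(i)] for i in sorted(idx)]

    for etype, base, alt, n in ((CU, "C", "T", config.n_cu_edits), (UC, "T", "C", config.n_uc_edits)):
        if n == 0:
            continue
        counts = rng.multinomial(n, config.codon_position_weights)
        for cp, k in enumerate(counts, start=1):
            if k == 0:
                continue
            pool = [
                e
                for e in _eligible(genes, genomes, base, used)
                if e[1] % 3 == cp - 1
            ]
            for g, off, ref in take(pool, int(k), f"{etype} at codon position {cp}"):
                frac = float(rng.uniform(*config.editing_fraction_range))
                truth.records.append(
                    TruthSite(g.gene_id, g.genomic_pos(off), ref, alt, etype, frac, cp)
                )
                if not config.allow_overlap:
                    used.add((g.gene_id, off))

    if config.n_artifact_sites:
        pool = _eligible(genes, genomes, "AG", used)
        for g, off, ref in take(pool, config.n_artifact_sites, "A:G/G:A artifacts"):
            alt = "G" if ref == "A" else "A"
            frac = float(rng.uniform(*config.artifact_fraction_range))
            truth.records.append(
                TruthSite(
                    g.gene_id, g.genomic_pos(off), ref, alt, "artifact", frac, off % 3 + 1
                )
            )
            if not config.allow_overlap:
                used.add((g.gene_id, off))

    if config.n_heteroplasmic_sites:
        pool = _eligible(genes, genomes, "ACGT", used)
        for g, off, ref in take(pool, config.n_heteroplasmic_sites, "heteroplasmic sites"):
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            frac = float(rng.uniform(*config.heteroplasmy_fraction_range))
            truth.heteroplasmic.append(
                TruthSite(
                    g.gene_id, g.genomic_pos(off), ref, alt, "heteroplasmy", frac, off % 3 + 1
                )
            )
            if not config.allow_overlap:
                used.add((g.gene_id, off))

    truth.records.sort(key=lambda r: (r.gene_id, r.pos0))
    truth.heteroplasmic.sort(key=lambda r: (r.gene_id, r.pos0))
    return truth


def _apply_errors(rng: np.random.Generator, bases: list[str], rate: float) -> None:
    if rate <= 0:
        return
    mask = rng.random(len(bases)) < rate
    for i in np.nonzero(mask)[0]:
        cur = bases[int(i)]
        bases[int(i)] = str(rng.choice([b for b in "ACGT" if b != cur]))


def simulate_reads(
    genes: Sequence[GeneModel],
    genomes: dict[str, str],
    truth: TruthEditome,
    config: SimulationConfig,
) -> tuple[list[SimRead], list[SimRead]]:
    """Draw aligned DNA reads (genomic) and RNA reads (spliced transcript).

    DNA reads carry heteroplasmic alternate bases at their planted fractions;
    RNA reads carry edited/artifact bases at theirs; both get independent
    per-base errors at ``error_rate``.  Read counts equal
    ``round(depth * template_length / read_length)`` exactly.
    """
    rng = _rng(config, 2)
    rl = config.read_length
    dna: list[SimRead] = []
    rna: list[SimRead] = []

    het_by_contig: dict[str, list[tuple[int, str, float]]] = {}
    gene_by_id = {g.gene_id: g for g in genes}
    for h in truth.heteroplasmic:
        g = gene_by_id[h.gene_id]
        alt_fwd = h.alt if g.strand == "+" else complement(h.alt)
        het_by_contig.setdefault(g.seq_id, []).append((h.pos0, alt_fwd, h.fraction))

    for g in genes:
        contig = genomes[g.seq_id]
        if rl > len(contig):
            raise GenerationError(
                f"read_length {rl} exceeds contig {g.seq_id} ({len(contig)} nt)"
            )
        n = round(config.depth * len(contig) / rl)
        starts = rng.integers(0, len(contig) - rl + 1, size=n)
        flips = rng.random(n) < 0.5
        hets = het_by_contig.get(g.seq_id, [])
        for j, s in enumerate(starts):
            s = int(s)
            bases = list(contig[s : s + rl])
            for pos, alt, frac in hets:
                if s <= pos < s + rl and rng.random() < frac:
                    bases[pos - s] = alt
            _apply_errors(rng, bases, config.error_rate)
            dna.append(
                SimRead(f"dna_{g.seq_id}_{j}", g.seq_id, s, f"{rl}M", "".join(bases), bool(flips[j]))
            )

    truth_by_gene = truth.by_gene()
    for g in genes:
        contig = genomes[g.seq_id]
        if rl > g.cds_length:
            raise GenerationError(
                f"read_length {rl} exceeds spliced transcript of {g.gene_id} "
                f"({g.cds_length} nt)"
            )
        # transcript template = spliced CDS plus genomic UTR padding on both
        # sides (organellar transcripts extend beyond the CDS), so coverage is
        # uniform across the whole coding region
        pad = min(config.flank, rl)
        s0, e_end = g.span
        if g.strand == "+":
            tx2g = list(range(s0 - pad, s0)) + g.transcript_to_genome() + list(
                range(e_end, e_end + pad)
            )
            tx = "".join(contig[p] for p in tx2g)
        else:
            tx2g = (
                list(range(e_end + pad - 1, e_end - 1, -1))
                + g.transcript_to_genome()
                + list(range(s0 - 1, s0 - pad - 1, -1))
            )
            tx = "".join(complement(contig[p]) for p in tx2g)
        site_list = [
            (pad + g.cds_offset(r.pos0), r.alt, r.fraction)
            for r in truth_by_gene.get(g.gene_id, [])
        ]
        n = round(config.depth * len(tx) / rl)
        starts = rng.integers(0, len(tx) - rl + 1, size=n)
        flips = rng.random(n) < 0.5
        for j, s in enumerate(starts):
            s = int(s)
            bases = list(tx[s : s + rl])
            for off, alt, frac in site_list:
                if s <= off < s + rl and rng.random() < frac:
                    bases[off - s] = alt
            _apply_errors(rng, bases, config.error_rate)
            gpos = tx2g[s : s + rl]
            if g.strand == "-":
                gpos = gpos[::-1]
                bases = list(revcomp("".join(bases)))
            cigar = _cigar_from_positions(gpos)
            rna.append(
                SimRead(
                    f"rna_{g.gene_id}_{j}", g.seq_id, gpos[0], cigar, "".join(bases), bool(flips[j])
                )
            )
    return dna, rna


def _cigar_from_positions(gpos: Sequence[int]) -> str:
    """CIGAR (M/N only) for an ascending run of covered reference positions."""
    ops: list[str] = []
    run_start = gpos[0]
    prev = gpos[0]
    for p in gpos[1:]:
        if p == prev + 1:
            prev = p
            continue
        ops.append(f"{prev - run_start + 1}M")
        ops.append(f"{p - prev - 1}N")
        run_start = prev = p
    ops.append(f"{prev - run_start + 1}M")
    return "".join(ops)


# ---------------------------------------------------------------------------
# multi-species helpers: clade-structured editomes and diverged alignments
# ---------------------------------------------------------------------------

Clade = object  # nested tuples of species-name strings


def _clade_nodes(tree) -> list[tuple[str, ...]]:
    """All nodes of a nested-tuple tree as tuples of their leaf names (root first)."""
    nodes: list[tuple[str, ...]] = []

    def leaves(t) -> tuple[str, ...]:
        if isinstance(t, str):
            return (t,)
        return tuple(x for child in t for x in leaves(child))

    def walk(t):
        nodes.append(leaves(t))
        if not isinstance(t, str):
            for child in t:
                walk(child)

    walk(tree)
    return nodes


def plant_phylogenetic_editomes(
    genes: Sequence[GeneModel],
    genomes: dict[str, str],
    tree,
    sites_per_branch,
    cu_fraction: float = 0.85,
    seed: int = 0,
) -> tuple[dict[str, set], dict[tuple[str, ...], set]]:
    """Plant per-branch editing sites on a species tree (nested tuples).

    Each node of the tree (including the root and the leaves) receives
    ``sites_per_branch`` sites — an int for every branch, or a mapping from
    node (tuple of its leaf names) to count, so an ancestral-majority editome
    can be planted.  Sites on a branch are shared by exactly the leaves
    beneath it, so the per-species sets respect the phylogeny by construction.

    Returns ``(per_species, per_branch)`` where sites are keyed
    ``(gene_id, cds_offset, edit_type)``.
    """
    rng = np.random.default_rng([seed, 3])
    used: set[tuple[str, int]] = set()
    pools = {
        CU: _eligible(genes, genomes, "C", used),
        UC: _eligible(genes, genomes, "T", used),
    }
    nodes = _clade_nodes(tree)
    per_species: dict[str, set] = {sp: set() for sp in nodes[0]}
    per_branch: dict[tuple[str, ...], set] = {}
    for node in nodes:
        n_here = (
            sites_per_branch
            if isinstance(sites_per_branch, int)
            else sites_per_branch.get(node, 0)
        )
        branch_sites = set()
        for _ in range(n_here):
            etype = CU if rng.random() < cu_fraction else UC
            pool = [e for e in pools[etype] if (e[0].gene_id, e[1]) not in used]
            if not pool:
                raise GenerationError("not enough eligible positions for clade editome")
            g, off, _ = pool[int(rng.integers(0, len(pool)))]
            used.add((g.gene_id, off))
            branch_sites.add((g.gene_id, off, etype))
        per_branch[node] = branch_sites
        for sp in node:
            per_species[sp] |= branch_sites
    return per_species, per_branch


def diverge_alignments(
    genes: Sequence[GeneModel],
    genomes: dict[str, str],
    tree,
    subs_per_branch: int,
    seed: int = 0,
) -> dict[str, dict[str, str]]:
    """Evolve each gene's CDS down a species tree by random substitutions.

    Returns per-gene gapless alignments ``{gene_id: {species: sequence}}``
    (all sequences equal length, so they are their own alignment).
    """
    rng = np.random.default_rng([seed, 4])
    out: dict[str, dict[str, str]] = {g.gene_id: {} for g in genes}

    def mutate(seq: list[str]) -> list[str]:
        seq = seq.copy()
        for _ in range(subs_per_branch):
            i = int(rng.integers(0, len(seq)))
            seq[i] = str(rng.choice([b for b in "ACGT" if b != seq[i]]))
        return seq

    def walk(t, seqs: dict[str, list[str]]):
        seqs = {gid: mutate(s) for gid, s in seqs.items()}
        if isinstance(t, str):
            for gid, s in seqs.items():
                out[gid][t] = "".join(s)
        else:
            for child in t:
                walk(child, seqs)

    ancestral = {g.gene_id: list(g.spliced_cds(genomes[g.seq_id])) for g in genes}
    walk(tree, ancestral)
    return out
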