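"""Readers and writers for every standard format the pipeline touches.

FASTA via Biopython, GFF3 via gffutils (in-memory db), SAM via pysam, tables
via pandas.  Public file coordinates are 1-based inclusive (GFF3, edit table
``pos1``); everything in memory is 0-based half-open.

Only ``gene``, ``exon`` and ``CDS`` features are consumed from GFF3; other
feature types are ignored with a warning (organellar annotations vary widely).
Genes whose reference sequence contains ambiguity codes are flagged and those
positions auto-masked by the caller.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gffutils
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ContractError, FormatError
from .models import EditingSite, GeneModel, TruthEditome, TruthSite
from .synthetic import SimRead

log = logging.getLogger(__name__)

EDIT_TABLE_COLUMNS = [
    "gene_id",
    "pos1",
    "ref",
    "alt",
    "type",
    "depth",
    "alt_reads",
    "frequency",
    "codon_index",
    "codon_pos",
    "ref_codon",
    "edited_codon",
    "ref_aa",
    "edited_aa",
    "effect",
    "hydropathy_from",
    "hydropathy_to",
]

TRUTH_COLUMNS = ["gene_id", "pos0", "ref", "alt", "type", "fraction", "codon_pos"]


def to_1based(pos0: int) -> int:
    """0-based half-open start -> 1-based inclusive position."""
    return pos0 + 1


def to_0based(pos1: int) -> int:
    return pos1 - 1


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not seqs:
        raise FormatError(f"no sequences in {path}")
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")  # wraps at 60 columns


def ambiguous_positions(seq: str) -> list[int]:
    return [i for i, b in enumerate(seq) if b not in "ACGT"]


# ---------------------------------------------------------------------------
# GFF3 gene models
# ---------------------------------------------------------------------------

def write_gene_models(genes: Sequence[GeneModel], path: str | Path) -> None:
    """GFF3 (1-based inclusive) with gene/exon/CDS rows; CDS rows carry phase."""
    lines = ["##gff-version 3"]
    for g in genes:
        s0, e0 = g.span
        attrs = f"ID={g.gene_id};genome={g.genome}"
        lines.append(
            "\t".join(
                [g.seq_id, "editome", "gene", str(s0 + 1), str(e0), ".", g.strand, ".", attrs]
            )
        )
        order = list(g.exons) if g.strand == "+" else list(g.exons)[::-1]
        cum = 0
        phases = {}
        for ex in order:
            phases[ex] = (3 - cum % 3) % 3
            cum += ex[1] - ex[0]
        for i, (s, e) in enumerate(g.exons):
            for ftype, phase in (("exon", "."), ("CDS", str(phases[(s, e)]))):
                lines.append(
                    "\t".join(
                        [
                            g.seq_id,
                            "editome",
                            ftype,
                            str(s + 1),
                            str(e),
                            ".",
                            g.strand,
                            phase,
                            f"ID={ftype}-{g.gene_id}-{i + 1};Parent={g.gene_id}",
                        ]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_models(
    gff3_path: str | Path, fasta_path: str | Path
) -> tuple[dict[str, str], list[GeneModel]]:
    """Load gene models and verify each spliced CDS is a translatable frame.

    Checks: features inside sequence bounds, consistent strand, CDS length a
    multiple of 3, ATG start.  Reverse-strand genes are handled in coding
    orientation by :meth:`GeneModel.spliced_cds`.
    """
    genomes = read_fasta(fasta_path)
    try:
        db = gffutils.create_db(
            str(gff3_path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises plain ValueError on bad GFF
        raise FormatError(f"cannot parse GFF3 {gff3_path}: {exc}") from exc

    genes: list[GeneModel] = []
    seen_types = set(db.featuretypes())
    for extra in seen_types - {"gene", "exon", "CDS"}:
        log.warning("ignoring GFF3 feature type %r", extra)

    for feat in db.features_of_type("gene"):
        gid = feat.id
        if feat.seqid not in genomes:
            raise FormatError(f"gene {gid}: unknown sequence {feat.seqid}")
        contig = genomes[feat.seqid]
        cds_feats = list(db.children(feat, featuretype="CDS", order_by="start"))
        if not cds_feats:
            cds_feats = list(db.children(feat, featuretype="exon", order_by="start"))
        if not cds_feats:
            raise FormatError(f"gene {gid}: no CDS or exon children")
        exons = []
        strands = {c.strand for c in cds_feats} | {feat.strand}
        if len(strands) != 1:
            raise FormatError(f"gene {gid}: inconsistent strand across features")
        for c in cds_feats:
            if c.start < 1 or c.end > len(contig):
                raise FormatError(
                    f"gene {gid}: feature {c.start}-{c.end} outside {feat.seqid} "
                    f"(length {len(contig)})"
                )
            exons.append((c.start - 1, c.end))
        genome_type = (feat.attributes.get("genome") or ["mitogenome"])[0]
        try:
            gene = GeneModel(gid, feat.seqid, feat.strand, tuple(sorted(exons)), genome_type)
        except ValueError as exc:
            raise FormatError(f"gene {gid}: {exc}") from exc
        cds = gene.spliced_cds(contig)
        if len(cds) % 3 != 0:
            raise FormatError(f"gene {gid}: CDS length {len(cds)} not divisible by 3")
        if not cds.startswith("ATG"):
            raise FormatError(f"gene {gid}: spliced CDS does not start with ATG")
        amb = ambiguous_positions(cds)
        if amb:
            log.warning("gene %s: %d ambiguous CDS positions will be masked", gid, len(amb))
        genes.append(gene)
    return genomes, genes


# ---------------------------------------------------------------------------
# SAM alignments
# ---------------------------------------------------------------------------

def write_sam(
    reads: Iterable[SimRead], genomes: dict[str, str], path: str | Path
) -> None:
    """Write coordinate-sorted text SAM for synthetic reads."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": sid, "LN": len(seq)} for sid, seq in genomes.items()],
    }
    order = {sid: i for i, sid in enumerate(genomes)}
    sorted_reads = sorted(reads, key=lambda r: (order[r.seq_id], r.pos, r.qname))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for r in sorted_reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.qname
            a.flag = 16 if r.is_reverse else 0
            a.reference_id = order[r.seq_id]
            a.reference_start = r.pos
            a.mapping_quality = 60
            a.cigarstring = r.cigar
            a.query_sequence = r.seq
            out.write(a)


def read_alignments(path: str | Path) -> Iterator[pysam.AlignedSegment]:
    """Yield mapped, primary, non-duplicate records from a SAM/BAM file.

    Skipped records (unmapped/secondary/supplementary/duplicate) are tallied
    in a debug log line at exhaustion.
    """
    try:
        af = pysam.AlignmentFile(str(path), check_sq=True)
    except ValueError as exc:
        raise FormatError(f"cannot open alignments {path}: {exc}") from exc
    if af.header.nreferences == 0:
        raise FormatError(f"{path}: SAM header has no reference sequences")
    skipped = 0
    for rec in af:
        if (
            rec.is_unmapped
            or rec.is_secondary
            or rec.is_supplementary
            or rec.is_duplicate
        ):
            skipped += 1
            continue
        yield rec
    af.close()
    if skipped:
        log.debug("read_alignments(%s): skipped %d non-primary/unmapped records", path, skipped)


# ---------------------------------------------------------------------------
# edit table TSV
# ---------------------------------------------------------------------------

def _site_row(s: EditingSite) -> dict:
    c = s.consequence
    if c is None:
        raise ContractError(f"site {s.gene_id}:{s.pos0 + 1} is not annotated")
    return {
        "gene_id": s.gene_id,
        "pos1": s.pos0 + 1,
        "ref": s.ref,
        "alt": s.alt,
        "type": s.type,
        "depth": s.depth,
        "alt_reads": s.alt_reads,
        "frequency": f"{s.frequency:.4f}",
        "codon_index": c.codon_index,
        "codon_pos": c.codon_pos,
        "ref_codon": c.ref_codon,
        "edited_codon": c.edited_codon,
        "ref_aa": c.ref_aa,
        "edited_aa": c.edited_aa,
        "effect": c.effect,
        "hydropathy_from": s.hydropathy_from or "",
        "hydropathy_to": s.hydropathy_to or "",
    }


def write_edit_table(sites: Sequence[EditingSite], path: str | Path) -> None:
    """Fixed-column TSV of annotated sites; round-trips via read_edit_table."""
    df = pd.DataFrame([_site_row(s) for s in sites], columns=EDIT_TABLE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_edit_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"hydropathy_from": "string", "hydropathy_to": "string"},
        keep_default_na=False,
        na_values=[],
    )
    missing = set(EDIT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing edit-table columns {sorted(missing)}")
    for col in ("pos1", "depth", "alt_reads", "codon_index", "codon_pos"):
        df[col] = df[col].astype(int)
    df["frequency"] = df["frequency"].astype(float)
    return df


# ---------------------------------------------------------------------------
# truth table TSV
# ---------------------------------------------------------------------------

def write_truth_table(truth: TruthEditome, path: str | Path) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "pos0": r.pos0,
            "ref": r.ref,
            "alt": r.alt,
            "type": r.type,
            "fraction": f"{r.fraction:.6f}",
            "codon_pos": r.codon_pos,
        }
        for r in list(truth.records) + list(truth.heteroplasmic)
    ]
    pd.DataFrame(rows, columns=TRUTH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> TruthEditome:
    df = pd.read_csv(path, sep="\t")
    truth = TruthEditome()
    for row in df.itertuples(index=False):
        site = TruthSite(
            row.gene_id, int(row.pos0), row.ref, row.alt, row.type,
            float(row.fraction), row.codon_pos,
        )
        (truth.heteroplasmic if row.type == "heteroplasmy" else truth.records).append(site)
    return truth


# ---------------------------------------------------------------------------
# aligned FASTA (gap char '-')
# ---------------------------------------------------------------------------

def read_aligned_fasta(path: str | Path) -> dict[str, str]:
    aln = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if not aln:
        raise FormatError(f"no sequences in alignment {path}")
    lengths = {len(s) for s in aln.values()}
    if len(lengths) != 1:
        raise FormatError(f"{path}: aligned sequences have unequal lengths {sorted(lengths)}")
    return aln


def write_aligned_fasta(aln: dict[str, str], path: str | Path) -> None:
    write_fasta(aln, path)
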