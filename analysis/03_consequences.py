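#!/usr/bin/env python
"""Summarize the called editome into abundance tables.

Produces the per-genome and per-gene accounting (edit types, codon
positions, start/stop events, silent vs non-silent affected codons) and
prints the genome-level table.
"""
from pathlib import Path
import sys

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from editome import io as eio
from editome.consequence import annotate_sites, summarize, summarize_per_gene
from editome.models import EditingSite
from editome.pipeline import report

ROOT = Path(__file__).resolve().parent.parent / "results"
STUDY = Path(__file__).resolve().parent.parent / "scratch" / "study"


def sites_from_table(df: pd.DataFrame, genes) -> list[EditingSite]:
    by_id = {g.gene_id: g for g in genes}
    return [
        EditingSite(
            gene_id=r.gene_id, seq_id=by_id[r.gene_id].seq_id, pos0=int(r.pos1) - 1,
            ref=r.ref, alt=r.alt, type=r.type, depth=int(r.depth),
            alt_reads=int(r.alt_reads), frequency=float(r.frequency),
        )
        for r in df.itertuples(index=False)
    ]


def main() -> None:
    genomes, genes = eio.read_gene_models(STUDY / "genes.gff3", STUDY / "reference.fa")
    df = eio.read_edit_table(ROOT / "sites.tsv")
    sites = annotate_sites(sites_from_table(df, genes), genes, genomes)

    genome = summarize(sites, scope="genome")
    per_gene = summarize_per_gene(sites)
    rows = [genome.as_dict()] + [s.as_dict() for s in per_gene.values()]
    pd.DataFrame(rows).to_csv(ROOT / "summary.tsv", sep="\t", index=False)
    print(report({"genome": genome}))
    print(f"wrote {ROOT / 'summary.tsv'} ({len(rows)} scopes)")


if __name__ == "__main__":
    main()
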