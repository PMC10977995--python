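#!/usr/bin/env python
"""Tabulate hydrophobicity conversions of the non-silent edits.

Classifies the before/after residues of every affected codon on the
Kyte-Doolittle scale and writes the 4x4 conversion matrix; prints the
fraction of conversions that strictly increase hydrophobicity.
"""
from pathlib import Path
import sys

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from editome import io as eio
from editome.consequence import annotate_sites
from editome.hydropathy import HydropathyScale, conversion_counts_for_sites

ROOT = Path(__file__).resolve().parent.parent / "results"
STUDY = Path(__file__).resolve().parent.parent / "scratch" / "study"


def main() -> None:
    genomes, genes = eio.read_gene_models(STUDY / "genes.gff3", STUDY / "reference.fa")
    df = eio.read_edit_table(ROOT / "sites.tsv")

    # rebuild and annotate sites from the table (shared helper in step 03)
    from importlib.machinery import SourceFileLoader

    mod = SourceFileLoader(
        "_step3", str(Path(__file__).with_name("03_consequences.py"))
    ).load_module()
    sites = annotate_sites(mod.sites_from_table(df, genes), genes, genomes)

    matrix = conversion_counts_for_sites(sites)
    matrix.counts.to_csv(ROOT / "hydropathy_matrix.tsv", sep="\t")
    HydropathyScale.default().to_tsv(ROOT / "hydropathy_scale.tsv")
    print(matrix.counts)
    print(f"classifiable conversions: {matrix.total}")
    print(f"silent codons: {matrix.silent}, unclassifiable (stop involved): {matrix.unclassifiable}")
    print(f"toward-hydrophobic fraction: {matrix.toward_hydrophobic_fraction:.3f}")


if __name__ == "__main__":
    main()
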