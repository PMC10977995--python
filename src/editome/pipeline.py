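"""End-to-end orchestration: simulate -> call -> annotate -> report.

Every run writes a machine-readable manifest (config echo, input checksums,
per-stage record counts, package versions, seed).  Candidate fates obey a
conservation identity: accepted + per-rule rejections = total candidates,
with each candidate attributed to its first failing rule in the fixed order
mask -> end-exclusion depth -> count -> frequency -> variant-p -> strand-bias
-> junction -> multi-allelic resolution.
"""
from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .caller import CallResult, build_pileup, call_sites, consensus_rna, mask_heteroplasmy
from .config import CallerConfig, SimulationConfig
from .consequence import EditomeSummary, annotate_sites, summarize, summarize_per_gene
from .errors import InputError
from .hydropathy import (
    ConversionMatrix,
    HydropathyScale,
    annotate_hydropathy,
    conversion_counts_for_sites,
)
from .models import EditingSite, GeneModel
from . import io as eio
from .synthetic import generate_reference, plant_editome, simulate_reads

log = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _versions() -> dict[str, str]:
    import pysam
    import scipy

    return {
        "editome": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "pysam": pysam.__version__,
    }


@dataclass
class RunManifest:
    seed: Optional[int] = None
    config: dict = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    stages: dict[str, dict] = field(default_factory=dict)
    versions: dict[str, str] = field(default_factory=_versions)
    failed_stage: Optional[str] = None

    def add_inputs(self, *paths: str | Path) -> None:
        for p in paths:
            self.inputs[str(p)] = _sha256(Path(p))

    def check_fate_conservation(self) -> None:
        call = self.stages.get("call")
        if not call:
            return
        total = call["candidates"]
        fates = call["accepted"] + sum(
            v for k, v in call.items() if k not in ("candidates", "accepted")
        )
        if fates != total:
            raise AssertionError(
                f"manifest fate conservation violated: {fates} != {total}"
            )

    def write(self, path: str | Path) -> None:
        self.check_fate_conservation()
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def simulate_stage(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate reference, truth and reads; write FASTA/GFF3/SAM/TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genomes, genes = generate_reference(config)
    truth = plant_editome(genes, genomes, config)
    dna, rna = simulate_reads(genes, genomes, truth, config)
    paths = {
        "reference": out / "reference.fa",
        "genes": out / "genes.gff3",
        "dna": out / "dna.sam",
        "rna": out / "rna.sam",
        "truth": out / "truth.tsv",
        "config": out / "simulation.json",
    }
    eio.write_fasta(genomes, paths["reference"])
    eio.write_gene_models(genes, paths["genes"])
    eio.write_sam(dna, genomes, paths["dna"])
    eio.write_sam(rna, genomes, paths["rna"])
    eio.write_truth_table(truth, paths["truth"])
    config.to_json(paths["config"])
    return paths


@dataclass
class CallOutputs:
    sites: list[EditingSite]
    suspects: list[EditingSite]
    consensus: dict[str, str]  # gene_id -> mature coding sequence
    stats: dict[str, int]
    masked_positions: int


def _reads_by_contig(sam_path: str | Path):
    return itertools.groupby(eio.read_alignments(sam_path), key=lambda r: r.reference_name)


def call_stage(
    genomes: dict[str, str],
    genes: Sequence[GeneModel],
    dna_sam: str | Path,
    rna_sam: str | Path,
    config: CallerConfig,
    annotate: bool = True,
) -> CallOutputs:
    """Build pileups contig by contig and run the filter cascade."""
    genes_by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_contig.setdefault(g.seq_id, []).append(g)

    masks: dict[str, set[int]] = {}
    n_masked = 0
    for contig, reads in _reads_by_contig(dna_sam):
        if contig not in genomes:
            raise InputError(f"DNA reads aligned to unknown contig {contig}")
        pile = build_pileup(reads, contig, genomes[contig], collect_read_seqs=False)
        masks[contig] = mask_heteroplasmy(pile, config)
        n_masked += len(masks[contig])

    result = CallResult()
    for contig, reads in _reads_by_contig(rna_sam):
        if contig not in genomes:
            raise InputError(f"RNA reads aligned to unknown contig {contig}")
        contig_genes = genes_by_contig.get(contig, [])
        if not contig_genes:
            continue
        pile = build_pileup(reads, contig, genomes[contig])
        call_sites(pile, masks.get(contig, set()), genomes[contig], contig_genes, config, result)

    sites, suspects = result.sites, result.suspects
    if annotate:
        sites = annotate_sites(sites, genes, genomes)
        annotate_hydropathy(sites)
        try:
            suspects = annotate_sites(suspects, genes, genomes)
            annotate_hydropathy(suspects)
        except Exception:  # suspects may sit on unannotatable codons; keep raw
            log.warning("could not annotate suspect sites; writing them unannotated")

    consensus = {
        g.gene_id: consensus_rna(g, genomes[g.seq_id], sites, config) for g in genes
    }
    return CallOutputs(
        sites=sites,
        suspects=suspects,
        consensus=consensus,
        stats=dict(result.stats),
        masked_positions=n_masked,
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

SUMMARY_ROWS = [
    ("Total of C -> U and U -> C", "total"),
    ("C -> U", "C-to-U"),
    ("U -> C", "U-to-C"),
    ("1st codon position", "codon_position_1"),
    ("2nd codon position", "codon_position_2"),
    ("3rd codon position", "codon_position_3"),
    ("Start codon creation", "start_creation"),
    ("Stop codon creation", "stop_creation"),
    ("Stop codon removal", "stop_removal"),
    ("Total of affected codon", "affected_codons"),
    ("Silent", "silent"),
    ("Non-silent", "non_silent"),
]


def report(
    summaries: dict[str, EditomeSummary],
    venn=None,
    matrix: Optional[ConversionMatrix] = None,
    diversity: Optional[pd.DataFrame] = None,
    correlation: Optional[dict] = None,
) -> str:
    """Human-readable run report: abundance tables plus optional sections.

    Refuses to render if any summary violates its conservation identities.
    """
    lines: list[str] = []
    for scope, s in summaries.items():
        s.validate()  # raises naming the violated identity
        d = s.as_dict()
        lines.append(f"== RNA-editing abundance [{scope}] ==")
        for label, key in SUMMARY_ROWS:
            lines.append(f"{label:28s} {d[key]}")
        lines.append("")
    if venn is not None:
        lines.append("== Shared / exclusive sites ==")
        lines.append(venn.as_frame().to_string(index=False))
        lines.append(f"shared by all: {venn.shared_by_all} / union {venn.union_size} "
                     f"({100 * venn.shared_by_all_proportion:.1f}%)")
        lines.append("")
    else:
        lines.append("(single-species run: shared/exclusive section omitted)")
        lines.append("")
    if matrix is not None:
        lines.append("== Hydrophobicity conversions (before -> after) ==")
        lines.append(matrix.counts.to_string())
        lines.append(
            f"toward-hydrophobic fraction: {matrix.toward_hydrophobic_fraction:.3f}"
        )
        lines.append("")
    if diversity is not None:
        lines.append("== Nucleotide diversity (pi), DNA vs mature RNA ==")
        lines.append(diversity.to_string(index=False))
        lines.append("")
    if correlation is not None:
        lines.append("== GC% vs editing abundance ==")
        lines.append(json.dumps(correlation, indent=2, default=float))
        lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: dict | str | Path, out_dir: Optional[str | Path] = None) -> Path:
    """Run simulate -> call -> annotate -> report from a single JSON config.

    The config may hold ``simulation`` and ``caller`` sections plus
    ``out_dir``; re-running with the same config and seed reproduces
    byte-identical TSV/JSON outputs.  Returns the run directory.
    """
    if not isinstance(config, dict):
        config = json.loads(Path(config).read_text())
    run_dir = Path(out_dir or config.get("out_dir", "editome_run"))
    run_dir.mkdir(parents=True, exist_ok=True)
    sim_config = SimulationConfig.from_dict(config.get("simulation", {}))
    caller_config = CallerConfig.from_dict(config.get("caller", {}))

    manifest = RunManifest(seed=sim_config.seed, config=config)
    stage = "simulate"
    try:
        paths = simulate_stage(sim_config, run_dir)
        truth = eio.read_truth_table(paths["truth"])
        manifest.add_inputs(paths["reference"], paths["genes"], paths["dna"], paths["rna"])
        manifest.stages["simulate"] = {
            "genes": sim_config.n_genes,
            "truth_edits": len(truth.editing_records),
            "truth_artifacts": len(truth.artifact_records),
            "heteroplasmic_sites": len(truth.heteroplasmic),
        }

        stage = "call"
        genomes, genes = eio.read_gene_models(paths["genes"], paths["reference"])
        outputs = call_stage(genomes, genes, paths["dna"], paths["rna"], caller_config)
        eio.write_edit_table(outputs.sites, run_dir / "sites.tsv")
        if outputs.suspects and outputs.suspects[0].consequence is not None:
            eio.write_edit_table(outputs.suspects, run_dir / "suspects.tsv")
        eio.write_fasta(outputs.consensus, run_dir / "consensus.fa")
        manifest.stages["call"] = outputs.stats

        stage = "annotate"
        summary = summarize(outputs.sites, scope="genome")
        per_gene = summarize_per_gene(outputs.sites)
        rows = [summary.as_dict()] + [s.as_dict() for s in per_gene.values()]
        pd.DataFrame(rows).to_csv(run_dir / "summary.tsv", sep="\t", index=False)
        (run_dir / "summary.json").write_text(
            json.dumps({r["scope"]: r for r in rows}, indent=2) + "\n"
        )
        matrix = conversion_counts_for_sites(outputs.sites)
        matrix.counts.to_csv(run_dir / "hydropathy_matrix.tsv", sep="\t")
        manifest.stages["annotate"] = {
            "annotated_sites": len(outputs.sites),
            "suspect_sites": len(outputs.suspects),
        }

        stage = "report"
        text = report({"genome": summary}, matrix=matrix)
        (run_dir / "report.txt").write_text(text)
    except Exception:
        manifest.failed_stage = stage
        manifest.write(run_dir / "manifest.json")
        raise
    manifest.write(run_dir / "manifest.json")
    return run_dir
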