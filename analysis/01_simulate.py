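#!/usr/bin/env python
"""Generate the synthetic organellar study used by the downstream analyses.

Writes the reference genes (FASTA + GFF3), the planted truth editome, and
coordinate-sorted DNA/RNA alignments under results/study/.
"""
from pathlib import Path
import sys

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from editome import io as eio
from editome.config import SimulationConfig
from editome.pipeline import simulate_stage

OUT = Path(__file__).resolve().parent.parent / "scratch" / "study"


def main() -> None:
    cfg = SimulationConfig(seed=1)
    paths = simulate_stage(cfg, OUT)
    truth = eio.read_truth_table(paths["truth"])
    print(f"simulated {cfg.n_genes} genes at depth {cfg.depth}x")
    print(
        f"planted {len(truth.editing_records)} editing sites "
        f"({cfg.n_cu_edits} C-to-U, {cfg.n_uc_edits} U-to-C), "
        f"{len(truth.artifact_records)} artifact sites, "
        f"{len(truth.heteroplasmic)} heteroplasmic DNA positions"
    )
    for k, v in paths.items():
        print(f"  {k}: {v}")


if __name__ == "__main__":
    main()
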