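"""Shared fixtures: small synthetic studies and hand-built gene models."""
from __future__ import annotations

import pytest

from editome import io as eio
from editome.config import CallerConfig, SimulationConfig
from editome.models import GeneModel
from editome.pipeline import call_stage, simulate_stage
from editome.synthetic import generate_reference, plant_editome


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast study: few genes, few sites, moderate depth."""
    return SimulationConfig(
        n_genes=4,
        cds_length_range=(80, 150),
        n_cu_edits=30,
        n_uc_edits=8,
        n_heteroplasmic_sites=4,
        n_artifact_sites=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_reference(small_config):
    genomes, genes = generate_reference(small_config)
    return genomes, genes


@pytest.fixture(scope="session")
def small_truth(small_reference, small_config):
    genomes, genes = small_reference
    return plant_editome(genes, genomes, small_config)


@pytest.fixture(scope="session")
def small_study(tmp_path_factory, small_config):
    """Full simulated study on disk plus loaded models."""
    out = tmp_path_factory.mktemp("study")
    paths = simulate_stage(small_config, out)
    genomes, genes = eio.read_gene_models(paths["genes"], paths["reference"])
    truth = eio.read_truth_table(paths["truth"])
    return {"paths": paths, "genomes": genomes, "genes": genes, "truth": truth}


@pytest.fixture(scope="session")
def small_call(small_study):
    return call_stage(
        small_study["genomes"],
        small_study["genes"],
        small_study["paths"]["dna"],
        small_study["paths"]["rna"],
        CallerConfig(),
    )


@pytest.fixture
def plus_gene() -> GeneModel:
    """Single-exon plus-strand gene on [10, 100)."""
    return GeneModel("gP", "chr1", "+", ((10, 100),))


@pytest.fixture
def split_gene() -> GeneModel:
    """Two-exon plus-strand gene: [10, 40) + [60, 120)."""
    return GeneModel("gS", "chr1", "+", ((10, 40), (60, 120)))


@pytest.fixture
def minus_gene() -> GeneModel:
    """Two-exon minus-strand gene: transcription right-to-left."""
    return GeneModel("gM", "chr1", "-", ((10, 40), (60, 120)))
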