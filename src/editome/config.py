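"""Run configuration for the simulator and the editing-site caller."""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from .errors import ConfigurationError


def _check_range(name: str, rng, lo=None, hi=None) -> None:
    a, b = rng
    if a > b:
        raise ConfigurationError(f"{name} must be ordered low <= high, got {rng}")
    for v in (a, b):
        if lo is not None and v < lo or hi is not None and v > hi:
            raise ConfigurationError(f"{name} out of bounds {rng}")


@dataclass
class SimulationConfig:
    """Conditions of a synthetic organellar editome study.

    Defaults emulate a desk-scale lycophyte-like organellar dataset: ~38% GC
    coding regions, a C-to-U dominated editome with a 2nd > 1st > 3rd codon
    position spectrum, partial editing fractions, a few heteroplasmic DNA
    positions and low-frequency A:G/G:A artifact mismatches.
    """

    n_genes: int = 20
    cds_length_range: tuple[int, int] = (120, 400)  # codons
    intron_probability: float = 0.5
    intron_length_range: tuple[int, int] = (80, 300)  # nt
    gc_target: float = 0.38
    n_cu_edits: int = 250
    n_uc_edits: int = 50
    codon_position_weights: tuple[float, float, float] = (0.34, 0.48, 0.18)
    editing_fraction_range: tuple[float, float] = (0.2, 1.0)
    n_heteroplasmic_sites: int = 10
    heteroplasmy_fraction_range: tuple[float, float] = (0.25, 0.45)
    n_artifact_sites: int = 10
    artifact_fraction_range: tuple[float, float] = (0.01, 0.04)
    read_length: int = 100
    depth: int = 50
    error_rate: float = 0.001
    seed: int = 0
    genome: str = "mitogenome"
    flank: int = 120  # non-coding padding per contig; also the UTR of transcripts
    allow_overlap: bool = False  # permit edits/heteroplasmy/artifacts to collide

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigurationError("n_genes must be >= 1")
        _check_range("cds_length_range", self.cds_length_range, lo=2)
        _check_range("intron_length_range", self.intron_length_range, lo=10)
        _check_range("editing_fraction_range", self.editing_fraction_range, 0.0, 1.0)
        _check_range(
            "heteroplasmy_fraction_range", self.heteroplasmy_fraction_range, 0.0, 1.0
        )
        _check_range("artifact_fraction_range", self.artifact_fraction_range, 0.0, 1.0)
        for name in ("intron_probability", "gc_target", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        w = self.codon_position_weights
        if len(w) != 3 or abs(sum(w) - 1.0) > 1e-9 or min(w) < 0:
            raise ConfigurationError(
                f"codon_position_weights must be 3 non-negative fractions summing to 1, got {w}"
            )
        if self.read_length < 1 or self.depth < 1:
            raise ConfigurationError("read_length and depth must be >= 1")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown simulation keys: {sorted(unknown)}")
        d = {
            k: tuple(v) if isinstance(v, list) else v
            for k, v in d.items()
        }
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class CallerConfig:
    """Thresholds of the DNA:RNA mismatch filter cascade.

    Defaults: variant frequency >= 4.6% with >= 3 supporting reads (both
    inclusive); DNA positions with non-reference fraction >= 0.25 masked as
    heteroplasmic/ambiguous; binomial variant p <= 1e-6 under a flat assumed
    sequencing error rate (1e-3, ~Q30); two-sided Fisher strand-bias p >= 1e-5;
    bases within 6 nt of a read end excluded from tallies; consensus edits
    applied at >= 60% frequency.
    """

    min_variant_frequency: float = 0.046
    min_alt_reads: int = 3
    heteroplasmy_min_frequency: float = 0.25
    max_variant_p: float = 1e-6
    min_strand_bias_p: float = 1e-5
    read_end_exclusion: int = 6
    junction_window: int | None = None  # None -> observed read length
    consensus_threshold: float = 0.60
    assumed_error_rate: float = 1e-3
    call_introns: bool = False  # diagnostics: extend calling outside CDS exons

    def __post_init__(self) -> None:
        for name in (
            "min_variant_frequency",
            "heteroplasmy_min_frequency",
            "consensus_threshold",
            "assumed_error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0,1], got {v}")
        if self.min_alt_reads < 1:
            raise ConfigurationError("min_alt_reads must be >= 1")
        if self.read_end_exclusion < 0:
            raise ConfigurationError("read_end_exclusion must be >= 0")

    @classmethod
    def from_dict(cls, d: dict) -> "CallerConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown caller keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "CallerConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))
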