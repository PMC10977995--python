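"""Cross-species editome comparison, nucleotide diversity, GC correlation.

Editing sites of different species are "the same" iff they fall in the same
gene, the same column of that gene's (externally produced) alignment, and
carry the same edit type; Venn cells over species subsets are computed by
exact set algebra.  Nucleotide diversity follows the classic per-site
definition with complete deletion: columns containing a gap or ambiguity in
any sequence are excluded entirely, pi is the mean pairwise difference
fraction over the remaining sites.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError


# ---------------------------------------------------------------------------
# alignment column maps
# ---------------------------------------------------------------------------

def column_map(aligned_seq: str, gap: str = "-") -> np.ndarray:
    """Alignment column of every ungapped position (strictly increasing)."""
    arr = np.frombuffer(aligned_seq.encode(), dtype="S1")
    return np.nonzero(arr != gap.encode())[0]


def map_sites_to_alignment(
    alignment: Mapping[str, str],
    sites_by_species: Mapping[str, Iterable[tuple]],
    ungapped_check: Optional[Mapping[str, str]] = None,
) -> dict[str, dict[tuple, dict]]:
    """Re-key each species' sites from ungapped CDS coordinates to columns.

    ``sites_by_species[sp]`` holds ``(cds_offset, edit_type)`` tuples or
    ``(cds_offset, edit_type, attrs_dict)``.  If ``ungapped_check`` is given,
    each species' degapped aligned sequence must equal it exactly.

    Returns per species ``{(column, edit_type): attrs}``.
    """
    out: dict[str, dict[tuple, dict]] = {}
    for sp, sites in sites_by_species.items():
        if sp not in alignment:
            raise InputError(f"species {sp} absent from alignment")
        aligned = alignment[sp]
        if ungapped_check is not None:
            degapped = aligned.replace("-", "")
            expect = ungapped_check[sp]
            if degapped != expect:
                diff = next(
                    (i for i, (a, b) in enumerate(zip(degapped, expect)) if a != b),
                    min(len(degapped), len(expect)),
                )
                raise InputError(
                    f"{sp}: ungapped aligned sequence differs from CDS at position {diff}"
                )
        cmap = column_map(aligned)
        mapped: dict[tuple, dict] = {}
        for site in sites:
            off, etype = site[0], site[1]
            attrs = dict(site[2]) if len(site) > 2 else {}
            if off >= len(cmap):
                raise InputError(f"{sp}: site offset {off} beyond ungapped length {len(cmap)}")
            mapped[(int(cmap[off]), etype)] = attrs
        out[sp] = mapped
    return out


# ---------------------------------------------------------------------------
# shared / exclusive partitioning
# ---------------------------------------------------------------------------

@dataclass
class SharedSiteReport:
    """Venn-cell counts over species subsets, overall and per stratum."""

    species: tuple[str, ...]
    cells: dict[frozenset, int]
    stratified: dict[str, dict[object, dict[frozenset, int]]] = field(default_factory=dict)
    union_size: int = 0
    shared_by_all: int = 0

    @property
    def shared_by_all_proportion(self) -> float:
        return self.shared_by_all / self.union_size if self.union_size else float("nan")

    def cell(self, *species: str) -> int:
        return self.cells.get(frozenset(species), 0)

    def as_frame(self) -> pd.DataFrame:
        rows = []
        for subset in sorted(self.cells, key=lambda s: (len(s), sorted(s))):
            rows.append(
                {"species": "&".join(sorted(subset)), "n_species": len(subset),
                 "count": self.cells[subset]}
            )
        return pd.DataFrame(rows)


def shared_exclusive(
    site_sets: Mapping[str, Iterable],
    attrs: Optional[Mapping[str, Mapping]] = None,
    strata: Sequence[str] = (),
) -> SharedSiteReport:
    """Partition sites into exact species-subset (Venn) cells.

    ``site_sets[sp]`` is an iterable of hashable site keys.  ``attrs`` may
    provide per-species ``{key: {...}}`` metadata used to stratify cells by
    the names in ``strata`` (when species disagree on a stratum value for a
    shared key, the alphabetically first species wins).
    """
    species = tuple(sorted(site_sets))
    if len(species) < 2:
        raise InputError("shared/exclusive partitioning needs >= 2 species")
    sets = {sp: set(site_sets[sp]) for sp in species}
    union = set().union(*sets.values())
    cells: dict[frozenset, int] = {}
    membership: dict[object, frozenset] = {}
    for key in union:
        subset = frozenset(sp for sp in species if key in sets[sp])
        membership[key] = subset
        cells[subset] = cells.get(subset, 0) + 1

    stratified: dict[str, dict[object, dict[frozenset, int]]] = {}
    if strata and attrs is not None:
        for stratum in strata:
            per_value: dict[object, dict[frozenset, int]] = {}
            for key, subset in membership.items():
                value = None
                for sp in species:
                    if key in sets[sp] and key in attrs.get(sp, {}):
                        value = attrs[sp][key].get(stratum)
                        if value is not None:
                            break
                bucket = per_value.setdefault(value, {})
                bucket[subset] = bucket.get(subset, 0) + 1
            stratified[stratum] = per_value

    all_set = frozenset(species)
    return SharedSiteReport(
        species=species,
        cells=cells,
        stratified=stratified,
        union_size=len(union),
        shared_by_all=cells.get(all_set, 0),
    )


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

@dataclass
class DiversityResult:
    gene_id: str
    pi_dna: Optional[float]
    pi_rna: Optional[float]
    n_sequences: int
    analyzed_sites: int


def nucleotide_diversity(seqs: Sequence[str]) -> tuple[Optional[float], int]:
    """Per-site nucleotide diversity pi with complete deletion.

    pi = mean over unordered sequence pairs of (pairwise differences / L)
    where L counts columns that are A/C/G/T in *every* sequence.  Returns
    ``(None, 0)`` when no analyzable site remains.
    """
    n = len(seqs)
    if n < 2:
        raise InputError("nucleotide diversity needs >= 2 sequences")
    if len({len(s) for s in seqs}) != 1:
        raise InputError("aligned sequences must have equal length")
    mat = np.array([np.frombuffer(s.encode(), dtype="S1") for s in seqs])
    valid = np.isin(mat, [b"A", b"C", b"G", b"T"]).all(axis=0)
    L = int(valid.sum())
    if L == 0:
        return None, 0
    sub = mat[:, valid]
    total = 0.0
    for i, j in itertools.combinations(range(n), 2):
        total += (sub[i] != sub[j]).sum() / L
    return total / (n * (n - 1) / 2), L


def apply_edits_to_alignment(
    alignment: Mapping[str, str],
    edits_by_species: Mapping[str, Iterable[tuple[int, str]]],
) -> dict[str, str]:
    """Apply per-species consensus edits (ungapped position, alt base) to an
    alignment, preserving its gap structure."""
    out = {}
    for sp, aligned in alignment.items():
        cmap = column_map(aligned)
        seq = list(aligned)
        for off, alt in edits_by_species.get(sp, ()):
            if off >= len(cmap):
                raise InputError(f"{sp}: edit offset {off} beyond ungapped length")
            seq[int(cmap[off])] = alt
        out[sp] = "".join(seq)
    return out


def diversity_contrast(
    dna_alignments: Mapping[str, Mapping[str, str]],
    edits: Mapping[str, Mapping[str, Iterable[tuple[int, str]]]],
) -> tuple[list[DiversityResult], dict[str, float]]:
    """Per-gene pi of genomic DNA vs edited (mature) RNA alignments.

    ``dna_alignments[gene][species]`` are aligned sequences; ``edits[gene]``
    maps species to consensus edits in ungapped coordinates.  The RNA
    alignment of a gene is its DNA alignment with each species' edits applied
    in place, so gap structure and analyzed sites are directly comparable.
    Means across genes are unweighted (one point per gene).
    """
    results: list[DiversityResult] = []
    for gene_id in sorted(dna_alignments):
        aln = dna_alignments[gene_id]
        gene_edits = edits.get(gene_id, {})
        unknown = set(gene_edits) - set(aln)
        if unknown:
            raise InputError(f"{gene_id}: edits for species not in alignment: {sorted(unknown)}")
        rna_aln = apply_edits_to_alignment(aln, gene_edits)
        order = sorted(aln)
        pi_dna, L = nucleotide_diversity([aln[sp] for sp in order])
        pi_rna, _ = nucleotide_diversity([rna_aln[sp] for sp in order])
        results.append(DiversityResult(gene_id, pi_dna, pi_rna, len(order), L))
    dna_vals = [r.pi_dna for r in results if r.pi_dna is not None]
    rna_vals = [r.pi_rna for r in results if r.pi_rna is not None]
    means = {
        "mean_pi_dna": float(np.mean(dna_vals)) if dna_vals else float("nan"),
        "mean_pi_rna": float(np.mean(rna_vals)) if rna_vals else float("nan"),
    }
    return results, means


# ---------------------------------------------------------------------------
# GC% vs editing abundance
# ---------------------------------------------------------------------------

@dataclass
class CorrelationResult:
    n: int
    shapiro_p_gc: float
    shapiro_p_edits: float
    kendall_tau: Optional[float]
    kendall_p: Optional[float]
    pearson_r: Optional[float]
    pearson_p: Optional[float]
    regressions: dict[str, dict[str, float]]

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "shapiro_p_gc": self.shapiro_p_gc,
            "shapiro_p_edits": self.shapiro_p_edits,
            "kendall_tau": self.kendall_tau,
            "kendall_p": self.kendall_p,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "regressions": self.regressions,
        }


def gc_editing_correlation(
    table: pd.DataFrame,
    group_col: str = "group",
    gc_col: str = "gc",
    edits_col: str = "edits",
) -> CorrelationResult:
    """Association between GC fraction and editing abundance across taxa.

    Kendall's tau-b (tie-corrected) is always computed; Pearson's r is
    additionally reported only when both variables pass Shapiro-Wilk
    normality (p >= 0.05).  An ordinary least-squares regression of edit
    count on GC% is fitted within every group with >= 3 taxa (and overall),
    reporting slope, R^2 and p.
    """
    if len(table) < 3:
        raise InputError("correlation needs >= 3 taxa")
    gc = table[gc_col].to_numpy(dtype=float)
    edits = table[edits_col].to_numpy(dtype=float)
    sw_gc = float(stats.shapiro(gc).pvalue)
    sw_ed = float(stats.shapiro(edits).pvalue)
    if np.ptp(gc) == 0 or np.ptp(edits) == 0:
        tau = tau_p = None
    else:
        kt = stats.kendalltau(gc, edits)
        tau, tau_p = float(kt.statistic), float(kt.pvalue)
    pearson_r = pearson_p = None
    if sw_gc >= 0.05 and sw_ed >= 0.05 and np.ptp(gc) > 0 and np.ptp(edits) > 0:
        pr = stats.pearsonr(gc, edits)
        pearson_r, pearson_p = float(pr.statistic), float(pr.pvalue)

    regressions: dict[str, dict[str, float]] = {}

    def fit(name: str, x: np.ndarray, y: np.ndarray) -> None:
        if len(x) < 3 or np.ptp(x) == 0:
            return
        res = stats.linregress(x, y)
        regressions[name] = {
            "slope": float(res.slope),
            "intercept": float(res.intercept),
            "r_squared": float(res.rvalue**2),
            "p": float(res.pvalue),
            "n": int(len(x)),
        }

    fit("overall", gc, edits)
    if group_col in table.columns:
        for group, sub in table.groupby(group_col):
            fit(str(group), sub[gc_col].to_numpy(dtype=float), sub[edits_col].to_numpy(dtype=float))

    return CorrelationResult(
        n=len(table),
        shapiro_p_gc=sw_gc,
        shapiro_p_edits=sw_ed,
        kendall_tau=tau,
        kendall_p=tau_p,
        pearson_r=pearson_r,
        pearson_p=pearson_p,
        regressions=regressions,
    )
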