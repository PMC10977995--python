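"""Filter cascade: pileups, individual filters, end-to-end site calling.

The binomial and Fisher statistics are checked against independent exact
oracles: a Fraction tail sum and a factorial-formula hypergeometric
enumeration, plus scipy cross-checks on non-borderline tables.
"""
from __future__ import annotations

import math
from fractions import Fraction

import pytest
import scipy.stats

from editome import io as eio
from editome.caller import (
    CallResult,
    Pileup,
    PileupColumn,
    build_pileup,
    call_sites,
    consensus_rna,
    end_exclusion_filter,
    junction_artifact_check,
    mask_heteroplasmy,
    strand_bias_test,
    variant_significance,
)
from editome.config import CallerConfig, SimulationConfig
from editome.models import CU, UC, GeneModel, revcomp
from editome.pipeline import call_stage, simulate_stage


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def binom_upper_tail_exact(k: int, n: int, p: float) -> float:
    """Exact P(X >= k) as a Fraction sum over the tail."""
    pf = Fraction(p).limit_denominator(10**12)
    total = Fraction(0)
    for i in range(k, n + 1):
        total += math.comb(n, i) * pf**i * (1 - pf) ** (n - i)
    return float(total)


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by hypergeometric enumeration with factorials."""
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d

    def pmf(x: int) -> Fraction:
        return Fraction(
            math.factorial(r1) * math.factorial(r2) * math.factorial(c1) * math.factorial(n - c1),
            math.factorial(n)
            * math.factorial(x)
            * math.factorial(r1 - x)
            * math.factorial(c1 - x)
            * math.factorial(r2 - c1 + x),
        )

    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    obs = pmf(a)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        m = pmf(x)
        if m <= obs:
            total += m
    return float(total)


# ---------------------------------------------------------------------------
# pileup construction
# ---------------------------------------------------------------------------

def _sam(tmp_path, body, ln=1000):
    p = tmp_path / "reads.sam"
    p.write_text("@HD\tVN:1.6\tSO:coordinate\n@SQ\tSN:chr1\tLN:%d\n" % ln + body)
    return p


class TestBuildPileup:
    def test_identical_full_match_reads(self, tmp_path):
        ref = "A" * 100
        body = "".join(
            f"r{i}\t0\tchr1\t1\t60\t20M\t*\t0\t0\t{'A' * 20}\t*\n" for i in range(10)
        )
        pile = build_pileup(eio.read_alignments(_sam(tmp_path, body)), "chr1", ref)
        col = pile.column(5)
        assert col.depth == 10
        assert set(col.obs) == {"A"}

    def test_intron_skip_contributes_nothing(self, tmp_path):
        ref = "A" * 100
        body = f"r1\t0\tchr1\t1\t60\t10M30N10M\t*\t0\t0\t{'A' * 20}\t*\n"
        pile = build_pileup(eio.read_alignments(_sam(tmp_path, body)), "chr1", ref)
        assert pile.column(15) is None
        assert pile.column(9).depth == 1
        assert pile.column(40).depth == 1

    def test_strand_counts(self, tmp_path):
        ref = "A" * 100
        body = "".join(
            f"r{i}\t{16 if i >= 6 else 0}\tchr1\t1\t60\t20M\t*\t0\t0\t{'A' * 20}\t*\n"
            for i in range(10)
        )
        pile = build_pileup(eio.read_alignments(_sam(tmp_path, body)), "chr1", ref)
        entries = pile.column(3).obs["A"]
        fwd = sum(1 for rev, _ in entries if not rev)
        rev = sum(1 for rev_, _ in entries if rev_)
        assert (fwd, rev) == (6, 4)


class TestHeteroplasmyMask:
    def _pileup(self, ref_base, counts):
        pile = Pileup("chr1", ref_base * 10)
        col = PileupColumn(4, ref_base)
        for base, k in counts.items():
            for _ in range(k):
                col.add(base, False, 50, None)
        pile.columns[4] = col
        return pile

    def test_fraction_030_masked(self):
        pile = self._pileup("A", {"A": 14, "G": 6})  # 0.30 alternate
        assert 4 in mask_heteroplasmy(pile, CallerConfig())

    def test_fraction_020_not_masked(self):
        pile = self._pileup("A", {"A": 16, "G": 4})
        assert 4 not in mask_heteroplasmy(pile, CallerConfig())

    def test_masked_set_monotone_in_threshold(self):
        pile = self._pileup("A", {"A": 14, "G": 6})
        lo = mask_heteroplasmy(pile, CallerConfig(heteroplasmy_min_frequency=0.25))
        hi = mask_heteroplasmy(pile, CallerConfig(heteroplasmy_min_frequency=0.5))
        assert hi <= lo

    def test_ambiguous_reference_masked(self):
        pile = Pileup("chr1", "ACGNACGT")
        assert 3 in mask_heteroplasmy(pile, CallerConfig())


class TestEndExclusion:
    def _col(self, offsets):
        col = PileupColumn(0, "C")
        for base, off in offsets:
            col.add(base, False, off, None)
        return col

    def test_bases_near_ends_excluded(self):
        col = self._col([("T", 3), ("T", 10), ("C", 50)])
        adj = end_exclusion_filter(col, CallerConfig())
        assert adj["T"] == (1, 0)  # offset 3 dropped

    def test_boundary_offset_six_retained(self):
        col = self._col([("T", 6), ("T", 5)])
        adj = end_exclusion_filter(col, CallerConfig())
        assert adj["T"] == (1, 0)

    def test_all_end_proximal_leaves_no_depth(self):
        col = self._col([("T", 2), ("C", 1)])
        assert end_exclusion_filter(col, CallerConfig()) == {}


class TestVariantSignificance:
    def test_zero_alt_reads_gives_one(self):
        assert variant_significance(0, 100, 0.001) == 1.0

    @pytest.mark.parametrize(
        "k,n,passes",
        [(5, 100, True), (2, 1000, False)],
    )
    def test_against_exact_tail(self, k, n, passes):
        p = variant_significance(k, n, 0.001)
        exact = binom_upper_tail_exact(k, n, 0.001)
        assert p == pytest.approx(exact, rel=1e-9)
        assert (p <= 1e-6) is passes

    def test_enumeration_all_small_depths(self):
        # every (k, n) with n <= 60 matches the exact Fraction tail sum
        for n in range(1, 61):
            for k in range(0, n + 1):
                got = variant_significance(k, n, 0.001)
                exact = binom_upper_tail_exact(k, n, 0.001)
                assert got == pytest.approx(exact, rel=1e-9, abs=0), (k, n)

    def test_zero_depth_undefined(self):
        with pytest.raises(ValueError):
            variant_significance(0, 0, 0.001)


class TestStrandBias:
    def test_balanced_table_p_one(self):
        assert strand_bias_test(10, 10, 50, 50) == 1.0

    def test_extreme_bias_rejected(self):
        p = strand_bias_test(30, 0, 50, 50)
        assert p == pytest.approx(fisher_two_sided_exact(30, 0, 50, 50), rel=1e-9)
        assert p < 1e-5

    def test_enumeration_small_tables(self):
        # exhaustive over all tables with total <= 26
        for n in range(1, 27):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        got = strand_bias_test(a, b, c, d)
                        exact = fisher_two_sided_exact(a, b, c, d)
                        assert got == pytest.approx(exact, rel=1e-9, abs=0), (a, b, c, d)

    def test_random_tables_up_to_total_60(self):
        import numpy as np

        rng = np.random.default_rng(8)
        for _ in range(400):
            n = int(rng.integers(27, 61))
            cuts = sorted(rng.integers(0, n + 1, size=3))
            a, b, c = cuts[0], cuts[1] - cuts[0], cuts[2] - cuts[1]
            d = n - a - b - c
            got = strand_bias_test(a, b, c, d)
            exact = fisher_two_sided_exact(a, b, c, d)
            assert got == pytest.approx(exact, rel=1e-9, abs=0), (a, b, c, d)

    @pytest.mark.parametrize("table", [(3, 9, 40, 22), (1, 7, 11, 2), (12, 3, 5, 18)])
    def test_scipy_cross_check(self, table):
        a, b, c, d = table
        _, p = scipy.stats.fisher_exact([[a, b], [c, d]])
        assert strand_bias_test(a, b, c, d) == pytest.approx(p, rel=1e-7)


class TestJunctionCheck:
    def _gene_and_contig(self):
        import numpy as np

        rng = np.random.default_rng(17)
        codons = []  # redraw any accidental in-frame stop
        while len(codons) < 30:
            c = "".join(rng.choice(list("ACGT"), 3))
            if c not in ("TAA", "TAG", "TGA"):
                codons.append(c)
        cds = "ATG" + "".join(codons) + "TAA"  # 96 nt, non-repetitive
        exon1, exon2 = cds[:48], cds[48:]
        intron = "GT" + "G" * 40 + "AG"
        contig = "T" * 10 + exon1 + intron + exon2 + "T" * 10
        gene = GeneModel(
            "g1", "chr1", "+", ((10, 10 + 48), (10 + 48 + 44, 10 + 48 + 44 + 48))
        )
        assert gene.spliced_cds(contig) == cds
        return gene, contig, cds

    def test_mismapped_spliced_reads_rejected(self):
        gene, contig, cds = self._gene_and_contig()
        # reads that are exact transcript substrings spanning the junction:
        # an apparent mismatch near the boundary fully explained by splicing
        reads = [cds[30:70], cds[28:68]]
        keep = junction_artifact_check(reads, gene, contig, 56, CallerConfig(), 40)
        assert keep is False

    def test_truly_edited_reads_kept(self):
        gene, contig, cds = self._gene_and_contig()
        edited = cds[:50] + "T" + cds[51:]  # one base differs from transcript
        reads = [edited[30:70]]
        keep = junction_artifact_check(reads, gene, contig, 56, CallerConfig(), 40)
        assert keep is True

    def test_mid_exon_candidate_not_checked(self):
        gene, contig, cds = self._gene_and_contig()
        # candidate far from any boundary: kept without inspecting reads
        keep = junction_artifact_check(
            [cds[0:40]], gene, contig, 30, CallerConfig(junction_window=5), 40
        )
        assert keep is True


def _column_from_counts(pos, ref, alt, alt_n, ref_n, read_seq=None):
    col = PileupColumn(pos, ref)
    for i in range(alt_n):
        col.add(alt, i % 2 == 1, 50, read_seq)
    for i in range(ref_n):
        col.add(ref, i % 2 == 1, 50, None)
    return col


def _single_gene_pileup(contig, gene, columns):
    pile = Pileup(gene.seq_id, contig)
    pile.max_read_length = 100
    for col in columns:
        pile.columns[col.pos] = col
    return pile


class TestCallSites:
    CONTIG = "T" * 10 + "ATG" + "CCA" * 28 + "TAA" + "T" * 10
    GENE = GeneModel("g1", "chr1", "+", ((10, 100),))

    def _call(self, columns, mask=frozenset(), config=None):
        pile = _single_gene_pileup(self.CONTIG, self.GENE, columns)
        return call_sites(pile, set(mask), self.CONTIG, [self.GENE], config or CallerConfig())

    def test_two_percent_rejected(self):
        res = self._call([_column_from_counts(50, "C", "T", 2, 98)])
        assert res.sites == []
        assert res.stats["min_alt_reads"] == 1

    def test_five_percent_accepted(self):
        res = self._call([_column_from_counts(50, "C", "T", 5, 95)])
        assert len(res.sites) == 1
        site = res.sites[0]
        assert site.type == CU and site.frequency == pytest.approx(0.05)

    def test_exact_threshold_ties_pass(self):
        # 46 / 1000 = 4.6% exactly, and exactly 3 alt reads at depth 65
        res = self._call([_column_from_counts(50, "C", "T", 46, 954)])
        assert len(res.sites) == 1
        res = self._call(
            [_column_from_counts(50, "C", "T", 3, 62)],
            config=CallerConfig(max_variant_p=1.0),
        )
        assert len(res.sites) == 1

    def test_masked_position_rejected(self):
        res = self._call([_column_from_counts(50, "C", "T", 5, 95)], mask={50})
        assert res.sites == [] and res.stats["masked"] == 1

    def test_minus_strand_type_convention(self):
        # genomic G with RNA A on a minus-strand gene => coding C-to-U
        contig = revcomp(self.CONTIG)
        n = len(contig)
        gene = GeneModel("g1", "chr1", "-", ((n - 100, n - 10),))
        pos = n - 1 - 50  # mirror of position 50 (a coding-strand C)
        assert contig[pos] == "G"
        pile = _single_gene_pileup(contig, gene, [_column_from_counts(pos, "G", "A", 10, 90)])
        res = call_sites(pile, set(), contig, [gene], CallerConfig())
        assert len(res.sites) == 1
        assert res.sites[0].type == CU
        assert (res.sites[0].ref, res.sites[0].alt) == ("C", "T")

    def test_suspect_ag_reported_separately(self):
        pos = 11  # coding A at CDS offset 1 (ATG)
        assert self.CONTIG[pos] == "T"
        pos = 13  # first C of CCA
        assert self.CONTIG[pos] == "C"
        # use a genomic A: offset 12+2=15 is A of CCA
        pos = 15
        assert self.CONTIG[pos] == "A"
        res = self._call([_column_from_counts(pos, "A", "G", 10, 90)])
        assert res.sites == []
        assert len(res.suspects) == 1
        assert res.suspects[0].type == "A-to-G"

    def test_monotonicity_in_thresholds(self, small_study):
        base = CallerConfig()
        stricter_freq = CallerConfig(min_variant_frequency=0.3)
        stricter_count = CallerConfig(min_alt_reads=20)
        results = {}
        for name, cfg in [("base", base), ("freq", stricter_freq), ("count", stricter_count)]:
            out = call_stage(
                small_study["genomes"], small_study["genes"],
                small_study["paths"]["dna"], small_study["paths"]["rna"], cfg,
                annotate=False,
            )
            results[name] = len(out.sites)
        assert results["freq"] <= results["base"]
        assert results["count"] <= results["base"]

    def test_fate_conservation(self, small_call):
        s = small_call.stats
        from editome.caller import FILTER_ORDER

        assert s["accepted"] + sum(s[k] for k in FILTER_ORDER) == s["candidates"]

    def test_multiallelic_highest_frequency_wins(self):
        col = PileupColumn(50, "C")
        for i in range(10):
            col.add("T", i % 2 == 1, 50, None)
        for i in range(6):
            col.add("G", i % 2 == 1, 50, None)
        for i in range(84):
            col.add("C", i % 2 == 1, 50, None)
        res = self._call([col], config=CallerConfig(max_variant_p=1.0))
        accepted = res.sites + res.suspects
        assert len(accepted) == 1
        assert accepted[0].alt == "T"
        assert res.stats["multiallelic"] == 1


class TestConsensus:
    CONTIG = TestCallSites.CONTIG
    GENE = TestCallSites.GENE

    def _site(self, pos, freq):
        from editome.models import EditingSite

        return EditingSite(
            gene_id="g1", seq_id="chr1", pos0=pos, ref="C", alt="T", type=CU,
            depth=100, alt_reads=int(freq * 100), frequency=freq,
        )

    def test_high_frequency_site_applied(self):
        cds = self.GENE.spliced_cds(self.CONTIG)
        out = consensus_rna(self.GENE, self.CONTIG, [self._site(13, 0.95)], CallerConfig())
        off = self.GENE.cds_offset(13)
        assert out[off] == "T"
        assert out[:off] == cds[:off] and out[off + 1 :] == cds[off + 1 :]

    def test_low_frequency_site_not_applied(self):
        cds = self.GENE.spliced_cds(self.CONTIG)
        out = consensus_rna(self.GENE, self.CONTIG, [self._site(13, 0.30)], CallerConfig())
        assert out == cds

    def test_no_sites_identity(self):
        cds = self.GENE.spliced_cds(self.CONTIG)
        assert consensus_rna(self.GENE, self.CONTIG, [], CallerConfig()) == cds


class TestRecallIdempotence:
    def test_recall_on_edited_reference_yields_zero_sites(self, tmp_path):
        """Simulate RNA from the consensus (fractions 1.0), call against the
        edited reference: no DNA:RNA mismatch should survive."""
        cfg = SimulationConfig(
            n_genes=3, cds_length_range=(100, 160), n_cu_edits=25, n_uc_edits=5,
            editing_fraction_range=(1.0, 1.0), n_heteroplasmic_sites=0,
            n_artifact_sites=0, seed=21,
        )
        paths = simulate_stage(cfg, tmp_path / "round1")
        genomes, genes = eio.read_gene_models(paths["genes"], paths["reference"])
        out1 = call_stage(genomes, genes, paths["dna"], paths["rna"], CallerConfig(),
                          annotate=False)
        assert out1.sites, "first pass should find the planted sites"

        # build an edited genome: apply each gene's consensus back onto the contig
        edited = dict(genomes)
        for g in genes:
            cons = consensus_rna(g, genomes[g.seq_id], out1.sites, CallerConfig())
            seq = list(edited[g.seq_id])
            for off, base in enumerate(cons):
                pos = g.genomic_pos(off)
                seq[pos] = base if g.strand == "+" else revcomp(base)
            edited[g.seq_id] = "".join(seq)

        # resimulate reads from the edited genome with no editing planted
        cfg2 = SimulationConfig(
            n_genes=3, cds_length_range=(100, 160), n_cu_edits=0, n_uc_edits=0,
            n_heteroplasmic_sites=0, n_artifact_sites=0, seed=22,
        )
        from editome.models import TruthEditome
        from editome.synthetic import simulate_reads

        dna, rna = simulate_reads(genes, edited, TruthEditome(), cfg2)
        d2 = tmp_path / "round2"
        d2.mkdir()
        eio.write_sam(dna, edited, d2 / "dna.sam")
        eio.write_sam(rna, edited, d2 / "rna.sam")
        out2 = call_stage(edited, genes, d2 / "dna.sam", d2 / "rna.sam", CallerConfig(),
                          annotate=False)
        assert out2.sites == []
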