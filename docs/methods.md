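# Methods

## The problem

In land-plant organelles, post-transcriptional RNA editing rewrites cytidines
to uridines (canonical, C-to-U) and — especially in lycophytes — uridines back
to cytidines (reverse, U-to-C) at thousands of positions in protein-coding
transcripts. An editome is detected as the set of DNA:RNA mismatches that
survive a cascade of artifact filters when genomic and transcriptomic reads
from the same organism are compared against the same reference. This package
implements that detection cascade, the downstream codon-consequence and
hydrophobicity accounting, cross-species shared/exclusive partitioning, and
the contrast of nucleotide diversity between genomic DNA and the edited
(mature) RNA — together with a synthetic-data generator that plants a known
editome so every stage can be validated against ground truth.

## The filter cascade

A reference position with at least one non-reference RNA base becomes a
candidate; a candidate becomes an editing site iff it survives every rule.
Rules are applied in a fixed order so that each rejected candidate is
attributed to exactly one rule (first failure wins), which makes the run
manifest's per-rule counts reproducible:

1. **Heteroplasmy mask.** Positions where the DNA pileup shows a
   non-reference fraction ≥ 0.25 are genomically ambiguous (heteroplasmy or
   reference error) and masked. Reference ambiguity codes are masked
   unconditionally.
2. **Read-end exclusion.** Bases whose 0-based distance to the nearer end of
   their read is < 6 nt are removed from both the alternate and the depth
   tallies before any frequency is computed. "Within 6 bp of the ends" is
   read inclusively: the first and last six bases are dropped, the seventh
   (offset 6) is kept. Applying the count/frequency thresholds to the
   adjusted tallies is the more conservative of the two possible orders.
3. **Support count.** ≥ 3 alternate reads (inclusive: exactly 3 passes).
4. **Variant frequency.** ≥ 4.6 % of the adjusted depth (inclusive: exactly
   4.6 % passes). This deliberately permissive threshold trades false
   positives for a low false-negative rate; downstream consumers can
   re-filter the table.
5. **Variant significance.** The probability that sequencing error alone
   produces at least the observed support, P(X ≥ k | n, e) under a binomial
   with a flat assumed error rate e (default 10⁻³, ≈ Q30), must be ≤ 10⁻⁶.
   The error model behind the original tool's "maximum variant p-value" is
   not documented, so a flat-rate binomial upper tail is used and the rate is
   configurable.
6. **Strand bias.** A two-sided Fisher exact test on the 2×2 table
   (alt forward, alt reverse) × (other forward, other reverse); candidates
   with p < 10⁻⁵ are artifacts. The p-value is computed by exact integer
   enumeration: hypergeometric point masses share the denominator C(n, c₁),
   so tables are ranked by their integer numerators C(r₁, x)·C(r₂, c₁−x) and
   ties are exact — no floating-point epsilon decides which tables enter the
   two-sided sum.
7. **Junction mismapping check.** A candidate within one read length of an
   internal exon boundary may be an unspliced-mapping artifact: reads from
   the spliced transcript forced onto the genomic sequence produce apparent
   mismatches near the junction. The spliced transcript is reconstructed and
   every alternate-supporting read aligned to it (infix mode, both
   orientations, via edlib); if all of them match at edit distance 0 the
   mismatch is fully explained by splicing and the candidate is rejected. A
   genuinely edited read necessarily differs from the unedited transcript at
   ≥ 1 position, so true sites near junctions are retained. The check is
   vulnerable to highly repetitive transcripts (a shifted exact match can
   absorb a real edit); organellar coding sequence is not repetitive at read
   scale.

Multi-allelic columns are evaluated per alternate base; at most one allele is
accepted per position (highest adjusted frequency; an exact tie rejects both,
logged). Only positions inside annotated CDS exons are called by default;
`call_introns` extends calling across the gene span for diagnostics.

Edit type is assigned on the coding strand: genomic C with RNA T is C-to-U,
T→C is U-to-C (for minus-strand genes the observed bases are complemented
first). A:G and G:A mismatches — the classic signature of residual
sequencing/mapping artifacts in plant organelles, where deamination-type
editing cannot produce them — are typed "suspect", reported in a separate
table and never counted in editome totals.

**Consensus (mature) RNA.** The edited coding sequence applies every accepted
site with frequency ≥ 60 % to the spliced CDS; sites between 4.6 % and 60 %
stay in the table but do not change the consensus. Whether partially edited
sites should enter the mature sequence is genuinely open; the two-threshold
design keeps both answers available.

## Codon consequences

Sites are mapped through spliced, strand-aware coordinates to CDS offsets;
codon position is (offset mod 3) + 1, and codons split by introns are handled
by concatenation. All accepted edits within one codon are applied jointly
(one codon, one verdict) and both codons translated under the standard
genetic code (table 1, the code used by land-plant organelles; the table id
is configurable). Effect labels, in precedence order: start-creation (codon
index 0, non-ATG → ATG), stop-creation (non-stop → stop, anywhere; an
`is_terminal` flag distinguishes premature from terminal), stop-removal
(stop → non-stop), then silent/non-silent by amino-acid identity. For the
summary roll-up a codon is silent iff its translated meaning is unchanged, so
*silent + non-silent = affected codons* holds exactly; the special categories
are counted in their own rows in addition. Each site also carries the
provisional effect of that edit alone, for transparency when codons carry
multiple edits.

## Hydrophobicity conversions

Residues are classified on the Kyte–Doolittle hydropathy index with
cut-points ≥ 2.5 (very hydrophobic), (0, 2.5) (hydrophobic), [−1.5, 0]
(neutral), < −1.5 (hydrophilic). The published index underlying the original
analysis (a pH 7 hydrophobicity scale) is not recoverable in detail, so the
scale is pluggable via TSV and the default is documented as Kyte–Doolittle
rather than asserted as identical. Stops are unclassified and excluded from
the matrix; the accounting identity *matrix total + unclassifiable + silent =
affected codons* is enforced. The "toward-hydrophobic fraction" is the share
of classifiable conversions that strictly increase the category rank — on
C-to-U dominated editomes with the organellar codon-position spectrum it
exceeds 0.5 because C→U edits preferentially create hydrophobic codons
(S→L, P→L, S→F, ...).

## Cross-species comparison

Sites are compared on externally produced per-gene alignments (the package
consumes aligned FASTA; it does not align). Two sites are the same iff they
share gene, alignment column and edit type; type-matched identity is the
default because the type stratification is biologically meaningful, and can
be relaxed. Venn cells over species subsets are exact set algebra; the
shared-by-all proportion uses the union of all species' sites as denominator
(the natural reading when per-species totals differ).

Nucleotide diversity per site is

π = Σ_{i<j} d_ij / C(n, 2),  d_ij = (pairwise differences at analyzed
sites) / L,

with complete deletion: L counts only columns that are A/C/G/T in every
sequence (gap or ambiguity anywhere removes the column), matching the
default of the classic population-genetics tools. The mature-RNA alignment
of a gene is its DNA alignment with each species' consensus edits applied in
place, preserving gap structure, so π_DNA and π_RNA are computed over the
same columns: edits shared by all species at the same column add no pairwise
differences (π unchanged) while species-exclusive edits can only add them
(π_RNA ≥ π_DNA). Means across genes are unweighted (one gene, one point).

GC%-vs-editing association: Kendall's tau-b (tie-corrected) is always
computed across taxa; Pearson's r is added only when both variables pass
Shapiro–Wilk at p ≥ 0.05 (the nonparametric statistic is the primary one
because editing counts across distant taxa are not credibly normal); OLS of
edit count on GC fraction is fitted within each group of ≥ 3 taxa and
overall, reporting slope, R² and p.

## The synthetic-data generator

The generator is first-class, tested code; its defaults are the package's
study conditions at desk scale:

| parameter | default | rationale |
|---|---|---|
| n_genes | 20 | of the order of an organellar protein-coding gene set |
| cds_length_range | 120–400 codons | small organellar genes |
| gc_target | 0.38 | lycophyte-like organellar coding GC (~37–38 %) |
| intron_probability / length | 0.5, 80–300 nt | intron-containing genes with splice junctions to exercise |
| n_cu_edits / n_uc_edits | 250 / 50 | C-to-U dominated editome, ~5:1 |
| codon_position_weights | (0.34, 0.48, 0.18) | 2nd > 1st > 3rd spectrum of organellar editomes |
| editing_fraction_range | 0.2–1.0 | partial editing down to the hard-to-call regime |
| heteroplasmy | 10 sites, fraction 0.25–0.45 | genomic ambiguity the mask must remove |
| artifacts | 10 A:G/G:A sites at 1–4 % | below the 4.6 % threshold, as residual noise |
| depth / read_length / error_rate | 50× / 100 nt / 10⁻³ | Illumina-like desk-scale coverage |

CDSs are built codon-wise (ATG start, no internal in-frame stop, one terminal
stop) from GC-weighted base draws; each gene sits on its own contig with
120 nt flanks, on a random strand, optionally split by one or two introns at
arbitrary CDS offsets (so codons can span junctions). Edits, artifacts and
heteroplasmic sites occupy disjoint positions unless `allow_overlap` is set;
the start codon is never edited. Reads are emitted already aligned: DNA reads
as full matches on the contig, RNA reads from the spliced transcript plus
read-length UTR padding on both sides (organellar transcripts extend beyond
the CDS; the padding keeps usable coverage uniform across the whole coding
region), with intron skips encoded as N CIGAR operations and minus-strand
genes emitted genome-forward. Every truth site carries its edited base per
read with its planted fraction; independent per-base errors are applied at
`error_rate`. One RNG family is seeded from `seed`; stages use sub-streams
at fixed offsets (0 reference, 1 editome, 2 reads, 3/4 clade helpers), and
identical config + seed reproduce byte-identical FASTA/GFF3/SAM/TSV.

Two helpers support the comparative analyses: per-branch editome planting on
a nested-tuple species tree (sites on a branch are shared by exactly its
descendant leaves; per-branch counts configurable so an ancestral-majority
editome can be planted) and substitution-only divergence of each CDS down the
same tree, yielding gapless per-gene alignments.

What the generator does **not** emulate: quality-score ramps and
position-dependent error profiles, indels, PCR duplicates, paired-end insert
geometry, mapping uncertainty (reads are emitted at their true coordinates),
expression-level variation between genes, and genuinely mismapped spliced
reads. Passing the planted-recovery tests therefore demonstrates the
correctness of the cascade's logic and statistics under idealized alignment,
not robustness to real-world mapping artifacts — which is precisely why the
filters it validates are the conservative published ones.

## Numerical and design choices

- Binomial tail via `scipy.stats.binom.sf`; Fisher two-sided p by exact
  integer enumeration (see above); both are checked against independent
  exact-arithmetic oracles to 10⁻⁹ relative in the test suite.
- π is computed in numpy over byte matrices; the brute-force pairwise oracle
  agrees to 10⁻¹².
- Thresholds at exactly 4.6 % / 3 reads / 0.25 / 60 % pass (all thresholds
  inclusive on the "minimum" side).
- Degenerate inputs: zero usable depth after end-exclusion rejects the
  candidate ("no usable depth"); π of an all-gap alignment is reported
  missing rather than 0; a constant variable makes tau undefined and it is
  reported as missing.
- Coordinates are 0-based half-open internally, 1-based inclusive in GFF3
  and the public edit table; the converters are inverse bijections.
- Desk-scale problem sizes (20 genes, 50× depth, 300 planted sites; clade
  analyses on 10 genes × 4 species) keep a full study under half a minute
  while leaving every per-site statistic in its realistic regime.

## Known limitations

- The strand-bias and variant-significance models are standard stand-ins for
  an undocumented commercial implementation; absolute p-values need not
  match it, only the logic of the thresholds.
- The junction check requires alternate-read sequences in the pileup; when a
  pileup is built without them the check passes candidates with a logged
  warning.
- Consensus application is frequency-only; the original 60 % rule also
  weighs base qualities, which the simulator does not model.
- Shared-site identity assumes per-gene alignments are correct; alignment
  error masquerades as species-exclusive editing.
- The GC-correlation module reports association only; it makes no causal or
  phylogenetically corrected claim (no independent-contrasts correction).
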