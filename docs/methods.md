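# Methods

This note documents the models and procedures implemented in `lncreg`,
the parameters that matter, the synthetic data used to validate them,
and the design decisions taken where the published descriptions of these
methods leave room.

## Pipeline model

The analysis treats lncRNA discovery as a filter-and-prioritize problem:
novel transcripts are first classified by genomic position, reduced to a
high-confidence lncRNA catalogue by sequence-level filters, and then
prioritized by two complementary statistical signals — differential
expression between phenotype groups, and differential co-expression with
a panel of phenotype-relevant mRNA (RIF). Networks, QTL overlap, miRNA
interactions and set enrichment annotate the prioritized candidates.
Every stage is a pure function of its inputs and a seed.

## Positional classification

Class codes follow the cuffcompare vocabulary. Against a single
reference transcript the checks are, in order: identical intron chain
(`=`; single-exon pairs must match exactly, tolerance 0), containment
with matching internal junctions (`c`), a shared splice junction (`j`),
same-strand exonic overlap without a shared junction (`o`), containment
within a single reference intron (`i`, strand-agnostic), opposite-strand
exonic overlap (`x`), and an intron overlapping a reference intron on
the opposite strand without exonic overlap (`s`). Against a full
reference the most specific code wins with precedence
`= > c > j > o > i > x > s > u`; ties between references at equal
precedence go to the lexicographically smallest reference ID, making the
result independent of reference order. Unstranded novel transcripts are
treated as matching either strand for the strand-requiring positive
codes and are never assigned `x`/`s`. Transcripts on sequences absent
from the reference are `u` (logged).

## ORF definition

An ORF is a complete ATG→stop span; its length counts the start codon
and excludes the stop, and both strands and all six frames are scanned
(a config switch restricts to the forward strand). `N` never matches a
start or stop. The 300 nt threshold is an exclusion bound: ORFs of
exactly 300 nt pass. For coding features, if no complete ORF exists the
longest open ATG→end run is used with integrity −1.

## Homology screens and significance

Local alignment uses Smith–Waterman throughout (Biopython's
`PairwiseAligner`): translated six-frame queries vs peptides with
BLOSUM62 and affine gap cost 11 + L (protein), and match +2 / mismatch
−3 with gap cost 5 + 2L (nucleotide, both strands; `N` scores as a
mismatch everywhere). Significance is Karlin–Altschul,
E = K·m·n·e^(−λS), with λ solved by root-finding from
Σᵢⱼ pᵢpⱼ e^(λsᵢⱼ) = 1 under database residue frequencies (uniform for
nucleotides) and K fixed at 0.13. This is an ungapped-style calibration
applied to gapped scores: E-values are deterministic and monotone in
score, which is what the 10⁻⁶ thresholds require, but they are not
BLAST's numbers. Perfect matches of the sizes planted by the generator
sit many orders of magnitude below the threshold, and random sequences
sit above it, so the thresholding behaviour is insensitive to K.

## Coding-potential call

Features are the CPC2 set — Fickett TESTCODE over the whole transcript
(published position/composition lookup tables; non-ACGT letters are
ignored), best-ORF length, coverage and integrity, and the isoelectric
point of the best-ORF peptide (Henderson–Hasselbalch net charge, root
found by bisection; an empty peptide is defined as pI 7.0, integrity
−1). The classifier is a logistic model on standardized features, fit
once on synthetic labelled data (mRNA-like sequences with a clean
100–400 codon ORF vs their per-sequence shuffles) and shipped as the
versioned constant `data/coding_model.json` (`fit_coding_model`
regenerates it). The decision threshold is 0.5. This filter is a
backstop after the ORF and homology screens — in the motivating study it
removed 7 of 8716 candidates — so fidelity of the features matters more
than the exact boundary, and the model file keeps the call reproducible.

## miRNA interactions

Sponge sites are found miRanda-style. Stage one aligns the miRNA
(5'→3') against the lncRNA read 3'→5' by affine-gap Smith–Waterman over
complementarity: Watson–Crick pairs +5, G:U wobbles +1, mismatches −3,
gap open/extend −9/−4, with substitution scores at miRNA positions 2–8
(the seed) scaled ×4. The published description of this screen names
only the two thresholds, so these parameter values are pinned defaults
(`NtScoring`), all configurable. Candidate sites must score > 160;
overlapping candidates are resolved greedily by score, ties to the
leftmost coordinate, by masking each claimed span and rescanning. Stage
two evaluates a two-state nearest-neighbor duplex free energy on the
alignment: Turner-2004 stack terms for consecutive pairs
(`data/turner_stacks.json`), +4.10 kcal/mol duplex initiation, and a
flat +4.0 kcal/mol penalty per helix interruption; no terminal-AU terms,
no intramolecular structure, no multiloops. Reported sites satisfy both
score > 160 and ΔG < −20 kcal/mol. The model preserves the thresholding
behaviour of a full folding library without reproducing its numerics: a
perfect ~22-mer duplex lands near −40 kcal/mol, isolated pairs near +4.
Precursor candidacy is nucleotide homology (E < 10⁻⁶) to the hairpin
database, either strand.

## Expression, normalization, differential expression

TMM follows the edgeR formulation: the reference sample has the
upper-quartile CPM closest to the mean; M and A are computed over
transcripts nonzero in both sample and reference; the M tails are
trimmed 30% and the A tails 5% (rank rule `floor(0.3n)+1`); the factor
is 2 to the precision-weighted mean M with inverse asymptotic binomial
variances as weights; factors are rescaled to geometric mean 1. The
implementation agrees with edgeR's `calcNormFactors` to ~4 × 10⁻¹⁵ on
random NB matrices and with an independently coded direct-formula oracle
to < 10⁻⁸ in the test suite. Degenerate cases: a sample sharing no
expressed transcript with the reference gets factor 1 with a warning.

The expression filter keeps a transcript in a tissue iff CPM ≥ 1 in at
least ⌈n/2⌉ of that tissue's samples. Differential expression is a
per-transcript Welch t-test on log₂(CPM + 0.5) between the high- and
low-FE groups within a tissue, thresholded at raw p < 0.01 with no
multiplicity correction — the contrast is defined by a metadata column,
so a one-tissue-vs-rest contrast is a relabeling away. Zero variance in
both groups yields p = 1 when means agree and p = 0 otherwise. Under the
simulated null the rejection rate is calibrated (tested at 2000
transcripts within 3 binomial SD of 1%).

## Regulatory Impact Factors

With e1ⱼ, e2ⱼ the mean log-expression of target j per condition,
PIFⱼ = ((e1ⱼ+e2ⱼ)/2)(e1ⱼ−e2ⱼ), and r1ᵢⱼ, r2ᵢⱼ the within-condition
Pearson correlations:

    RIF1ᵢ = (1/n) Σⱼ PIFⱼ (r1ᵢⱼ − r2ᵢⱼ)²
    RIF2ᵢ = (1/n) Σⱼ [(e1ⱼ r1ᵢⱼ)² − (e2ⱼ r2ᵢⱼ)²]

Both are z-standardized across the regulator set; a regulator is *key*
when |z| ≥ 2.57 on **either** metric (union rule; a `both` option
exists). A zero-variance regulator contributes zero correlations
(logged); fewer than 3 samples per condition is a hard error. RIF2
flips sign when the conditions are swapped, and both metrics are
invariant to target order.

Identifiability matters here: a sample correlation at n = 9 per group
has an SD of ≈ 0.33 under independence, so no statistic can reliably
place one truly rewired regulator above 100 independent decoys in a
single draw at that n. The test suite therefore demonstrates two
different things: at the study's own 9 + 9 design, planted regulators
exceed decoys in mean |z| (rank separation); the top-rank recovery
property (planted regulator first by |RIF1 z| among 100 decoys in ≥ 95%
of 20 seeds) is established at 30 samples per condition, where the
planted wiring (r = 0.9 vs 0.0) dominates correlation noise.

## PCIT networks

For every trio (x,y,z) the three first-order partial correlations are
computed; the local tolerance is ε = ⅓(r̂xy.z/rxy + r̂xz.y/rxz +
r̂yz.x/ryz), and the edge (x,y) is flagged when, for some z, |rxy| ≤
|ε·rxz| and |rxy| ≤ |ε·ryz|. Surviving edges were never flagged and
have nonzero correlation. Trios with a zero direct correlation or a
unit correlation in a denominator are skipped. The enumeration is exact
O(n³), vectorized over the conditioning index, and equals an
independently coded brute-force triple loop on random instances
(n ≤ 15, 100 instances). Edge weights are the raw Pearson correlations
computed across all samples of the tissue.

Two behaviours of the tolerance rule are worth knowing. First, it is
conservative for strong indirect associations: for a latent chain with
link correlation a, the indirect edge is only removable when
a ≲ 0.55, so the chain-elimination property is demonstrated at a = 0.35
with 200 samples (where correlation estimates are tight; at n = 50 the
single decisive trio is dominated by sampling noise). Second, on pure
independent noise the rule retains a minority (~15–20%) of weak spurious
edges rather than none; the planted-module test (all 10 within-module
edges survive) provides the contrast.

## Annotation and enrichment

QTL overlap is strand-agnostic, any-shared-base, on half-open
coordinates, backed by an interval tree and verified against all-pairs
brute force. Catalogue homology reuses the nucleotide aligner
(E < 10⁻⁶), best hit per (lncRNA, entry) pair, many-to-one allowed.
Gene-set enrichment is the upper-tail hypergeometric with BH correction
(enriched at FDR < 0.1); miRNA sets use the one-sided Fisher's exact
test (the two agree exactly on identical 2×2 tables, and both equal
explicit tail enumeration). The universe is the caller's choice; the
pipeline uses all expressed mRNA of the tissue's network — the
published analyses ran behind web services whose backgrounds are not
recoverable, so the universe is explicit here.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *structure* of the study: five tissues, two
groups of 9 samples, a reference annotation of multi-exon genes, novel
transcripts planted to satisfy each class code's geometry exactly (one
construction per code, verified unambiguous by round trip), sequences
with exactly controlled maximal ORFs (built from ATG/CAT-free background
so no start codon exists on either strand except the planted one),
negative-binomial counts (mean m, variance m + φm², φ = 0.08 by
default) with a multiplicative 2² group effect on planted DE
transcripts, and regulator wiring via a shared latent Gaussian factor on
the log₂-mean scale whose loading differs by group (√r_high vs √r_low).

Three generator choices ensure planted mechanisms actually manifest in
the emitted counts rather than drowning in counting noise: wired rows
(regulators and their targets) sit in the well-expressed range
(log₂ mean 6.5–9), the shared program has amplitude 1.2 on the log₂
scale against 0.7 for background biological noise, and target mRNA carry
a mild +0.8 log₂ group shift — the RIF target panel emulates
phenotype-relevant mRNA, which differ between groups by construction of
such panels. With these, the realized within-group regulator–target
correlation on normalized log counts is ≈ 0.8 when r_high = 0.9.

Precursor hairpins carry a three-point-diverged copy of their mature
sequence so that a planted perfect sponge site (the exact antisense of a
mature miRNA) cannot reach precursor-homology significance on its own;
sponge and precursor ground truth stay separable. QTL ground truth
records every transcript a padded interval actually covers, not just its
anchor. DE and regulator roles are planted only on transcripts that can
survive the cascade (multi-exon novel classes), so downstream recovery
is well-defined.

Not emulated: reads, alignment and assembly artifacts, polyA selection,
GC or length biases, isoform-sharing of exons between novel transcripts,
real tissue biology (tissue specificity is planted as on/off
expression), and realistic genome-scale transcript counts. Passing
tests therefore validate the algorithms and their wiring, not
performance on real libraries.

## Problem sizes and runtime

Defaults are sized for complete desk-scale runs: 30 reference genes, 60
novel transcripts, 120 mRNA, five tissues of 9 + 9 samples. The full
test suite runs in well under a minute; the acceptance script (1000
ORF-oracle sequences, 100 PCIT instances, 20 RIF recovery seeds, a 2000-
transcript null, and a double end-to-end run) takes ~15 s on one CPU.
The PCIT implementation is dense O(n³) and comfortable to ~2000 nodes.

## Known limitations

- E-values are internally consistent, not BLAST-calibrated; absolute
  values near the 10⁻⁶ threshold should not be compared across tools.
- The duplex energy model has no intramolecular folding; energies for
  sites with long internal loops are cruder than folding-library values.
- The coding model is trained on synthetic positives/negatives; on real
  transcriptomes a model fit to curated coding/noncoding sets would be
  preferred (the feature extraction is shared either way).
- The ±2.57 SD key-lncRNA rule inherits RIF's low power at n = 9:
  per-tissue key lists are prioritizations, not discoveries — the same
  caveat the raw-p DE rule carries by design.
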