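# Methods

`circena` is a desk-scale implementation of a circRNA discovery and
ceRNA-network workflow for multi-group bulk RNA-seq designs, together with a
synthetic-data generator that produces every input with known ground truth.
This note records the models, the defaults and why they were chosen, what the
simulations do and do not emulate, and the numerical choices that matter.

## Back-splice junction detection

circRNAs arise by back-splicing: a downstream splice donor joins an upstream
acceptor, producing a covalently closed circle. A sequencing read spanning the
back-splice junction is diagnostic — it cannot align contiguously to the
genome, and its two ends align in reversed ("head-to-tail") orientation.

The detector proceeds in stages:

1. **Quality filter.** Reads containing the adapter, more than 10% unknown
   (N) bases, or more than 50% low-quality bases (Phred Q ≤ 20) are
   discarded. Each discarded read is counted once, under the first failed
   rule.
2. **Linear-mapping filter.** Reads that align contiguously end-to-end
   (either strand, ≤ 2 mismatches by default) are removed. The aligner is an
   exact-match seed-and-verify surrogate: the terminal k-mers seed candidate
   offsets, and the full read is verified by direct comparison. It does not
   do indel-tolerant or spliced alignment; at the simulated scale the reads
   that survive this filter are splice- or back-splice-spanning reads, which
   is the population the junction caller needs.
3. **Anchor pairing.** The first and last 20-mers of each unmapped read are
   looked up in an exact k-mer index of both genome strands. Each anchor must
   occur exactly once genome-wide, and both on the same chromosome and
   strand; ambiguous anchors abort the read. Anchors on different
   chromosomes or strands are rejected — a single-chromosome, same-strand
   geometry is the only one consistent with back-splicing.
4. **Junction calling.** Head-to-tail orientation is required (on the plus
   strand the head anchor must sit downstream of the tail anchor; a
   minus-strand read is reverse-complemented, which swaps the anchors'
   roles). The read is then split at every admissible offset into a
   donor-side suffix and acceptor-side prefix of the circle; the split
   minimising total mismatches wins, with ties broken first in favour of
   canonical splice flanks, then by leftmost start. A call is accepted only
   if mismatches ≤ 2 and the flanks are canonical: GT immediately 3′ of the
   donor breakpoint and AG immediately 5′ of the acceptor breakpoint, read
   on the transcript strand (on the genome plus strand this means AC/CT for
   minus-strand circles).
5. **Support filter.** Candidates are grouped by breakpoint pair
   (chromosome, start, end, strand). Supporting reads are deduplicated by
   sequence — byte-identical copies (PCR duplicates) count once — and a
   junction is kept only with ≥ 2 unique reads in at least one sample.
6. **Classification.** A junction is *exonic* if both breakpoints lie in
   exons of one same-strand gene (its spliced length is the exonic overlap),
   *intronic* if the whole span sits inside a single intron of a same-strand
   gene, *antisense* if it overlaps genes only on the opposite strand (that
   gene is recorded), and *intergenic* otherwise (no source gene).

Coordinates are 0-based half-open internally and in BED output; GTF I/O
converts to/from 1-based inclusive at the boundary and nowhere else.
Catalog ids (`circ_000001`…) are assigned in coordinate order, so output is
deterministic for identical input.

**Parameters.** `k` (anchor length, default 20 bases): shorter anchors lose
genome-wide uniqueness, longer ones reduce sensitivity near read ends.
`max_mismatches` (default 2, both for linear mapping and anchor extension):
the tolerance for sequencing error in a 100-base read at ~1% error.
`min_support` (default 2 unique reads): the conventional evidence floor for
a junction call.

## Quantification and differential expression

Abundance is reported as RPM — back-spliced junction reads per million
mapped reads: `count / mapped_total × 10⁶`. RPM is invariant to rescaling a
sample's counts and total together.

The two-group differential test is an exact Poisson rate comparison on
pooled counts. With group sums a and b and library-size totals L_A and L_B,
conditional on a + b the count a is Binomial(a + b, L_A/(L_A + L_B)) under
the null; the two-sided p-value is the minimum-likelihood binomial tail.
This is a deliberately simple, exactly testable surrogate for shrinkage
estimators like edgeR's: it matches the decision rule used in this kind of
screen (linear fold change ≥ 2 and raw p < 0.05, no multiplicity
correction) without the empirical-Bayes machinery, and it is exact under
Poisson sampling. The fold change is computed on per-million-normalized
group means with a pseudocount of 0.5 (so all-zero features are defined),
as a difference of logs so that swapping the groups negates log2FC
bit-exactly; the p-value is evaluated in a canonical group orientation so a
swap preserves it bit-exactly. Features with zero counts everywhere report
p = 1, log2FC = 0.

For overdispersed counts an optional `nb-common` method estimates a single
common negative-binomial dispersion by method of moments (median of
(s² − m)/m² within groups) and computes the conditional two-sided tail
numerically from the product of two NB likelihoods. It is a calibration
fallback, not a reimplementation of any published shrinkage estimator.

RT-qPCR validation uses the standard 2^−ΔΔCt relative expression:
ΔΔCt = (Ct_target − Ct_reference)_sample − (Ct_target − Ct_reference)_calibrator.

## Enrichment

Over-representation of a selected gene list (e.g. source genes of
differentially expressed circRNAs) is the one-tailed hypergeometric test:
p = P[X ≥ k] with X ~ Hypergeom(N, K, n) for a universe of N genes, K of
them annotated to the term, and n selected. The universe defaults to the
experiment's detected source genes, not the whole genome — the selection
was drawn from that list, so that is the correct null. Genes annotated to a
term but absent from the universe are dropped before testing; terms with no
universe genes are not tested. Benjamini–Hochberg q-values are reported
within each category (BP/MF/CC/pathway), but thresholding is left to the
caller; both raw and adjusted values are emitted.

## ceRNA network construction

Three rules, applied to circRNA/miRNA/mRNA expression matrices over the
same samples (default: 4 groups × 4 replicates = 16):

1. Sponge pairs: Spearman rank correlation (average ranks for ties)
   strictly below −0.7 for circRNA–miRNA and mRNA–miRNA pairs.
2. Partner pairs: Pearson correlation strictly above +0.9 for circRNA–mRNA
   pairs.
3. Shared-sponge significance: for each partner pair, the overlap k of the
   two miRNA sets is tested with the hypergeometric upper tail
   P[X ≥ k], X ~ Hypergeom(N, K, n), where K and n are the two set sizes
   and N is the miRNA universe; triads with p < 0.05 are retained.

Selection is on the correlation coefficients only (no correlation
p-values), and the sponge-test p is used raw. The miRNA universe is all
miRNAs present in the (filtered) miRNA matrix — the maximal defensible
universe when no target-prediction annotation narrows it; it is
configurable. No sequence-based miRNA target prediction is applied.
Features with more than 50% zero values are excluded from correlation
(mostly-zero profiles give tie-degenerate ranks); the threshold is
configurable. Constant features are skipped with a log entry.

The network is assembled from retained triads: one circRNA–mRNA edge per
triad plus circRNA–miRNA and miRNA–mRNA edges for each shared miRNA, nodes
and edges deduplicated. Exports are Cytoscape-loadable SIF (canonically
ordered, byte-stable on rewrite), GraphML, and node/edge attribute TSVs.

## Trait statistics

Group means are compared by one-way ANOVA followed by Duncan's multiple
range test at α = 0.05. For means separated by a span of p ordered means,
the least significant range is q(α_p, p, df)·√(MSE/n_h), with protection
level α_p = 1 − (1 − α)^(p−1), q the studentized-range quantile computed
numerically from its distribution (no hard-coded tables, so any df and α
are supported), and n_h the harmonic mean of the pair's group sizes (the
Kramer adjustment; exact for balanced designs). The step-down rule applies:
a pair inside a span already declared homogeneous is never declared
different. Decisions are summarized as a compact letter display built by
insert-and-absorb; by construction groups share a letter iff they were not
declared different, and the test suite verifies this encoding exhaustively
on randomized fixtures.

Expression–trait association is the two-tailed Pearson test via the t
transform t = r·√((n−2)/(1−r²)) with n − 2 df, computed per sample
(n = 16 by default), with the conventional star annotation (* p < 0.05,
** p < 0.01, *** p < 0.001). Correlation uses RPM-scale expression by
default (configurable); zero-variance vectors are reported as missing.
Dressing percentage is hot carcass weight / live weight × 100.

## Synthetic data: what it emulates, and what it does not

The generator produces a toy reference (default 2 chromosomes × 100 kb,
20 genes with 4 exons of 200 bp and introns of 300 bp, both strands),
plants back-splice junctions at exon boundaries (plus intronic, antisense
and intergenic cases, in roughly the proportions seen in muscle circRNA
catalogs), and overwrites the flanking dinucleotides so every true junction
satisfies the canonical splice rule on its strand. Three kinds of negative
controls are planted alongside: junctions with a sabotaged acceptor flank
(GT/AC), junctions supported by a single unique read plus byte-identical
duplicates, and ~2,000 linear reads drawn from spliced transcripts (whose
exon-exon junction reads exercise the colinear-orientation rejection).
Back-splice reads concatenate the circle's 3′ terminal segment to its 5′
start; the junction offset is drawn without replacement from
[25, read_length − 25], so both 20-mer anchors are informative and each
error-free read is a distinct (unique) supporting read.

Expression matrices contain planted ceRNA triads: per sample,
miRNA ~ N(100, 20), circRNA = 500 − 2·miRNA + ε, mRNA = 50 + circRNA + ε′,
with ε, ε′ ~ N(0, triad_noise_sd), clipped at zero. The default
triad_noise_sd = 10 puts planted pair correlations near ±0.97 at n = 16,
so essentially all planted triads clear the SCC/PCC filters while i.i.d.
decoys (200 circRNA, 50 miRNA, 50 mRNA by default) essentially never do;
the default was calibrated once against the ≥90% filter-pass requirement
and then frozen. As noise → 0 the planted correlations converge to
exactly −1/+1. A separate integer count matrix carries planted fold
changes (Poisson means ×4 in the contrast group) over a Poisson null
background. Traits are group means plus Gaussian noise (5% CV), with shear
force carrying a monotone age trend and optional circRNA–trait couplings
added as scaled z-scores of the coupled feature's expression.

The simulations deliberately do **not** emulate: realistic error and
quality-score profiles, indels, multi-mapping repeat structure, isoform
diversity within a circle, RNase R enrichment, library-composition biases
(all library sizes are equal unless configured), overdispersion beyond the
optional NB count mode, or the magnitudes of any real trait measurements —
only ordinal structure is meaningful. Passing tests therefore demonstrate
algorithmic correctness under the stated generative model, not performance
on real sequencing data, where alignment ambiguity and biological variance
dominate.

## Numerical choices and degenerate inputs

- Hypergeometric and binomial tails come from scipy's exact distribution
  functions; tests pin them against independent exhaustive enumeration
  (exact integer combinatorics) to 1e-10.
- Correlation matrices are computed by centred dot products; tests pin them
  against direct-formula oracles to 1e-12.
- Mismatch counting treats N as matching nothing.
- Breakpoint ties (equal-mismatch splits) resolve to flank-satisfying, then
  leftmost-start splits, making catalogs deterministic.
- All-identical trait data returns a single shared letter; zero MSE with
  unequal means raises a degenerate-data error.
- Studentized-range quantiles are cached by (α_p, span, df).
- Every random process takes an explicit seed; identical configuration
  yields byte-identical files.

## Problem sizes

The shipped tests and the acceptance script run at the package's standard
desk scale: 2 × 100 kb genome, 50 planted junctions with 3 reads each plus
~2,000 linear reads for detection; 16 samples, 20 triads against 200/50/50
decoys over 10 seeds for network recovery; 2,000 null and 200 planted
features for DE calibration; 100 randomized fixtures for the letter
display. These sizes were chosen so each property is measured with useful
resolution while a full run stays interactive.

## Known limitations

- The linear-mapping surrogate misses alignments whose terminal k-mers both
  carry errors; at the default error rate this is negligible, but the
  filter is not a general-purpose aligner.
- The exact Poisson test is anticonservative under strong overdispersion;
  use `nb-common` there, and neither method reproduces shrinkage-based
  estimators' tagwise behaviour.
- Duncan's procedure controls its per-span protection levels, not the
  family-wise error rate; that is inherent to the method.
- The sponge test treats miRNA sets as exchangeable draws from the
  universe; correlated expression violates this, as it does in any
  hypergeometric overlap test of co-expression-derived sets.
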