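# Methods

`regulome` implements, as a reusable and tested library, an integrative
analysis of a transcription factor's regulatory programme in two
genotype backgrounds: where the factor binds (consensus ChIP-seq
peaks), which genes it activates or represses (cohort correlation and
knockdown intersection), how its genotype-dependent effect shifts
under knockdown (fold-change shift classes with bootstrap nulls), how
DNA methylation differs at its binding regions (dual-criterion region
test and single-cytosine calls), and which binding motifs occur and
co-occur in its peaks (exact-p PWM scanning, set enrichment,
clustering, similarity trees). The motivating system is a
methylation-sensitive repressor such as REST in IDH-mutant versus
IDH-wild-type glioma, where the mutation drives genome-wide
hypermethylation and may redirect binding; nothing in the code is
specific to that factor.

## Coordinates and containers

All genomic records are 0-based half-open (BED convention) everywhere:
readers, writers, internal algebra. One-based inputs must be shifted
on ingest. Tabular data live in pandas DataFrames; peaks, intervals,
gene models and PWMs are small frozen dataclasses.

## Consensus peaks and categorization

For each condition, the two replicate peak sets are intersected
pairwise; every pair overlapping by at least 1 bp yields one consensus
record. The summit is the midpoint of the intersection (floored for
even lengths — the definition gives no tie rule, so the floor is
fixed here) and the consensus interval is `[summit - h, summit + h)`
with `h = 100` bp by default, clipped at position 0, giving uniform
200-bp observations except at a chromosome start. Categorization is by
set algebra with the same >= 1 bp overlap rule: an A-consensus peak
overlapping any B-consensus peak becomes one `common` record with A's
coordinates (two A peaks over one B peak give two records; no
merging); non-overlapping peaks stay `A_specific`/`B_specific`. The
three labels partition all reported peaks. Promoter annotation assigns
a peak to every gene whose strand-aware promoter window (TSS -2000/+500
by default; -/+3000 available through `RunConfig.promoter_window`)
it overlaps by >= 1 bp; unassigned peaks are reported once as `distal`.

## Target classification and knockdown statistics

`classify_targets` correlates each candidate target's expression with
the regulator's across cohort samples (Pearson; two-sided p from the
t approximation with n-2 df — the p-value method is a package choice)
and applies a Bonferroni correction whose multiplier is the number of
targets actually tested, not the genome size. Calls require both
|r| > 0.15 and corrected p < 1e-4; constant-expression genes are
flagged and never tested. Power analysis worth knowing when choosing
cohort sizes: at true |r| = 0.5 these thresholds need the *sample* r to
exceed ~0.49 when ~500 genes are tested, so per-target detection power
is only ~54% at n = 100 samples and approaches 1 around n >= 200. The
synthetic-cohort tests therefore demonstrate (i) perfect sign accuracy
of the calls that are made and a null-miscall rate far below the
nominal level at n = 100, and (ii) near-complete recall in a
well-powered regime (|r| = 0.9).

`primary_targets` intersects ChIP-bound genes with knockdown
differential expression: bound genes up after knockdown are primary
repressed targets, bound genes down are primary activated targets
(padj < 0.05). `fc_shift_classes` takes two genotype contrasts — one
under knockdown, one under control transfection — and classifies each
gene by `shift = log2FC_kd - log2FC_ctrl`: strictly above +0.25 is
`iDEG`, strictly below -0.25 is `dDEG`, the boundary and everything
between is `independent` (the threshold is quoted as "above", hence
strict). Genes missing from either table are dropped with a count.

Both bootstrap nulls are seeded and use the `(1 + #{null >= obs}) /
(n_iter + 1)` estimator, so empirical p is never 0. The concordance
null pairs the observed multiset of query signs, in fixed order, with
the signs of genes drawn uniformly without replacement from the
measured universe (the procedure's published description does not say
how sampled genes acquire labels; this relabeling null is the package's
choice). The overlap null draws |reference| genes uniformly and
overlaps them with the query, whose mean is the hypergeometric
`|q||r|/|U|` — the consistency tests check both closed forms to within
3 Monte-Carlo standard errors at 10,000 draws.

## Differential methylation

The region test pools beta-values per group over all covered cytosines
of a region (cytosine x sample observations; an alternative
`cytosine_mean` mode averages each cytosine across a group's samples
first — the published description does not state which pooling is
used, and pooled is the default). Two criteria are computed: (1) for
each group pair, a Pearson chi-squared test (no continuity correction
anywhere in the package) on counts binned into [0, 0.2), [0.2, 0.6),
[0.6, 1.0], BH-corrected per pair across regions; (2) Kruskal-Wallis
(tie-corrected, chi-squared approximation at any n) on raw beta-values
across all groups, BH-corrected across regions. A region is
significant only when the smallest pairwise q and the KW q are both
below 0.05. Regions with an uncovered group are flagged untestable and
excluded from the FDR; a degenerate pairwise table (all observations
in one bin for both groups) contributes statistic 0 and p 1 rather
than dropping the region, since the KW criterion can still evaluate.

Single-cytosine calls first drop records below the coverage floor
(default 7 reads for cell-line data, 10 for tumor data), then average
beta per group per locus over the samples that retain it and call
`higher`/`lower` when the group difference reaches 0.15 in magnitude.
Note the two distinct 0.2 conventions, both kept exactly as defined:
the region-test binning places beta = 0.2 in the middle bin, while the
three-level summary discretization (`low [0, 0.2]`, `medium (0.2,
0.6]`, `high (0.6, 1]`) places 0.2 in `low`. Motif-level summaries
deduplicate cytosines within one TF's motifs but count a cytosine once
per TF when motifs of different TFs share it.

## Motif analysis

Scanning scores every offset on both strands with log2-odds against a
zero-order background. P-values are exact: per-position scores are
discretized to 1e-3 bits and the full null distribution of the window
score is built by dynamic programming over positions, so the reported
p is the true tail probability of the discretized score — identical to
exhaustive enumeration of all 4^W words, which the tests verify for
W <= 6. The discretization error on the score itself is at most
W * 5e-4 bits; p-values are exact for the discretized score function.
Reverse-strand hits are scored with the reverse-complement matrix and
take p-values from that matrix's own null table; with the default
GC-parameterized (strand-symmetric) background the two tables
coincide and scanning a reverse-complemented sequence returns the
mirrored hit multiset exactly. Windows containing non-ACGT characters
are skipped. PWMs constructed from counts receive a 0.01-per-base
pseudocount before normalization so log-odds stay finite; matrices
normalized without pseudocount can be represented but not scanned.

Hit-level multiplicity uses BH over the whole scan batch with q < 0.05.
Set-level enrichment comes in two variants: a lognormal-background
group test — per-sequence affinity is the log of the mean of 2^score
over all positions and strands, a normal null is fitted to background
affinities and the foreground mean is tested against
`Normal(mu, sd^2/n)` upper-tail (a simplified reimplementation of the
lognormal group correction idea; exact numeric parity with any
external tool is a non-goal) — and a two-sided Fisher exact test of
presence counts implemented by hypergeometric enumeration with BH
across motifs. Unequal set sizes are handled by the balanced-draw
procedure: the enrichment is run on the full large set and on `n_draws`
(default 10) uniform subsamples matched to the small set's size, and
the result is the full-set motifs intersected with the union over
draws (union, not majority vote — the source description is ambiguous
and union is the permissive reading).

Peak co-occurrence clustering turns each peak into a binary
motif-presence vector and applies Euclidean/complete-linkage
hierarchical clustering (the named heatmap tool's documented default;
configurable in principle via scipy). Positional enrichment counts
hits whose midpoint falls in a central window of the fixed-length
sequences against an upper-tail binomial with success probability
window/length; the E-value multiplies p by an explicit
`n_pwms_tested`. PWM similarity is the best ungapped alignment of
probability columns scored by mean per-column Pearson correlation over
overlaps of at least 4 columns, both orientations considered
(zero-variance columns contribute correlation 0); distance
`1 - similarity` feeds UPGMA (scipy average linkage), serialized as
newick through scikit-bio.

## Synthetic data

The generators plant every effect they claim and serialize the truth:

- **Peaks**: 400-bp base intervals on a 2-kb grid, Gaussian coordinate
  jitter per replicate (SD 20 bp in the reference configuration) —
  spacing guarantees that jitter below the consensus half-window never
  crosses categories, which is why recovery is exact.
- **Methylomes**: 10-30 CpGs per region, per-observation beta drawn
  from a Beta distribution with the group's region mean and
  concentration 50 (a spread chosen to look like real per-CpG
  variability), coverage Poisson(30); baseline means uniform in
  [0.1, 0.5], planted regions shift the last group's mean by
  delta-beta 0.4.
- **Expression cohort**: regulator standard normal; a planted target is
  `r*reg + sqrt(1-r^2)*noise`; gene ids are shuffled so names carry no
  class information.
- **DE tables**: control log2FC standard normal, knockdown log2FC adds
  the planted shift (+/-0.5) plus Normal(0, 0.05) noise; adjusted
  p-values for planted genes are *assigned* below 0.05 because DE
  model fitting is out of scope.
- **Sequences**: i.i.d. background at a given GC, one motif instance
  per Bernoulli success, sampled column-wise from the PWM, at a
  uniform offset and strand.

What this does *not* emulate — and therefore what passing tests do not
establish about real data: spatial CpG-island structure and
neighbour correlation of methylation, read-level beta estimation
(beta is drawn, not computed as k/coverage), library-size and
mean-variance structure of RNA-seq counts, sequence composition beyond
zero-order, and peak-calling artefacts. Reference problem sizes (500
regions, 500 genes, hundreds of sequences) were chosen as the smallest
scales at which the planted-recovery statements are statistically
stable.

## Numerical choices and degenerate inputs

- Chi-squared independence drops all-zero rows/columns and refuses
  tables with fewer than two informative rows or columns.
- Kruskal-Wallis returns H = 0, p = 1 on complete ties; empty groups
  are errors.
- BH is the exact step-up with stable sort; adjusted values are capped
  at 1 and returned in input order.
- Fisher's two-sided p sums hypergeometric point probabilities no
  larger than the observed with a 1e-9 relative tie tolerance.
- Pearson correlation is clamped to [-1, 1]; |r| = 1 returns p = 0;
  constant vectors are errors.
- All randomized operations take an explicit integer seed
  (`numpy.random.default_rng`); identical seeds give byte-identical
  outputs.

## Known limitations

- The lognormal group test is an approximation whose null is fitted,
  not derived; its p-values are calibrated only as well as the
  normality of background affinities.
- The region chi-squared treats pooled cytosine x sample observations
  as independent, ignoring within-sample correlation; the
  `cytosine_mean` mode is the conservative alternative.
- Promoter annotation is overlap-only; no exon/intron/UTR hierarchy.
- Bonferroni-corrected correlation screening at cohort sizes around
  100 samples is underpowered for moderate correlations (see the power
  note above); interpret absence of a call accordingly.
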