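# Methods

This note documents the models, conventions, parameter defaults and design
choices behind `hicomp`, and what the synthetic-data validation does and
does not establish about real data.

## Conventions

Pair-record positions are 1-based bp (pairs-file convention); bins are
0-based half-open, `ceil(length / bin_size)` per chromosome with a possibly
short last bin.  Contact matrices are dense, symmetric, non-negative; a
contact is counted once, so the *contact total* of a matrix is its
upper-triangle (incl. diagonal) sum.  Gap bins are carried as a boolean
mask and excluded — never zero-filled — from normalization, eigen-analysis,
correlation strata and enrichment averages.  Whenever two conditions are
compared, the union of their gap masks is applied to both, so the retained
cell set is identical on both sides.

## Pair filtering

A read pair is kept iff (in this precedence, so the bookkeeping buckets are
disjoint): both mates have MAPQ strictly greater than `mapq_min` (default
30); the mates map to different restriction fragments (applied regardless
of separation, cis only — fragment ids are only comparable within a
chromosome); and, for cis pairs, the separation is at least
`dangling_max_bp` (default 500 bp — closer pairs are unligated dangling
ends).  The dangling rule is a pure distance rule; strand orientation is
not consulted, and strand is ignored for binning.  The trans fraction is
`n_trans / n_valid`.

## ICE balancing

The bias model is `M_ij = b_i b_j T_ij` with T of equal row sums.  Each
sweep divides the matrix by the outer product of its normalized row sums
(masked bins held fixed) until the maximum relative row-sum deviation falls
below `tol` (default 1e-6; `max_iter` 200, with a hard error carrying the
last residual on non-convergence).  ICE fixes b only up to a scalar; the
reported bias has geometric mean 1 over unmasked bins, and the balanced
matrix is rescaled to preserve the input's contact total.  For factorizable
inputs (`M = D A D` with balanced A) the planted D is recovered exactly, up
to the scalar.

Gap detection (on raw matrices): a bin is a gap if its marginal is zero or
if fewer than 5% of its row cells (over non-zero-marginal bins) are
nonzero; the fraction rule keeps the detector robust on sparse 40 kb maps.

Depth equalization between conditions rescales both matrices to the mean
of their unmasked contact totals; it corrects sequencing-depth differences
and nothing else.

## SCC

Strata are diagonals k = 1..`max_dist` (default 5 Mb in bins).  Diagonal 0
is excluded: self-interaction bins are artifact-dominated in real data and
zeroed by the simulator.  Per stratum, r_k is the Pearson correlation of
unmasked cell pairs and the weight is `N_k sd(X_k) sd(Y_k)` (population
sd); strata with fewer than 2 cells or zero variance in either map are
skipped rather than counted as r = 0.  The optional mean filter has
half-width h (default 1 at 40 kb, 0 at coarser resolutions); masked cells
are excluded from window means.  Genome-wide SCC pools strata across
chromosomes before weighting.  Count-matched subsampling (multivariate
hypergeometric on the upper triangle) is provided for depth-matching maps
before SCC.

## A/B compartments

Default transform per chromosome: O/E (each cell divided by the mean of
its unmasked diagonal), then the Pearson correlation matrix of O/E
columns, then the leading eigenvector (PC1) of that correlation matrix.
NaN cells inside the unmasked submatrix (e.g. the zero diagonal) are
treated as the neutral O/E value 1 before correlating.  A raw-matrix PCA
mode (`use_correlation=False`) exists for sensitivity checks; the standard
transform is the default and is what the recovery tests exercise, since
"PCA of the normalized matrix" without the correlation step is ambiguous
in common usage.

PC1 is defined only up to sign, so it is oriented against a per-bin
expression density (summed TPM of genes whose midpoint falls in the bin —
the stand-in for an RNA-seq coverage track): if the Pearson correlation is
negative the vector is negated.  This works because active (A) chromatin
is the gene-dense, transcribed fraction; the generator builds that
correlation in (see below).  Bins with PC1 > 0 are A, < 0 are B; exactly 0
(a measure-zero case) is masked rather than assigned arbitrarily.

Switches are classified at bin granularity (A-common, B-common, AtoB,
BtoA, with condition-1 label first); bins masked in either condition are
masked.  Switch abundance is compared against the replicate-to-replicate
switch rate by a 2×2 chi-squared test (1 df, no continuity correction).
Bin-level counting makes the switched fraction directly comparable to
per-bin ground truth; contiguous category segments are also derived for
segment-level summaries and enrichment.

## TADs

The segmentation objective is the γ-scaled density: for a window [k, l),
`s(k,l)` is its upper-triangle sum (diagonal included; the diagonal is
zero by convention) divided by `(l−k)^γ`, and its quality is `q(k,l) =
s(k,l) − μ_s(l−k)` with μ_s the mean of s over all windows of that length.
The dynamic program maximizes the sum of q over disjoint domains of at
least `min_len` (= 2) bins; windows with q ≤ 0 are never included, so a
constant or empty matrix yields no domains.  The DP optimum is verified
against exhaustive enumeration on small instances.  Ties are broken toward
more domains, then earlier left borders, making output deterministic.
γ defaults to 0.8; a single-γ segmentation is reported (no multiscale
consensus, no nested domains).  Multiplying the matrix by a positive
scalar scales q and leaves the segmentation unchanged.

Border overlap between two domain sets matches borders greedily
nearest-first, one-to-one, within ±`tol_bins` (default 1 bin — "within
the limits of resolution" read as one bin); fractions are reported in
both directions and as a Jaccard index.

## Contact enrichment

The mean contact of an interval pair averages over its bin pairs
(Cartesian product for distinct intervals; unordered off-diagonal pairs
within one interval), excluding gap pairs (either bin masked).  A pair is
dropped when gap pairs exceed 50% of its bin pairs — strictly more than,
so exactly half is retained.  Cross-condition comparison keeps only pairs
retained in both conditions and reports per-category log2 ratios, their
median, and a two-sided Wilcoxon rank-sum p between the two per-pair mean
vectors (undefined below 3 retained pairs).

Normalization for these comparisons is deliberately configurable, and the
planted-effect validation runs on raw, depth-matched counts: a
cross-condition *ratio* on the same interval pair cancels multiplicative
bin biases exactly, whereas ICE — which forces equal row sums — provably
redistributes a B-B-only gain partly into an apparent A-A enrichment and
shrinks the recovered effect.  On real data with unequal sequencing
depths, depth equalization (and optionally ICE) should precede
enrichment; the pipeline applies depth normalization in its report path.

## Expression

TPM is the standard length-rate normalization summing to 1e6 per sample;
annotated transcript length is used as effective length (no
fragment-length correction).  Genes map to bins by midpoint under the
half-open convention; a gene spanning a boundary takes its midpoint bin's
category.

The differential-expression caller is an explicit stand-in, not a
negative-binomial shrinkage estimator: size factors by median-of-ratios,
log2 fold change of size-factor-normalized condition means with
pseudocount 0.5, and a p-value from the exact Wilcoxon rank sum on
normalized counts when both groups have ≥ 4 replicates, else from a
two-sided exact Poisson-ratio (binomial) test on pooled normalized counts.
The replicate cutoff is 4 because the exact two-sided rank-sum cannot
reach p < 0.05 below 4 + 4 samples (minimum 2/20 at 3 v 3), which would
make the caller blind at typical 3-replicate designs; the method used is
recorded in the result.  The Poisson route ignores overdispersion and is
anticonservative on its own, but a call additionally requires |log2FC| > 2
(and p < 0.05), which holds the false-flag rate on null genes far below
5% in the recovery tests.  An externally produced DE table (gene, log2FC,
p) can be substituted to reproduce a DESeq2-based workflow.

The rank-sum kernel uses exact enumeration when n + m ≤ 20 without ties
and the tie- and continuity-corrected normal approximation otherwise
(identical constant samples return p = 1); it is validated against full
enumeration of rank assignments for all n, m ≤ 8.  A paired signed-rank
helper on per-item log ratios complements it: when the same items
(segments, genes) are measured in both conditions, the unpaired rank-sum
null is conservative — shared baselines make the two vectors interleave
more evenly than independence allows — while the signed-rank null is
exactly calibrated.  The rank-sum is the reported headline test
(distribution-level comparison); the signed-rank is used where exact null
calibration matters.

The per-category association compares the per-gene mean-TPM vectors of the
two conditions within each switch category by the two-sided rank-sum
(p undefined below 3 genes); a paired mode is available via the
signed-rank helper.

## Synthetic experiments

Expected counts for cell (i, j), i ≠ j:

    E_ij = C · |i−j|^(−α) · (1 + p·[same compartment]) · (1 + t·[same TAD])
             · boost_ij · b_i · b_j

with boost_ij = `bb_boost` iff condition 2 and both bins B in condition 2.
Observed counts are Poisson draws of the upper triangle, mirrored; the
main diagonal is zero (self-ligation bins would otherwise dominate ICE and
the short SCC strata while informing no downstream stage).  `C` is
calibrated once per chromosome on the condition-1, boost-free expectation
so that the expected contact total equals `depth`.  Calibrating per
condition instead would rescale unswitched regions by the compensating
depth factor, planting a spurious cross-condition offset; with the shared
constant, unswitched regions are exactly condition-invariant and the B-B
boost adds contacts the way a genuine gain of B-B interactions would
(condition-2 totals deviate from `depth` by under 2% at bb_boost = 1).

Defaults, chosen as the study conditions the analysis is meant to face:
α = 1.0 (typical mammalian cis decay), plaid p = 0.3 and TAD enrichment
t = 1.0 (recovery succeeds at depth 1e6 per 500-bin chromosome without
being trivial), depth 1e6 contacts per chromosome, bb_boost = 2.
Compartment segments alternate A/B with geometric lengths of mean 20 bins
(~2 Mb at 100 kb); TAD lengths are geometric with mean 6 bins and floor 2
(median domain ~200 kb at 40 kb bins).  Switches flip whole segments
(truncating the last to hit the rounded targets exactly), so they are
contiguous runs: 6% of bins switch, 72% of those A→B.  Planted biases are
lognormal (log-sd 0.25).  The real distribution of switch-segment lengths
is unknown; the geometric choice is a modeling convenience, not an
inference.

Pair streams carry the fields the filter consults; artifact classes
(low-MAPQ, same-fragment on a 500 bp fragment grid, dangling) are planted
at specified rates with a scalar trans fraction, and valid cis pairs are
drawn from the expected matrix so that binning the stream reproduces the
planted architecture.  No trans matrices are simulated, and no
polymer/loop-extrusion physics.

Expression: genes are placed uniformly over bins with lognormal baseline
means; genes in B bins (condition-1 labels) are 4-fold lower — the
A-active coupling that makes PC1 orientation by expression density work.
Genes in B→A bins get their condition-2 mean multiplied by
2^`effect_log2fc` (default 3); counts are negative binomial with
dispersion 0.1.  Tying baselines to condition-1 labels only keeps the
null (effect 0) exactly exchangeable between conditions.

### What passing recovery tests shows — and does not

The generator reproduces the statistical structure the methods assume:
power-law decay, plaid, block domains, factorizable biases, Poisson
counting noise, NB expression noise.  It does not reproduce
distance-dependent bias structure, translocations/CNVs, unmappable-region
gap patterns (gaps are planted uniformly when requested), condition
effects on decay slope, or correlated replicate artifacts.  Recovery at
desk scale therefore validates the implementation and the identifiability
of the planted parameters — not the biological accuracy of any particular
real-data conclusion.

## Problem sizes

Validation runs use chromosomes of 500 bins at the analysis resolution
(100 kb for compartments, 40 kb for TADs), depth 1e6 contacts per
chromosome, 2–3 chromosomes where a statistic needs more segments
(≥ 30 B-common segments, ≥ 50 interval pairs, ≥ 20 affected genes), 200
seeds for null calibrations and 25 for power estimates.  These sizes make
every recovery quantity stable at its stated tolerance while a full test
run stays in the tens of seconds.  The pipeline's default simulated
experiment (two 20 Mb chromosomes, 400k pairs per replicate) is sized the
same way — a desk-scale stand-in, not a genome.

## Known limitations

- Single-γ TAD segmentation; no multiscale consensus, no hierarchy.
- No KR/VC balancing alternatives; ICE only.
- No sub-compartment clustering or saddle-plot compartment strength.
- The DE stand-in is not DESeq2; effect-size shrinkage and dispersion
  sharing are absent (external DE tables are accepted instead).
- Trans contacts appear only as a scalar rate in pair streams; all
  matrix-level analysis is cis.
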