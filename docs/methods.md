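# Methods

## Model and procedure

The package treats a two-class expression study as M independent,
identically distributed subjects (columns); genes within a subject may
be correlated.  Gene relevance is assessed in four stages.

**1. MRMR filter weight.**  Relevance is the two-group one-way ANOVA
F-statistic (equal to the squared pooled-variance two-sample t);
redundancy is the mean absolute Pearson correlation with the other
N−1 genes, computed across all samples ignoring class labels.  The
weight is their quotient, so a gene that separates the classes but
duplicates information carried by many other genes is discounted.
Degenerate cases: a zero pooled variance with equal class means gives
F = 0; with unequal means the denominator is floored at ε = 1e−12.
Zero-variance genes contribute 0 to correlations (logged) rather than
being dropped — bootstrap resamples routinely create near-degenerate
columns, and dropping them would change N mid-pipeline.

**2. SVM wrapper weight.**  A soft-margin linear SVM is fit with
samples as observations and genes as features; the per-gene score is
the absolute primal weight |kᵢ|, kᵢ = Σₘ φₘ yₘ xᵢₘ.  The margin
derivation assumes separable classes; real resamples often are not, so
the implementation is soft-margin with C configurable (default 1.0),
recovering hard-margin behaviour as C grows.  The solver tolerance is
tightened to 1e−8 so the dual expansion reproduces the primal weights
to the 1e−6 contract and refits are bit-stable.  No feature
standardization is applied by default (data are log2-scale and
normalized upstream); it is available as an option.

**3. Quadratic integration.**  Both weight vectors are min–max
normalized to [0,1] (a constant vector maps to zeros: a constant
ranking carries no information) and ranked ascending with average
ties, keeping the rank sum invariant.  The integration score SD is the
rank-weighted mean of the two normalized weights; because ranks are
≥ 1 and β ∈ (0,1), the denominator is strictly positive and
SD ∈ [0,1] always.  The tradeoff β is either fixed or selected by grid
search: for each candidate, the top-50 SD genes feed a linear SVM
scored by seeded stratified 5-fold cross-validation, and the β with
the best mean accuracy wins, ties going to the smallest β (favouring
redundancy control).  This selection protocol is a reconstruction —
the original calibration procedure is not published in detail — and is
labelled as such; β is selected once on the full data and reused
across all bootstrap replicates.

**4. Bootstrap signed-rank inference.**  B = 200 subject resamples
(with replacement; draws leaving fewer than two subjects in a class
are redrawn, at most 1000 times) each get a fresh SD ranking.  Gene
positions are assigned by descending SD with ties broken by gene id,
so each replicate's positions are a permutation of 1..N and the rank
scores Rᵢᵦ = (N+1−Pᵢᵦ)/N form exactly the grid {1/N, …, 1}, with
median → 0.5 and third quartile → 0.75 as N grows.  The one-sided test
of "rank score above Q₃ = 0.75" uses W = Σᵦ 1{R>Q₃}·rank(|R−Q₃|)
(ascending ranks, ties averaged), standardized by E(W) = B(B+1)/8 and
V(W) = B(B+1)(2B+1)/32 and referred to the normal upper tail.  The
indicator definition follows the alternative hypothesis directly; the
literal printed definition of the indicator variable is degenerate and
the step-up adjustment recursion is implemented in its standard form
p̃₍ᵢ₎ = min(p̃₍ᵢ₊₁₎, (N−i+1)p₍ᵢ₎), both verified against independent
oracles (a brute-force retain/reject walk at random levels, and
statsmodels).  Q₃ = 0.75 and the median 0.5 are fixed constants, not
recomputed from data.  P-values are one-sided upper-tail, matching the
one-sided alternative.

## Evaluation criteria

*Sliding windows:* for a ranked set of n genes, window k covers ranks
(k−1)L+1 … (k−1)L+S, K = ⌊(n−S)/L⌋ windows in total.  Each window's
classifier (SVM with linear/RBF/polynomial/sigmoid kernel at library
default hyperparameters) is scored by pooled held-out predictions of a
seeded stratified 5-fold split, so CA is an exact fraction of samples;
the summary is the mean CA and the population standard deviation
(divisor K).  *QTL criterion:* a gene counts when its span is fully
contained (same chromosome, both ends inside) in at least one QTL;
Qstat counts distinct genes (a gene in several QTLs counts once; the
raw pair count is reported separately), and enrichment is the
hypergeometric upper tail P[Qstat ≥ v] with population N, successes V,
draws n.  *GO criterion:* the average pairwise Jaccard distance
1 − |GOᵢ∩GOⱼ|/|GOᵢ∪GOⱼ| over annotated gene pairs; pairs involving an
unannotated gene are skipped and counted, and the divisor is the
number of pairs actually used.

## Synthetic data

The generator emulates a log2-scale microarray-like study: background
genes i.i.d. Gaussian with baseline mean 8 and within-group SD 1,
informative genes shifted by Δ·σ in the case class, and redundant
blocks built from a latent Gaussian factor with loading √ρ plus
independent noise (expected within-block correlation ρ, default 0.6,
block size 10).  Default study conditions: N = 500 genes, M₁ = M₂ = 20
subjects, 20 informative genes at Δ = 2.  Genome fixtures place genes
as non-overlapping 1 kb spans on 12 chromosomes (a rice-like
karyotype, cosmetic only) with QTLs constructed to contain a requested
fraction of a designated subset and nothing else; annotation fixtures
give a coherent subset a shared 5-term core.  What the generator does
*not* emulate: probe-level artifacts, batch effects, heavy-tailed or
count-distributed expression, unbalanced missingness.  Passing tests
therefore demonstrate correctness of the machinery and recovery under
idealized Gaussian signal, not performance on any particular real
platform.

## Numerical choices

Denominator floors at ε = 1e−12 (pooled variance, mean absolute
correlation); ascending ranks with average ties everywhere; SD ties in
position assignment broken lexicographically by gene id (stable and
permutation-valid); bootstrap draws rejected until both classes retain
≥ 2 subjects; all randomness flows from a single integer seed through
one generator, so a fixed seed gives bit-identical result tables.
Result TSVs are written at 12 significant digits and round-trip
losslessly at that precision.

## Calibration of the null approximation

The closed-form moments of W assume the per-replicate indicators are
i.i.d. Bernoulli(1/4), independent of the ranks.  Two departures exist
in practice.  First, |R − 0.75| is not symmetrically distributed under
a uniform rank-score null, which by itself biases W low (conservative).
Second — and dominant — all B replicates resample the *same* observed
dataset, so a gene's position is autocorrelated across replicates: a
gene that by chance looks differential in the observed sample ranks
high in most resamples.  On global-null simulated data the realized
variance of W is an order of magnitude above the nominal closed form,
and the fraction of raw p ≤ 0.05 lands well above the nominal level
(the test suite and the acceptance script compute this fraction
directly).  This behaviour is inherent to the published null
approximation and is characterized here rather than altered: the
method's power comes from rewarding consistent high ranking, and the
same consistency arises for lucky null genes.  Practical implication:
adjusted p-values order genes well (recovery of planted signal is
excellent) but should be read as a ranking score with an approximate,
anti-conservative error rate under a global null, not as exact
frequentist error control.

## Problem sizes

The test suite and acceptance script run simulated studies at
N = 500 genes, 40 subjects and B = 200 bootstrap replicates (about one
second per full pipeline run), with 10 seeded replicates for the
recovery study and 10⁵ Monte-Carlo draws for the null-moment check —
sizes chosen to make each stochastic assertion stable at 3-standard-
error tolerances while keeping a full run interactive.

## Known limitations

Gaussian-only simulator; no RMA/probe-level preprocessing or platform
control-probe removal (a dataset can be prefiltered upstream; the
fold-change/t-test screen is included); no recursive feature
elimination or nonlinear-kernel feature weighting (kernels are used
only for post-selection classification); GO similarity is Jaccard on
flat term sets, not an information-content semantic similarity; the
hypergeometric background for QTL enrichment treats genes as
exchangeable units, ignoring gene length.
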