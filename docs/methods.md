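# Methods

This note documents the statistical model behind each component, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical choices that affect results.

## Shrinkage-entropy mutual information for two-state DE

With a dozen cells per state, maximum-likelihood cell frequencies of a
discretized contingency table are noisy, and the plug-in entropy — hence
the mutual information — is biased upward. The James–Stein-type
empirical-Bayes estimator replaces the ML frequencies θ̂_k = n_k/n with

    p̂_k = λ*·t_k + (1 − λ*)·θ̂_k,
    λ* = (1 − Σ θ̂_k²) / ((n − 1) · Σ (t_k − θ̂_k)²),

clipped to [0, 1], with λ* = 1 when the denominator vanishes (the ML
estimate already equals the target). The shrinkage target t is uniform over
all joint cells — the standard choice for this estimator family; the
intensity is fully data-driven, so no tuning parameter is exposed beyond
the target itself.

Discretization uses the Freedman–Diaconis rule: bin width 2·IQR·n^(−1/3)
with linear-interpolation quantiles, K = ceil(range/width) equal-width bins
spanning [min, max]. K is capped at 16: with ~24 cells, more bins than
samples carries no information and only slows shrinkage. Degenerate inputs:
zero range collapses to one bin; zero IQR with nonzero range (e.g. a gene
expressed in a single cell) falls back to ceil(log2 n) + 1 bins.

Mutual information is the entropy decomposition MI = H(X) + H(Y) − H(X,Y)
in bits (base 2 throughout; entropy has no canonical unit and bits are the
information-theoretic convention). Marginals are obtained by summing the
(shrunk) joint, which makes MI ≥ 0 structural rather than numerical. MI is
computed between *discretized expression* (K bins) and *cell state*
(2 labels). A K×K table between two unpaired cell populations is not
constructible without an arbitrary pairing of cells; the K×L form realizes
the intended reading — high MI means the expression distribution separates
the two states — and the code path accepts genuinely paired K×K input
unchanged.

Numerical detail: entropy sums and the λ* sums run over *sorted* terms.
This makes every result exactly invariant under permutation of the cells of
the table, so MI(T) == MI(Tᵀ) holds to the last bit, not merely to
rounding.

The per-gene test statistic is complemented by a two-sided Wilcoxon
rank-sum p-value: exact null enumeration when min(n_a, n_b) ≤ 12 and the
data are tie-free, otherwise the normal approximation with tie and
continuity corrections (ties are common in single-cell data because
dropout produces exact zeros). If all values are identical, p = 1. Multiple
testing uses Benjamini–Hochberg across all tested genes; genes constant
across every sample are reported untested rather than given MI = 0, since
a constant gene carries no evidence either way. The default decision rule
is q < 0.05 with MI used for ranking; no joint MI/q threshold is imposed.

## Reproducibility metrics

Detection is *strictly* greater than the unit-scale threshold (FPKM > 1.0,
tpm > 1.0, RMA > 7.0) in **both** profiles; requiring both makes the
denominator symmetric in the two replicates. "Reproducible" additionally
requires max/min < fold_threshold (default 2.0) on the linear scale; RMA
log2 values are exponentiated before forming the ratio. Correlations are
Pearson on log10(value + pseudo_count); pseudo_count defaults to 1.0
because the zero-handling convention for log-scale correlation is not
standardized — it is an exposed parameter, and results report the
parameters used.

Downsampling models sequencing at reduced depth as multinomial sampling
with probabilities proportional to the observed counts (with replacement —
the de facto standard, appropriate when depth ≪ library complexity); an
exact without-replacement (multivariate hypergeometric) mode exists, under
which depth = total reproduces the input exactly. With gene lengths
supplied, FPKM is recomputed at each depth as
count / (length_kb · depth_millions). For a min-count rule of 1 the
expected detected-gene count has the closed form Σ_g (1 − (1 − p_g)^depth),
which the tests use as the analytic reference.

Quantile normalization maps each sample onto the across-sample mean of
order statistics; ties within a sample receive the average of the
reference values over the tied ranks (implemented via average ranks and
linear interpolation), which preserves ranks and makes the operation
idempotent.

## Fluctuation analysis

Dispersion is the sample SD (n−1 denominator) of log10(value + 1) — the
log scale because expression noise is multiplicative — or the linear-scale
CV (SD/mean, undefined at mean 0) when a scale-free measure is needed for
cross-platform comparison.

Reproducibility of fluctuation between two independent single-cell sets is
a per-gene two-sided variance-ratio F-test, p = 2·min(P(F ≤ f), P(F ≥ f))
with (n_a−1, n_b−1) degrees of freedom, BH-adjusted. Genes whose adjusted
p *exceeds* the threshold (default 0.6) are called reproducibly
fluctuating: failure to reject dispersion equality is read as agreement
between the sets. The threshold is a parameter, and the unusual direction
of the rule (large q = good) is deliberate. Degenerate cases: zero variance
in both sets means identical dispersion (degenerate-reproducible); zero
variance in exactly one set is maximal disagreement (p set to 0,
non-reproducible).

Separating biology from technical error uses pooled-equivalent samples —
single-cell-sized aliquots of a many-cell lysate, whose biological
variability averages out — as the error-only reference: a one-sided F-test
of var_single > var_pooled per gene. The F calibration is exact when log
expression is normal; on real (or dropout-bearing synthetic) data it is
approximate, which is why the null-calibration test generates lognormal
data and correlates on the pure log scale.

## Sequence QC

The adaptor scan declares a read a hit if any ungapped placement of the
adaptor or its reverse complement — at any offset, including end overhangs
of at least min_overlap (16) bases — reaches identity ≥ min_identity (0.8)
over the overlapping region. IUPAC codes in the adaptor match their base
sets via 4-bit masks; N in a read never matches. Gapped alignment is
deliberately omitted: adaptor carry-over is ungapped in practice, and the
ungapped scan is deterministic, order-independent and fast (reads are
processed in rectangular batches with vectorized bit-AND comparisons).
Both strands are scanned by default. Lowering min_identity can only add
hits (monotonicity), which the tests verify.

Coverage breadth is covered_bases/length per transcript, with the summary
median taken over transcripts at expression ≥ 10 (inclusive). The
GC/length profile partitions isoforms by a detection flag and reports group
means with a two-sided Mann–Whitney location test.

## Sample structure

PCA and Ward clustering operate on log10(value + 1) profiles with genes
centered but not variance-scaled: scaling to unit variance would let
near-constant genes dominate, which is the wrong trade-off for expression
data. PCA signs are fixed by making the largest-magnitude gene loading of
each component positive. Clustering sorts samples by id before linkage, so
the tree is invariant to input column order and ties break
deterministically; trees serialize to Newick with branch lengths derived
from merge heights. Gene selection per principal component for
over-representation is the top m genes by absolute loading (default 500) —
a documented choice, since no canonical rule exists. The hypergeometric
test is the inclusive upper tail P(X ≥ k), BH-adjusted across the set
collection.

## The synthetic-data generator

The generator emulates the structure the analyses assume, with planted
truth for scoring:

- **Expression model.** Per gene and cell type, a baseline log10 mean
  (Normal(1.0, 0.5) — centered on ~10 FPKM, spanning roughly 0.3–300);
  DE genes shift the second cell type by log2FC·log10(2) with |log2FC| ~
  Uniform(1, 4); per-gene cell-cycle shifts Normal(0, 0.1) for S and G2M
  (G1 is the reference). A single cell adds a biological deviation
  Normal(0, σ_bio) with σ_bio ~ Uniform(0.1, 0.5) per gene, then lognormal
  technical noise 10^Normal(0, σ_tech). Noise is lognormal on the log10
  scale because expression analyses here are log-scale throughout; no
  distributional family is canonical and this one is the simplest
  consistent choice.
- **σ_tech = 0.2 (log10) is a free parameter**, documented as such — it is
  not an estimate of any particular protocol's technical noise. All
  sweep-style tests vary it explicitly.
- **Dropout** is Bernoulli with logistic probability
  sigmoid(b₀ − b₁·log10 μ + b₂·(GC − 0.5) − b₃·(log10 L − 3.25)), defaults
  b₀ = −1, b₁ = 1, b₂ = 4, b₃ = 1: low-expressed, GC-rich, short
  transcripts drop out more — the bias directions amplification-based
  protocols exhibit. Only the directions are anchored in observation; the
  magnitudes are generator choices.
- **Pooled-equivalent samples** use the log-scale mean profile (no
  biological deviation) with technical noise and no dropout: they model
  aliquots of a pooled lysate whose input quantity is not limiting, so
  their replicate spread is experimental error only.
- **Spike-ins** at Lys 1000 / Dap 100 / Phe 20 / Thr 5 copies per
  single-cell equivalent, technical noise only.
- **Reads.** Planted reads carry the WTA suppression-primer adaptor
  (forward or reverse complement, uniform position, optional per-base
  substitution rate) in exactly round(n_reads·rate) reads; the remainder
  are uniform random bases, rejection-resampled in the rare event that a
  random read would itself pass the default similarity scan. The exact
  planted count *is* the generator's contract — without rejection, ~2·10⁻⁵
  of random 50-mers would scan positive by chance and blur the truth.
- **Seeding.** The random stream of sample i depends only on
  (master seed, i), so appending design rows never changes existing
  samples. All generators are numpy `default_rng` over `SeedSequence`.

What the generator does **not** emulate — and therefore what passing tests
do not show about real data: gene–gene correlation (all genes independent
given the cell), count-level sampling noise at low expression (expression
is continuous), batch effects beyond the designed set structure,
amplification-efficiency variation that is sequence-specific beyond the
GC/length logistic, doublets, and cell-size/library-size factors. Recovery
results on synthetic data are necessary-condition checks of the machinery,
not protocol benchmarks.

## Problem sizes and tolerances

The test suite and acceptance script use: 1,000 random contingency tables
for estimator-oracle equivalence at 1e-12; the 2,000-gene, 12-vs-12,
200-planted-DE design with 20 label permutations for DE recovery; 5,000
genes at n = 12 vs 8 for F-test calibration (3 binomial SEs around 0.05);
96 single cells vs 48 pooled-equivalents over 1,000 genes for the
fluctuation/error separation; 10,000 reads for adaptor recovery (exact at
zero read error, ±1 percentage point at 10% substitution); and 10,000
Monte-Carlo draws for the downsampling expectation. The demo pipeline runs
at 300–400 genes and ~30 samples, chosen to exercise every stage while
keeping a full run in seconds. F-test p-values are validated against a
direct regularized-incomplete-beta evaluation at 1e-10; hand-derived
examples (λ* for counts [3,1] and [8,2], the 0.27807-bit MI table, the
quantile-normalization and reproducibility worked examples, 5/210 for the
hypergeometric draw) are asserted at printed precision or tighter.

## Known limitations

- The MI statistic has no analytic null distribution here; inference rides
  on the Wilcoxon p-value, with MI used for ranking and effect-size
  reading.
- FD binning on 24 pooled values is coarse (K is typically 3–6); genes
  whose difference is purely in dispersion, not location or distribution
  shape across bins, can score low.
- The F-test assumes log-normal expression; with the +1 pseudo-count and
  dropout zeros the calibration is approximate on single-cell data.
- `de_scan` treats samples as exchangeable within state; no covariates or
  batch terms.
- Quantile normalization assumes comparable distributions; it will erase
  genuine global shifts.
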