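# Methods

## The question and the design

Given a pool of tumor and normal RNA-seq samples, we ask how reproducible a
standard two-group differential-expression (DE) analysis is as a function of
the number of biological replicates n. For each n, a uniform random
permutation of each group's pool is partitioned into four blocks of n, giving
four "experimental repeats" (I–IV) whose sample sets are pairwise disjoint by
construction; each repeat is analyzed entirely on its own, low-count
filtering included, as four independent labs would. The grid runs from n = 3
(below which biological variability is not estimable) to ⌊min(pools)/4⌋.
Repeats are redrawn independently for every n; nesting the draws across n
would correlate the trend curves, and nothing in the design requires it.
Samples beyond 4n are simply unused at that n. A master seed spawns one
child seed per n by fixed arithmetic (`SeedSequence((seed, n))`), so
extending the grid never perturbs existing draws.

## The DE engine

The engine is the classic exact-test workflow for unpaired two-group count
data.

**Filtering.** A gene is kept iff at least `min(group sizes)` samples have
CPM ≥ c, with c = `min_count` / median library size × 10⁶ (default
`min_count` = 10), and its total count is ≥ `min_total` (default 15). CPM
here uses raw library sizes, as filtering precedes normalization.

**TMM normalization.** The reference sample is the one whose 75th-percentile
count fraction is closest to the mean of those fractions. For each other
sample, genes nonzero in both it and the reference contribute
M = log₂ ratio and A = mean log₂ abundance; the top and bottom 30% by M and
5% by A are trimmed, and the factor is 2^(precision-weighted mean M), with
inverse asymptotic binomial variances as weights. Factors are renormalized
to geometric mean 1; effective library size = raw size × factor.

**Dispersion.** Counts are equalized to the geometric-mean effective library
size ("pseudo-counts"). For a gene with within-group counts y₁…y_ν and total
z, the NB conditional log-likelihood given z is
Σᵢ lnΓ(yᵢ + r) − ν lnΓ(r) + lnΓ(νr) − lnΓ(z + νr), with r = 1/φ; the common
dispersion maximizes the sum over genes and groups on φ ∈ [10⁻⁶, 10] (61-point
log-grid plus bounded golden-type refinement; deterministic). Per-gene
(tagwise) dispersions maximize the gene's conditional log-likelihood plus a
`prior_df`-weighted log-likelihood anchor at the common value — a Gaussian
log-density on log φ centred at log φ_common with unit curvature per prior
degree of freedom — via a vectorized golden-section search. `prior_df` = 0
gives unshrunk per-gene estimates; `prior_df` → ∞ collapses every estimate
onto the common value; the default `prior_df` = 10 is a moderate shrinkage
appropriate for the 2n ≤ 48 sample sizes the grid uses.

**Exact test.** With equal per-sample means within a group after
equalization, group totals are NB with size n_g·r, and the tumor total
conditional on the (per-group-rounded) grand total t follows
BetaBinomial(t, n_T·r, n_N·r). Group totals are rounded separately so that
swapping the group labels is an exact symmetry of the p-value. The two-sided
p doubles the smaller tail including the observed outcome, capped at 1; tail
masses are accumulated from the normalized log-pmf to avoid cancellation.
log₂FC is tumor over normal on group-mean pseudo-counts moderated by
`prior_count` = 0.125. DEG calling is |log₂FC| ≥ 1 (inclusive) and
BH-adjusted FDR < 0.05 (strict), both configurable.

This engine deliberately does not chase numerical parity with any external
implementation: pseudo-counts are obtained by simple rescaling rather than a
quantile adjustment, and the moderation scheme above is our own. The
contract is the conditional test as specified, verified against brute-force
enumeration oracles in the test suite; an external exact-test implementation
would be a cross-check, never the engine.

## Reproducibility and power statistics

Overlap rate of k lists = |intersection| / |union|; "the total number of
DEGs of the compared repeats" is the union — the convention forced by the
arithmetic of the worked example (3079 common of 6528 total → 47.17%). For
four repeats, overlap rates and common-DEG counts are averaged over all
C(4, k) combinations for k = 2, 3, 4. DEG-count SD uses the n−1 denominator
(the four repeats are a sample of possible repeats). Power references are
the intersection and union at the grid's maximum n, so power there is 1 by
construction. Degenerate corners never reached in practice are defined and
logged: overlap rate of all-empty lists is 0; union/intersection with an
empty intersection is reported as missing (NaN).

## Outlier forensics

Non-common DEGs between two repeats are the symmetric difference of their
DEG sets, restricted to genes kept by both filters (genes filtered out of
one analysis are reported separately). The report selects the top-k
(default 10) non-common DEGs ranked by FDR in the repeat where each is
significant, and records per repeat the %CV of TMM-scaled CPM per group,
log₂FC, FDR, and Tukey outliers. Quartiles use linear interpolation
(hinge-based conventions may classify edge values differently by at most the
hinge/interpolation discrepancy); mild outliers lie in
(Q3 + 1.5·IQR, Q3 + 3·IQR] or [Q1 − 3·IQR, Q1 − 1.5·IQR), extreme beyond
3·IQR, with the strict inequality at the mild fence.

The exclusion re-test removes a gene's mild + extreme outlier samples *for
that gene only*, reuses the original normalization factors and the gene's
original dispersion, and re-runs the single-gene exact test with the reduced
(possibly unequal) group sizes. The new p-value is compared against the
analysis's original FDR threshold together with the original |log₂FC|
threshold — a full BH re-run over all genes would perturb every other gene's
FDR, defeating per-gene attribution; this approximation is the price of
keeping genes individually re-assessable. Re-estimating normalization and
dispersion after exclusion is available as an explicit choice, not the
default. A gene is *rescued* when exclusion makes its status concordant
across the two repeats. Exclusions leaving fewer than two samples in a group
make the gene untestable, reported as such.

## The synthetic generator

The generator emulates the features of heterogeneous cohort data the
framework is sensitive to, not any particular cohort's marginals:

- per-gene relative expression `baseline_g` ~ lognormal(μ = 4, σ = 1.5)
  (natural-log scale of expected CPM-like abundance);
- gene-wise NB dispersions φ_g ~ Gamma(shape 2, mean 0.15) — a biological
  CV of ~0.4, typical for human tissue;
- true DEGs: a fraction `frac_de` = 0.1 of genes with
  log₂FC = ±(1 + Exponential(1)), so truth aligns with the |log₂FC| ≥ 1
  calling rule by construction;
- library sizes ~ lognormal(μ = 11.7 → ~1.2·10⁵ reads, σ = 0.3) — a
  desk-scale depth at which one DE run completes in under a second while
  counts for kept genes remain well into the tens;
- per-cell heterogeneity h_gj: unit-mean lognormal with σ = 0.5 (tumor) /
  0.25 (normal), placing median per-group %CV in the 50–150 range typical of
  tumor cohorts, with tumor variability above normal;
- outliers: each gene-sample cell independently selected with probability
  0.002 and multiplied by Uniform(10, 50). Injection is post-hoc
  multiplication rather than a mixture in the NB mean, so injected positions
  are exactly known and downstream attribution ("was this non-common DEG
  caused by an injected outlier?") is decidable from the recorded truth.

Defaults: 2,000 genes, pools of 60 + 60 (n up to 15). One integer seed
drives fixed-offset child streams per sub-stage, so outputs are bit-identical
across runs and independent of call order.

What the generator does **not** model: batch effects, patient pairing,
isoform structure, count correlation between genes, and the long-tailed
depth distribution of real cohorts. Passing tests therefore demonstrate the
framework's internal correctness and its qualitative mechanisms
(heterogeneity and outliers degrade reproducibility; exclusion rescues
outlier-driven discordance), not quantitative agreement with any real
cohort's DEG counts.

## Numerical choices and degenerate inputs

- Dispersion search window [10⁻⁶, 10]; estimates are clipped to it. Zero
  within-group variability drives the estimate to the lower bound.
- Golden-section refinements use fixed iteration counts / tight tolerances,
  so results are platform-deterministic.
- All-zero samples, negative counts, unlabeled samples, out-of-range
  p-values and infeasible n raise typed errors naming the offender.
- Floats in every TSV are written with six significant digits so repeated
  runs diff byte-identically.
- Type-I-error calibration is assessed on a pure NB null (no heterogeneity,
  no outliers, no true DEGs): that is the test's own model; heterogeneity
  and outliers are the alternative mechanisms under study.

## Problem sizes

The shipped tests and the acceptance script run on the generator's default
profile (2,000 genes, 60 + 60 pools) with grids restricted to the
informative endpoints (n = 3 vs n = 10) and smaller fixtures (200 genes,
12 + 12) for structural checks — sizes at which the full suite completes in
well under a minute while every statistic retains enough resolution for the
qualitative contrasts it asserts.

## Known limitations

- Power is always relative to the maximum-n reference of the same grid; it
  is a reproducibility-anchored power, not power against ground truth
  (ground-truth recall is tested separately where truth is known).
- The post-exclusion significance rule (new p against the original FDR
  threshold) is an approximation, documented above.
- The exact test conditions on rounded pseudo-count totals; for very shallow
  libraries the rounding is a larger share of the signal.
- Overlap statistics treat DEG lists as unordered sets; no weighting by
  effect size or rank.
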