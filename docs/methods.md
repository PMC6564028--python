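# Methods

This note documents the statistical models, estimators, defaults and
design choices behind `cenckit`, and what the synthetic-data tests do and
do not establish about real data.

## The overlap-enrichment model

The central quantity is the intersection k between a query gene list
(n_a genes, e.g. the upregulated genes of a disease-vs-control
comparison) and a reference signature (n_b genes), both drawn from a
universe of N expressed genes. Under the null of no association the
overlap is X ~ Hypergeometric(N, n_b, n_a), with

    E[X]  = n_a · n_b / N
    Var X = n_a · (n_b/N) · (1 − n_b/N) · (N − n_a)/(N − 1)

Two tests are always reported side by side:

* **Exact tail**: P(X ≥ k) for enrichment, P(X ≤ k) for depletion
  (computed with `scipy.stats.hypergeom`; an exact-rational subset-counting
  oracle in the test suite verifies every feasible tail for N ≤ 25 to
  1e−12). The two tails overlap in P(X = k), so they sum to ≥ 1.
* **Bootstrap sampling distribution**: r random n_a-subsets of the
  universe are intersected with the fixed signature (sampling without
  replacement; r = 10,000 by default). Two summaries are derived: a
  normal-approximation upper tail 1 − Φ((k − μ̂)/σ̂) from the simulated
  mean and sd, and an add-one empirical tail (1 + #{sim ≥ k})/(r + 1).
  The add-one correction keeps p in (0, 1]: it reports exactly 1.0 for a
  maximally depleted observation and never an impossible 0. The empirical
  flavor drives enrichment calls by default because it makes no shape
  assumption; the normal flavor is retained for comparability with
  normal-theory treatments of the same statistic.

Calls use a one-sided convention applied identically to both flavors:
*enriched* if the upper-tail p < 0.05, *depleted* if it exceeds 0.95,
*neither* otherwise.

Implementation detail: the null subsets are simulated by a vectorized
random-key scheme — each iteration assigns i.i.d. uniform keys to all N
genes, the n_a smallest keys define the sampled subset, and the overlap
is the count of reference keys at or below the n_a-th order statistic.
This is identical in law to materializing the subsets and intersecting
them, but runs at numpy speed. Because the overlap law is symmetric in
(n_a, n_b), the larger set is always the randomized one; this makes
results exactly invariant under swapping query and reference at a fixed
seed. Universes are abstract index sets inside the sampler; gene identity
enters only through k.

**Type-I calibration.** The discreteness of the null matters: for an
achieved size near the nominal 0.05 the consecutive exact tail
probabilities around the threshold must be closely spaced, which requires
sets large enough that the null sd spans several integers. The
calibration check therefore uses N = 1500, n_a = n_b = 400 (null sd ≈ 7.8
genes), where the analytic rejection rate of the empirical-p rule at
r = 2,000 is 0.044; smaller sets would put the nearest attainable size
outside 0.05 ± 0.01 for any test of this form.

## Differential expression

The DE stage is deliberately a simple two-group location test: Welch's
unequal-variance t on log2(TPM + 1), two-sided, with per-gene variances
floored at 1e−12 so that genes with identical values in both groups get
t = 0, p = 1 rather than NaN. Transcript-level likelihood-ratio testing
on raw read data is out of scope; the package's claims are about recovery
on ground-truthed synthetic data, not concordance with any specific
quantification tool.

* Fold change: ratio of pseudocounted linear group means,
  fc = (mean_a + 0.5)/(mean_b + 0.5); the pseudocount (configurable)
  avoids division by zero for silenced genes. fc_max = max(fc, 1/fc).
* Multiple testing: Benjamini–Hochberg step-up
  (q_(i) = min_{j≥i} p_(j)·m/j, capped at 1), delegated to
  `statsmodels.stats.multitest` and verified against a brute-force
  implementation of the definition.
* Threshold profiles: `ppcd` (fc > 2, TPM > 15, q < 0.3) and `cellline`
  (fc > 1.5, TPM > 0.6, q < 0.05). All three comparisons are strict, so a
  gene exactly at a bound fails. The loose q of the tissue profile trades
  FDR for power in small, high-variance cohorts (n = 3). The TPM bound is
  applied to the larger of the two group means, so a gene silent in one
  condition but well expressed in the other (the ectopic-expression case
  of interest) is retained.

## Similarity analytics

* Spearman correlation with average ranks for ties; invariant under
  strictly monotone transforms, so it is computed directly on TPM.
* PCA on log2(TPM + 1), genes centered, not variance-scaled (log
  stabilization is the community norm for TPM; variance scaling would
  up-weight low-expression noise). Component signs are fixed by making
  each component's largest-magnitude loading positive, removing the usual
  sign indeterminacy.
* Hierarchical clustering is an explicit O(n³) agglomerative
  implementation rather than a library call because the package promises
  a deterministic, permutation-invariant tree: among equal-distance merge
  candidates, the pair whose lexicographically smallest member labels
  sort first is merged. Metrics: euclidean, or correlation distance
  defined as 1 − Spearman (consistent with the correlation-matrix view of
  the same samples). Linkage: average (default) or complete, both of
  which guarantee monotone merge heights. scipy's linkage serves as a
  cross-check oracle on tie-free data in the tests. Trees serialize to
  Newick with branch lengths equal to merge-height differences.

## Assay quantification

* qPCR: relative expression 2^−ΔCt with ΔCt = Ct_target − Ct_reference.
  The housekeeping reference is an input, not a hard-coded gene.
* Proliferation: N_t/N_0 with N_0 the count at the reference timepoint
  (3 h by default — attached cells before the first division).
* Morphometry: median, 25th/75th percentiles (box, central 50%) and
  1st/99th percentiles (whiskers, central 98%) of per-cell major-axis
  lengths, using linear interpolation between closest order statistics.
  The convention is stated because box/whisker percentiles differ across
  software; at least 5 cells are required.
* pH kinetics: pH converts to proton concentration as
  [H] = 10^(9 − pH) nM. From a lactate-perfusion trace the package
  reports (i) resting [H], the mean over the 30 s before lactate onset
  (window configurable; no standard exists); (ii) max d[H]/dt, the
  maximum central-difference derivative strictly inside the lactate
  window; (iii) the influx excursion, reported as the magnitude of the
  resting-to-extremum change with the direction logged separately (the
  extremum is a rise in [H] — acidification — for an inward
  lactate–H⁺ cotransport); and (iv) the signed post-minus-pre resting
  shift, using the final 30 s. Optional moving-average smoothing of [H]
  before differentiation is available but off by default: smoothing an
  exponential onset biases the maximum derivative downward by roughly
  (window)/(2τ), which is worse than the noise it removes at the default
  noise level.

## The synthetic-data generator

The generator defines the study conditions under which everything is
tested.

**Planted compendium.** Baseline log2(TPM) is gene-wise
Normal(5, 2) — a right-skewed TPM distribution spanning ~0.1 to ~10⁴,
with roughly two-thirds of genes above the 15-TPM tissue threshold.
Differential expression multiplies the disease condition by the planted
linear fold (default 4 up and 4 down); replicate noise is
Normal(0, 0.4) in log2, a realistic cell-line replicate dispersion, with
n = 3 replicates per condition. The default geometry places 429 up- and
378 down-regulated genes in a 12,000-gene universe with disjoint
epithelial (249) and endothelial (108) signatures and planted overlaps of
75 (up ∩ epithelial), 43 (down ∩ endothelial), 3 and 1 (the
wrong-direction pairings). The universe size is a named parameter, not a
constant: published overlap studies rarely state their expressed-gene
universe, and the chance level scales as 1/N. Set construction is by
slicing a single random permutation, so planted overlap counts are exact
by construction rather than by rejection sampling — recovery tests need
exact truth.

**Cell-line panel.** n_groups × n_clones samples; each group receives its
own Normal(0, 2.0) log2 shift on a shared random 10% of genes. Within-
group correlation then exceeds between-group correlation whenever the
effect sd dominates replicate noise (5× at defaults); a zero effect gives
an exchangeable null panel.

**pH trace.** [H](t) rests at 10^(9−7.4) ≈ 39.8 nM, rises during lactate
as H₀ + A(1 − e^−(t−t_on)/τ) with A = 60 nM and τ = 20 s, and after
washout relaxes (τ = 20 s) toward H₀ plus a 10 nM post-resting shift;
protocol 60 s baseline, 120 s lactate, 150 s washout at 1 Hz. Gaussian
noise (sd 0.002 pH) is added in pH space because the instrument reports
ratiometric pH. The default noise is set by an error-budget argument: the
central-difference estimator of max d[H]/dt at 1 Hz carries a
deterministic −4.8% discretization bias (it averages the decaying slope
over 2 s), and the maximum-over-samples operation converts derivative
noise into a positive bias of order the per-sample derivative sd; 0.002
pH keeps the combined error of the mean estimate within 5% of the
analytic A/τ = 3 nM/s. Kinetics recovery is therefore asserted on means
across seeded traces, not per trace — the max of a noisy sequence is not
an unbiased per-trace estimator at any realistic noise level. Ground
truth recorded with each trace is analytic: max d[H]/dt = A/τ,
Δ[H]_influx = A(1 − e^−(t_off−t_on)/τ), resting shift =
post_resting_shift.

**What passing these tests shows — and does not.** The generator is
log-normal with gene-independent noise and multiplicative, two-group
effects. Real RNA-seq has correlated genes, mean-variance coupling,
library-composition effects and quantification uncertainty; real pH
traces have drift and calibration error. Recovery on synthetic data
validates the statistical machinery (exactness, calibration, seeded
reproducibility, planted-signal detection), not the biological
correctness of any particular real-data result.

## Determinism and problem sizes

Every stochastic operation takes an explicit seed and uses its own
`numpy.random.default_rng`; the pipeline fans a single top-level seed out
to per-stage seeds via a stable hash, so stages are independently
reproducible and a rerun is byte-identical apart from the report
timestamp. The test suite runs the bootstrap–exact agreement check at
r = 100,000 over 20 geometries up to N = 5,000, the calibration at 2,000
replicates of r = 2,000, and the end-to-end recovery at the full default
scale (N = 12,000, r = 10,000); the acceptance script uses the same
defaults with 500 calibration replicates. These sizes keep the whole
suite in a few CPU-minutes while leaving Monte Carlo error an order of
magnitude below every asserted tolerance.

## Known limitations

* The DE stage is a two-group location test on TPM; it does not model
  counts, covariates or transcript-level uncertainty.
* Gene identifiers are matched by exact string equality (after trimming);
  no alias resolution.
* The enrichment test conditions on fixed set sizes; it is not a
  competitive test on continuous statistics (no GSEA-style analogue).
* The pH pipeline starts from pH, not raw fluorescence ratios; BCECF
  calibration is upstream of the package.
* Impedance-based barrier-function modelling and image-derived
  measurements (wound closure, cell segmentation) are out of scope; the
  morphometry and proliferation calculators consume already-measured
  values.
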