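# Methods

This note documents the statistical machinery, the defaults and why they
were chosen, what the synthetic cohorts do and do not emulate, and the
numerical decisions that matter when reproducing results.

## Risk partition

Each gene is screened per cohort with a univariate Cox proportional-hazards
model, hazard h(t|x) = h0(t)·exp(βx), with expression x as a *continuous*
covariate — the score, not the individual gene, is what gets dichotomized
later. The engine maximizes the **Breslow** partial likelihood (tied event
times each contribute a full risk-set term) by Newton iteration on an
internally standardized covariate, capped at 100 steps with step-halving
whenever the likelihood decreases. Wald inference uses the observed
information. A fit that does not converge — in practice, complete
separation, where the partial likelihood has no interior maximum — is
reported as not-significant with a warning rather than propagating a
divergent estimate. Breslow was chosen over Efron because it admits an
exact brute-force oracle (a grid search over β on the same likelihood),
which the test suite exercises on small instances to 1e-3; on tie-free
data the engine also matches lifelines' Efron fit to 1e-4.

Classification: high-risk iff p < α and HR > 1, low-risk iff p < α and
HR < 1, with α = 0.05. The cross-cohort vote is literal: a gene goes to
the positive set only when its high-risk count strictly exceeds its
low-risk count; ties and never-significant genes fall to the negative set
("otherwise"). Genes unmeasured or unfittable in a cohort simply do not
contribute a vote there. A `drop_never_significant` switch excludes
never-significant genes from both sets instead; it is off by default.

## Single-sample enrichment and the directional score

For gene i with values x_i1..x_in across samples, the kernel CDF estimate
is ẑ_ij = (1/n) Σ_k Φ((x_ij − x_ik)/h_i) with Gaussian Φ and bandwidth
h_i = sd_i/4. Constant genes get a floored bandwidth, 1e-8·(global sd + 1),
so they land mid-rank instead of dividing by zero. Within each sample,
genes are ranked by ẑ descending — ties broken lexicographically by gene
id, making every run bit-reproducible — and the symmetric rank statistic
is r_ij = |p/2 − rank_ij|.

The enrichment walk visits the sample's genes in that order: an in-set gene
adds |r|^τ normalized by the in-set total (τ = 1 by default), an out-of-set
gene subtracts 1/(p − |S|). ES is the maximum positive deviation plus the
minimum negative deviation (the magnitude-difference variant), hence
bounded in [−1, 1]. If all in-set weights are exactly zero — possible only
for tiny sets at even p — in-set steps fall back to uniform 1/|S|.

The directional score is ES(positive) − ES(negative). Swapping the two sets
negates it exactly. Samples split into high/low groups at the cohort-wise
median, with scores exactly at the median assigned to the low group
(they are not *above* the median).

Two estimator notes. First, the Gaussian-kernel ẑ is exactly invariant to
affine per-gene transforms (the bandwidth rescales with the data) and
preserves each gene's cross-sample ordering under any strictly monotone
transform, but the cross-*gene* ranking within a sample — and hence ES —
is only approximately invariant under non-affine monotone transforms. An
`ecdf` kernel option replaces ẑ by the empirical CDF and is exactly
rank-invariant. Second, the kernel CDF is estimated within each cohort by
default, matching the per-cohort median split; a pooled mode estimates it
once on the full matrix.

## Copy-number burden

Coordinates are 1-based inclusive (SEG convention). Binning of a log2
ratio onto {−2,−1,0,1,2} uses the published cutpoints with the published
inclusivity: [1,∞)→2, [0.25,1)→1, [−0.25,0.25)→0, [−1,−0.25)→−1,
(−∞,−1)→−2.

* A segment is **focal** when it lies within a single arm and is shorter
  than `focal_fraction` (default 0.5) of that arm. The published method
  never defines "focal"; the length-fraction rule follows the broad/focal
  convention of standard CNV callers and is configurable. The focal score
  is the sum of binned ratios over focal segments.
* Each arm's level is the overlap-length-weighted mean log2 ratio of the
  segments on it, with uncovered bases counted as 0 (masked segment files
  omit neutral regions). Arms are called gain above +0.25 and loss below
  −0.25.
* "Both arms at the same log2 ratio" is operationalized as both arms
  *binning* to the same nonzero value — raw float equality is measure-zero
  — in which case the event contributes its bin once to the chromosome
  score and those arms are excluded from the arm score, so the additive
  decomposition total = focal + arm + chromosome attributes each event to
  exactly one scale. An `arm_indicator_mode` switch counts arms as ±1
  instead of their binned magnitude.

TMB divides the per-sample count of nonsilent mutation calls (missense,
nonsense, frameshift, in-frame, splice, start/stop) by an exome size of
38 Mb, a common convention; raw counts are also reported.

## Association suite

Prognosis uses the same Cox engine on the continuous score; Kaplan–Meier
curves and the log-rank test come from lifelines. The adjusted linear
model is OLS of burden (or TMB) on score plus age/sex/race covariates,
one-hot encoded against the alphabetically first level; a rank-deficient
design is an error naming the collinear columns. Spearman panels are BH-
adjusted within one family per feature table per cohort — panel-shaped
families mirror how such heatmaps are read. The differential filter uses
Welch's t per gene with BH over all genes and keeps |log2FC| > 1 with
padj < 0.05, where log2FC is the difference of group means of the already
log2-scaled matrix (no pseudo-counts; the matrix is assumed log-scale on
input). Welch-t was chosen over a moderated-t empirical-Bayes fit: at the
group sizes this pipeline targets (hundreds per group) shrinkage changes
little, and the filter thresholds are identical.

## Consensus selection

All three selectors consume the same per-gene standardized matrix.

* **LASSO-logistic** scans 50 log-spaced inverse penalties with common
  stratified k-fold assignments (k = 5) and picks the CV deviance minimum;
  the minimum rule is deliberately permissive and matches a several-gene
  selection on small panels. A one-standard-error option picks the
  sparsest model within one SE — that variant, not the default, is what
  controls false selections under null labels.
* **Random forest** (500 trees) ranks genes by impurity importance and
  selects those above the mean importance. Any rule turning a ranking into
  a list is a convention; above-mean is declared, simple, and scale-free.
* **SVM-RFE** fits a linear SVM (C = 1, balanced class weights), drops the
  smallest-|weight| gene per round, records the 5-fold CV error at every
  surviving-set size, and selects the set at the error minimum, preferring
  the smaller set on ties. One caveat is worth knowing: once the
  informative genes are in the surviving set the error curve is nearly
  flat, so the *exact* location of the minimum is noise-driven even though
  the informative genes themselves are reliably retained.

The consensus is the plain set intersection, reported lexicographically.
All seeds and fold assignments are recorded in the result, and reruns at a
fixed seed are bit-identical.

## Synthetic cohorts

A single latent factor s ~ N(0,1) per sample drives every planted signal —
the simplest structure under which each downstream panel has a sign-known
answer:

* expression: truth-positive genes a·s + ε, truth-negative −a·s + ε, null
  genes ε, with loading a = 1 and ε ~ N(0,1) (so truth genes correlate
  1/√2 with the signal);
* survival: event times exponential with hazard h0·exp(β·s), h0 = 1/1000
  per day and β = 0.8 by default; independent exponential censoring whose
  rate is solved numerically (Brent) so the expected censored fraction hits
  the 30% target; DSS/DFI/PFI share the event process with independent
  re-censoring, emulating correlated endpoints;
* copy number: three default event classes on the four-chromosome toy
  genome — a focal gain (log2 = 1.2, 10% of an arm, 30% of samples), a
  whole-arm gain (0.5, 30%), a whole-chromosome loss (−1.2, 20%) — with
  carriers drawn with weights exp(0.8·s) so burden associates positively
  with the score; every arm is fully tiled with background log2 = 0
  segments and every planted event is recorded;
* mutations: nonsilent counts Poisson(10·exp(0.3·s)) plus ~30% silent
  calls;
* features: four planted panels at target Spearman correlations ±0.4/±0.5
  with s, constructed through the bivariate-normal identity
  ρ_Pearson = 2·sin(π·ρ_Spearman/6).

The default study conditions are 3 cohorts × 500 samples and 10 + 10 truth
genes among 60. Everything derives from one SeedSequence, so a seed fully
determines the bundle.

What the generator does **not** emulate: TCGA marginal distributions
(library size, batch structure, cohort-specific baselines), gene–gene
correlation beyond the single factor, subclonal or allele-specific copy
number, mutation hotspots, and paired tumor/adjacent tissue. Passing tests
therefore demonstrate that the machinery recovers planted effects of
realistic size under clean sampling assumptions — not that it is robust to
the full messiness of archival tumor data.

## Problem sizes used in the checked results

The acceptance script and acceptance tests run the default 1500-sample
bundle for screening/scoring/burden/association checks, 200 random small
instances (≤6 genes × ≤4 samples) for walk-oracle equivalence, 50 small
instances (n ≤ 8) for Cox-oracle equivalence, 200 replicates per test for
null calibration, and 100 seeds of the 300-sample 8-gene panel for
consensus recovery — sizes chosen so the full chain reruns from scratch in
a few minutes on one CPU.

## Known limitations

* The Cox engine is single-covariate by design; the adjusted analyses use
  OLS, not multivariate Cox.
* Arm means treat uncovered bases as neutral, which dilutes real events in
  sparsely covered files.
* The Gaussian-kernel enrichment statistic is only approximately invariant
  under non-affine monotone transforms (use the `ecdf` kernel when exact
  rank invariance matters).
* The RF above-mean selection rule and the focal length fraction are
  declared conventions, not published prescriptions; both are configurable.
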