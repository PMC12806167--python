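# Methods

This note documents the models, algorithms and parameter choices behind
`dfncstates`, in the spirit of a package methods appendix: what is
computed, under which assumptions, and what the defaults mean.

## The generative model behind the synthetic cohort

Real data for this kind of study — group-ICA component timecourses from a
clinical fMRI cohort — are not publicly deposited, so the package ships a
generator whose output exercises every pipeline stage with known ground
truth.

**States.** Brain dynamics are modeled as a first-order hidden Markov
chain over K covariance regimes with zero-mean multivariate Gaussian
emissions directly at the component-timecourse level (no voxel data, no
hemodynamic convolution, no ICA step — those are upstream of this
pipeline's inputs).  Each regime's C×C correlation matrix is a *block
sign-pattern* state: the C components are partitioned into functional
domains (default: default-mode 8, central-executive 6, salience 4,
attention 4, somatomotor 3, visual 6, subcortical 3 for C = 34), every
domain gets a sign per state, and

    cov = cross_r * g gᵀ + (within_r − cross_r) * blockdiag + (1 − within_r) * I

where `g` is the per-component sign vector.  Within-domain correlation is
`within_r`; between-domain correlation is `±cross_r` according to sign
agreement.  For `0 ≤ cross_r ≤ within_r < 1` this is symmetric positive
definite with unit diagonal *by construction*; other settings fall back
to a logged nearest-SPD repair (eigenvalue clipping plus diagonal
renormalization).  States differ on roughly half of all cross-domain
edges, which mirrors how empirical dFNC centroids differ — large-scale
patterns of between-domain correlation and anticorrelation — and gives
centroids an L1 separation that scales with the edge count rather than
with a single block.  Defaults: `within_r = 0.6`, `cross_r = 0.25`.

**Transitions.** A "sticky" chain with uniform off-diagonal mass:
self-transition 0.9 by default, i.e. mean dwell 10 TRs = 20 s.  The
emulated study reports no per-state transition probabilities, so this is
a free parameter chosen to produce dwell times on the order of (but below)
the window length.  The stationary distribution is uniform.

**Study design.** 62 subjects in four cells (MDD-active 18, MDD-sham 18,
HC-active 13, HC-sham 13), three runs each (`rest_pre`, `brooding`,
`rest_post`) of 200 timepoints at TR = 2 s over 34 components.  Covariates:
age ~ Normal(28, 9) truncated to 18–65, sex Bernoulli(0.74 female), mean
framewise displacement ~ |Normal(0.12 mm, 0.05 mm)| capped at the 0.3 mm
exclusion ceiling so the default design is never silently reduced
(explicit high-motion outliers can be planted with `n_fd_outliers`).

**The planted brooding link.** The RRS-B score is generated as

    rrs_b = round(group_mean + effect × (f − f̄) + ε),  clipped to [5, 20]

where `f` is the subject's *true* fraction of brooding-run timepoints in
the designated state (state 3 by default), `f̄` its cohort mean, and ε
Gaussian (sd 2.5 for MDD, 1.1 for HC; group means 12.7 and 6.2, matching
the emulated sample's summary statistics).  The link is planted in the
MDD group only (`effect_size`, default −20; `effect_size_hc` defaults to
0) because the association being emulated is depression-specific, and a
shared effect combined with the small HC score variance would make the
HC correlations dominate.  With the default chain, across-run occupancy
sd is ≈ 0.11, so `effect = −20` yields τ ≈ −0.4 in the MDD brooding cell
— the magnitude of association the package is designed to detect, and
one that is *borderline* under FDR at n = 36, again faithful to the
emulated effect size.  The "strong" setting used by the end-to-end
recovery tests is `effect = −40`, chosen by a design-time power
calculation to be detectable through the full FDR-controlled pipeline in
well over 80 % of replicates.

**The planted intervention effect.** For the MDD-active cell only, the
`rest_post` transition matrix is mixed with a point mass on the
designated state: `P′ = (1 − a) P + a 1ₛ`, default `a = 0.05`, raising
stationary occupancy from 0.25 to ≈ 0.46.  A design-time power
calculation put signed-rank detection at n = 18 above 95 % under a
Bonferroni-style family correction at this setting.

**What the generator does not emulate.** Hemodynamics, spatial structure,
scanner noise spectra, motion-correlated artifacts, inter-subject
covariance heterogeneity, and any dependence of covariates on group.
Passing tests therefore demonstrate correctness of the estimation and
inference machinery under the stated model, not robustness to real fMRI
artifacts.

## Denoising

Applied per run, in order: (1) zero-phase 5th-order Butterworth low-pass
at 0.15 Hz (forward-backward, so no phase distortion of windowed
covariance); (2) de-spiking by the scale-free robust rule
|x − median| > 4 × 1.4826 × MAD, flagged samples replaced by a cubic
spline through unflagged samples (boundary spikes take the
nearest-interior spline value; a column with > 50 % flags is rejected as
unusable); (3) least-squares removal of polynomial trends up to cubic;
(4) multiple regression on supplied nuisance regressors with an internal
intercept, dropping collinear columns with a warning.  Every step
preserves shape and is deterministic; the chain records a provenance log.
The de-spiking flags are amplitude-based by default (the alternative —
deriving flags from motion traces — is supported by passing a motion
regressor matrix and thresholding upstream).

## Windowed connectivity

Windows are a rectangle of `width` samples (default 22 TRs = 44 s)
convolved with a Gaussian of σ = 3 TRs, truncated to the window support
and normalized to unit sum.  Window starts are 0, step, 2·step, …, with
exactly ⌊(T − w)/step⌋ windows — the convention that yields the
published 178 windows for T = 200, w = 22, step 1 (the last admissible
full window is omitted).  The window covariance removes the
taper-weighted mean and floors zero variances at 1e−10 with a warning
rather than dropping windows, keeping window counts exact.

**Graphical lasso.** The per-window precision solves

    min_Θ  tr(SΘ) − log det Θ + λ‖Θ‖₁,off

by the classical block coordinate descent over columns of the working
covariance W (inner lasso subproblems solved by coordinate descent),
JIT-compiled with numba.  This algorithm is the appropriate one here
because 22-sample tapered windows of ≥ 34 components are *always*
rank-deficient: first-order whole-matrix methods stall on these inputs,
while BCD warm-started from the adjacent window converges in a few
sweeps (0.3–40 ms per fit).  Convergence is declared when the standard
duality-gap certificate falls below `tol × C` (default `tol = 1e−5`);
non-convergence raises an error carrying the last gap.  `λ = 0` returns
the unpenalized inverse.  The per-sweep objective trace is exposed and
asserted non-increasing in tests.  The estimate is validated against an
independently coded coordinate-descent/LARS solver to 1e−5.

**Penalty selection.** Per run, windows are split into 5 contiguous
folds; for each λ in a 10-point log grid on [0.01, 1] the precision is
fitted on the pooled (averaged) training-window covariance and scored by
mean held-out Gaussian log-likelihood.  Two details matter: (i) training
windows whose sample support overlaps the test fold are *embargoed* —
adjacent windows share 21 of 22 samples, and without the embargo the
leaked samples systematically favor overly dense fits; (ii) the argmax
rule resolves ties toward the larger (sparser) λ, and a glmnet-style
one-standard-error rule is available as an option.  One λ serves all
windows of a run.

**Fisher transform and covariates.** The regularized covariance implied
by Θ̂ is normalized to correlation and Fisher z-transformed (diagonal set
to 0).  Covariate control operates on the z scale *after* the transform
— residualizing raw correlations could leave values outside (−1, 1) —
and at the subject level: for each edge, subjects' across-window mean z
is regressed on mean-centered age, sex and mean FD, and the fitted
covariate contribution is subtracted from all of that subject's windows.
The intercept is preserved and within-run dynamics (the object of study)
are untouched.  Per-window covariate regression is deliberately not done.

## State clustering

Upper-triangle z edges of every window form the clustering space
(E = C(C−1)/2).  Exemplars are windows at local maxima of the per-window
edge variance (endpoints qualify against their single neighbor; plateau
ties go to the earlier window).  K-means uses Manhattan distance with
componentwise-median centroid updates (k-medians, the L1-optimal
centroid), distinct-point initialization, best of `n_replicates` runs
(default 500 on exemplars), and empty-cluster repair by splitting the
largest cluster.  The exemplar solution initializes one refining pass
over all windows (a frozen-centroid mode is available); final labels are
nearest-centroid with ties to the lower state index.

**Choosing k.** For each candidate k the validity index is the mean
within-cluster distance divided by each point's mean distance to the
*other* centroids.  The elbow is the interior candidate with the largest
perpendicular distance *below* the chord joining the curve's endpoints.
Two deliberate choices: the point-to-other-centroids denominator (the
mean pairwise-centroid version declines nearly linearly past the true k
and yields no usable bend), and the signed distance (an above-chord bulge
at small k is not an elbow).  An exactly linear curve degenerates to a
tie, resolved to the smallest interior candidate.

## Temporal metrics

Per run and state: fraction of time (window count ratio, computed with
exact rational arithmetic before conversion to float), mean dwell time
(mean length of maximal constant-label runs, in windows, with a
windows × step × TR seconds column alongside), a visited indicator, and
the transition count.  States never entered contribute zeros — not
missing values — so subjects who never reach a state stay in group
statistics, which is also why the tied-rank-aware τ-b is the correlation
of choice downstream.

## Inference

All permutation p-values use the add-one estimator (1+b)/(1+B), valid
and never zero; exhaustive enumeration replaces sampling whenever the
arrangement count fits within the permutation budget.  Rank statistics
use midranks with tie-corrected variances.

- **Group contrasts** (MDD vs HC; per state, outcome and baseline
  condition): Wilcoxon rank-sum with label-shuffling null, BH-FDR across
  the 2 × K × 2 family.
- **Brooding correlations**: Kendall τ-b of RRS-B against each outcome
  within every group × condition cell, BH-FDR pooled across all cells by
  default (a per-cell scope is available).  The "flagged" state is the
  smallest adjusted p in the MDD × brooding cell, ties broken by raw p.
- **Entry proportions**: Pearson χ² (df 1, no continuity correction by
  default) on entered/not-entered counts per state.
- **Zero vs non-zero occupancy**: pooled-variance two-sample t-test on
  RRS-B between subjects who never entered the flagged state and those
  who did.
- **Pre/post contrasts**: Wilcoxon signed-rank with sign-flip null per
  intervention subgroup and outcome, family-wise error controlled by the
  single-step max-|z| statistic over a *shared* permutation stream (one
  sign per subject per permutation, reused across that subject's
  outcomes); Bonferroni is available as an alternative.  The FWE family
  is the 4 subgroups × 2 outcomes by default.

Zero-difference pairs are dropped with their count recorded; degenerate
cells (zero-variance samples, empty marginals) are reported as NaN rows
with a note rather than aborting the analysis.

## Orchestration and reproducibility

`run_pipeline` chains exclusion (mean FD strictly above 0.3 mm; the
boundary is retained), denoising, FNC estimation, covariate control,
clustering, metrics and inference.  Every stage seed is
`sha256(master_seed:stage) mod 2³¹` — a pure function of the master seed
— so identical configurations reproduce outputs byte for byte.  Tables
are tab-delimited text; window arrays are `.npz` with JSON sidecars.

## Problem sizes used in tests and the reproduction script

The shipped tests and `scripts/acceptance.py` run the full 62-subject
design wherever the quantity is a design count or a truth-label-based
statistic (pooled window count, planted τ and pre/post z), and scaled
scenarios elsewhere: state recovery uses 12-subject, 12-component
high-SNR cohorts (`within_r = 0.7`, `cross_r = 0.6`, self-transition
0.975) with the standard 22-TR window; permutation calibration uses
2,000 null replicates at the study's 18-vs-13 and 18-pair sample sizes
with 999 permutations each.  These sizes were chosen so the entire suite
completes in minutes on a single CPU while keeping every statistical
check at its stated tolerance.

## Known limitations

- The graphical-lasso penalty is shared across a run's windows; a
  per-window λ is not supported (and would break comparability of
  sparsity across windows).
- Exhaustive signed-rank enumeration is used only up to 2^m ≤ B; for
  m ≈ 14–20 pairs the Monte-Carlo null with B = 10,000 has p-value
  resolution 1e−4.
- The elbow criterion needs at least three candidate k and assumes a
  decreasing index curve; heavily overlapping states can still defeat it.
- Dwell-time estimates are truncation-biased for states whose sojourns
  approach the run length.
- The synthetic emission model draws timepoints conditionally
  independently given the state sequence; it has no within-state
  autocorrelation beyond what the low-pass filter induces.
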