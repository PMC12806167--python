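# dfncstates

Temporal dynamic functional network connectivity (dFNC) analysis for
fMRI component timecourses, with a fully synthetic, ground-truthed cohort
generator.  The package targets studies that relate time spent in
recurring whole-brain connectivity states to behavior — here modeled on a
design with depressed (MDD) and healthy (HC) groups scanned at rest and
during an induced brooding (rumination) condition, before and after a
neurofeedback intervention, with brooding severity scored on the
Ruminative Response Scale brooding subscale (RRS-B, integer range 5–20).

## What it computes

Given per-run component timecourses (T×C matrices at sampling interval
TR), the pipeline:

1. **Denoises** each run: zero-phase low-pass Butterworth filter
   (0.15 Hz), MAD-based de-spiking with cubic-spline replacement,
   polynomial detrending (up to cubic), and nuisance regression.
2. **Estimates windowed connectivity**: Gaussian-tapered sliding windows
   (width 22 TRs, taper σ = 3 TRs, step 1 TR; a 200-timepoint run yields
   T − w = 178 windows), per-window sparse precision by graphical lasso

   &nbsp;&nbsp;&nbsp;&nbsp;Θ̂ = argmin_Θ  tr(SΘ) − log det Θ + λ‖Θ‖₁,off

   with λ chosen per run by embargoed contiguous-fold cross-validation,
   then converts Θ̂ to a correlation matrix and applies the Fisher
   z-transform. Subject-level covariates (age, sex, mean framewise
   displacement) are regressed out of the between-subject z levels.
3. **Finds brain states**: k-means with Manhattan distance and median
   centroids, initialized 500× on high-variance exemplar windows, then one
   refining pass over all windows; k selected by the elbow of the
   within/between cluster validity index.
4. **Summarizes dynamics** per run and state: fraction of time (occupancy)
   and mean dwell time (consecutive windows per visit), state-entry
   indicators and transition counts.
5. **Runs the inferential layer**: permutation Wilcoxon rank-sum group
   contrasts, Kendall τ-b correlations of RRS-B with occupancy under
   Benjamini–Hochberg FDR, χ² tests of state-entry proportions, a
   zero-vs-nonzero occupancy t-test, and pre/post permutation signed-rank
   tests with single-step max-statistic (Westfall–Young) FWE control —
   all with the add-one permutation p estimator (1+b)/(1+B) and 10,000
   permutations by default.

The synthetic module generates the whole study: a first-order Markov
chain over K covariance regimes (block sign-pattern correlation matrices
over functional domains) with Gaussian emissions, a planted negative
linear link between brooding-run occupancy of one designated state and
RRS-B in the MDD group, and a planted occupancy increase after the
intervention confined to the MDD-active cell.

## Worked example

Simulate the full 62-subject design and run every stage — denoising,
per-window graphical lasso with cross-validated λ, covariate control,
exemplar-initialized clustering at k = 4 and the complete inferential
layer — with one call:

```python
from dfncstates import PipelineConfig, run_pipeline

bundle = run_pipeline(PipelineConfig(master_seed=7))
print(bundle.inference.report)
```

prints (roughly 15 minutes on one CPU):

```
Temporal dynamics inference summary
====================================
alpha = 0.05, permutations = 10000
Flagged brooding-related state: 1 (not FDR-significant in MDD/brooding): dwell_time: tau=-0.239 (p_adj=0.5228), fraction: tau=-0.320 (p_adj=0.2732)
  pre->post  HC_active dwell_time z=-0.94 FWE-p=0.9201
  pre->post  HC_active fraction   z=+0.00 FWE-p=1.0000
  pre->post    HC_sham dwell_time z=+0.91 FWE-p=0.9299
  pre->post    HC_sham fraction   z=+0.42 FWE-p=0.9989
  pre->post MDD_active dwell_time z=+1.79 FWE-p=0.3589
  pre->post MDD_active fraction   z=+3.20 FWE-p=0.0017*
  pre->post   MDD_sham dwell_time z=-0.65 FWE-p=0.9867
  pre->post   MDD_sham fraction   z=-0.07 FWE-p=1.0000
```

Reading the output: recovered state indices are arbitrary cluster labels
— the flagged state here is the cluster matching the planted
anti-brooding state.  The planted pre→post occupancy increase is
detected exactly where it was planted (MDD-active, fraction of time,
z = +3.20, FWE-p = 0.0017) and nowhere else.  The brooding–occupancy
correlation comes out negative (τ = −0.32 for fraction) but short of FDR
significance: with mean state dwell times (≈ 20 s) shorter than the 44-s
window, many windows straddle transitions, and this label noise
attenuates a planted association whose true-label τ is ≈ −0.38.  The
reproduction script computes that truth-label association directly.

The same stages are available from the shell:

```bash
dfncstates simulate --config config.yaml --out data/ --seed 1
dfncstates denoise  --in data/ --out clean/
dfncstates dfnc     --in clean/ --covariates data/cohort_metadata.tsv --out fnc/
dfncstates cluster  --in fnc/ --k-range 2:8 --replicates 500 --seed 1 --out states/
dfncstates metrics  --in states/state_sequences.tsv --out metrics.tsv
dfncstates stats    --metrics metrics.tsv --meta data/cohort_metadata.tsv --out results/
dfncstates run-all  --seed 1 --out results/
```

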