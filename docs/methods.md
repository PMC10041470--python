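# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the known limitations of the package. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## The cascade

The pipeline runs, in dependency order:

1. **Polygenic scoring.** SNPs are filtered by sample MAF (< 0.05
   removed), allele ambiguity (A/T and G/C pairs removed), greedy LD
   clumping (pairwise genotype r² > 0.10 within 500 kb; the SNP with
   the smaller GWAS p is retained) and GWAS significance (p ≤ 5e-8).
   Scores are weighted sums of effect-allele counts; the counted allele
   of each PLINK `.raw` column is resolved against the weight table and
   flipped (c → 2−c) when it is the non-effect allele. Missing
   genotypes are imputed at twice the effect-allele frequency. The AD
   weight table is split into APOE-region (chr19:44.4–46.5 Mb, closed
   interval) and no-APOE scores.
2. **Phenotype CCAs (per wave).** Adversity scales (deprivation and
   family-conflict item means; neighbourhood safety reverse-coded into
   a crime index) plus the three PRS columns against syndrome-scale
   psychopathology sums, with nuisance covariates (age, sex,
   handedness, medical problems, scanner-site dummies, task motion)
   residualised per training fold.
3. **Connectomes and multilayer communities.** Per subject, Pearson
   correlations between parcel time series per task and wave, Fisher
   z-transformed with clipping at |r| = 1 − 1e−7, negatives zeroed.
   The four layers are coupled (ω = 0.5) on the 4-cycle MID↔SST within
   wave and wave 1↔2 within task; γ = 1. The generalised Louvain
   optimiser is restarted per subject and flexibility/recruitment are
   ensemble fractions.
4. **Behavioural PLS.** Six conditions (cross-task flexibility per
   wave; MID and SST recruitment per wave), correlated with the wave-2
   risk variate on training subjects, stacked and SVD'd; test-fold
   brain scores come from training saliences. The first LV's sign is
   fixed by requiring a nonnegative salience for the first condition,
   making downstream maps deterministic.
5. **Gene PLS and stress overlap.** The brain LV parcel-salience map is
   related to the parcel × gene matrix; folds partition parcels; spin
   nulls re-run the fold-wise fit on the rotated map. The overlap test
   counts stress_high/stress_low genes among the robustly positive and
   negative genes and compares the susceptibility conjunction against
   sign-aligned null gene LVs.
6. **Receptor CCA.** Receptor maps are standardised across parcels; the
   four correlated serotonin indices (HT1a, HT2, HT4, HT6) are averaged
   into a composite with HT1b kept separate; the block is related to
   the brain LV by cross-validated CCA with spin-null significance.
7. **Moderated mediation.** Predictor: the standardised average of the
   two wave-level risk variates. Mediator: the subject-level predicted
   brain score restricted to the SST-segregation conditions (the full-
   LV alternative is a one-line change). Moderator: median split of the
   predictor (ties go to the low group). Outcome: sqrt of the wave-3
   symptom total residualised on sqrt of the wave-2 total. Moderation
   acts on the M→Y path only; HC3 covariances for coefficient tests;
   percentile bootstrap (endpoints taken as order statistics of the
   draws) for indirect effects.

## Permutation inference: why full re-fit

The natural shortcut — permuting the pooled out-of-fold variate scores
— is anticonservative for cross-validated estimates: out-of-fold
predictions share training data across folds, which inflates the null
variance of the pooled correlation by a roughly constant factor
(measured ≈ 1.65 in sd at k = 10; empirical type-I ≈ 0.15 at α = 0.05)
that does not vanish with n. All pipeline p-values therefore come from
permutations that **re-run the entire fold-wise fit** on the permuted
(or spun) data; the acceptance suite verifies this test is uniform
under the null. The pooled-variate shortcut remains available as
`cca.permutation_test` for comparison. Every permutation and spin p
uses the estimator p = (1 + #{null ≥ observed}) / (1 + N), whose floor
is 1/(N+1).

Spin nulls draw uniform rotations from normalised quaternions, rotate
left-hemisphere centroids (and the x-mirrored rotation for the right
hemisphere) and reassign values by globally greedy nearest-available
matching, so every null is a hemisphere-preserving permutation and the
identity rotation maps to the identity.

## The synthetic study

The generator's defaults define the study conditions; they are chosen
once and shared by the tests and the acceptance script.

* **Geometry.** Parcels sit on two mirrored unit hemispheres via a
  Fibonacci lattice (default 297 parcels, matching a standard cortical
  parcellation's left/right structure); networks are mirror-symmetric
  polar-angle bands (default 7) and double as the planted base
  communities.
* **Time series.** Parcel signal = sqrt(SNR) · community latent + unit
  Gaussian noise (default SNR 1, 200 timepoints). A planted fraction of
  parcels (default 0.3) follows a different community during the
  inhibition task. Subject-level risk modulates how strongly those
  parcels express the shift: the shifted-latent mixing weight is
  sigmoid(1 + 2·B_s·pattern_p), where B_s = a·(risk latent) + noise
  (default a = 0.5) and pattern_p is a smooth spatial pattern. High-risk
  subjects therefore reorganise more, and they do so along the same
  spatial pattern that carries the transcriptomic and receptor
  loadings — which is what makes the downstream stages coherent.
* **Phenotypes.** Psychopathology items (default 112 per wave, waves
  1–3) are 0/1/2 thresholded latents with marginals 0.70/0.20/0.10 and
  item loading 0.4 — a free choice of severity; real-instrument item
  distributions are not emulated. The wave-level risk latent is an
  exact linear combination of the *observed* adversity scores and the
  genotype-derived PRS columns, so the planted canonical correlation
  (default 0.5) is recoverable from the tables alone; the wave-3
  latent adds the moderated mediation paths (defaults a = 0.5,
  b_low = 0, b_high = 0.4).
* **Genotypes.** Independent SNPs at uniform MAFs (0.1–0.5), with
  planted ambiguous, low-MAF, GWAS-nonsignificant and clumping-duplicate
  SNPs so every filter fires; a share of `.raw` columns count the
  non-effect allele to exercise orientation flips. There is no
  realistic LD structure.
* **Expression and receptors.** Gene columns share an exponential
  spatial covariance exp(−d/ρ) over centroid distances (default
  ρ = 0.5); 45 "high" genes load +0.6 and 27 "low" genes −0.6 on the
  planted pattern; receptor maps load 0.6 on the same pattern with
  smooth residuals. Default 15,632 genes.

What passing tests on these data do **not** show: robustness to
haemodynamic confounds, motion artefacts, site batch effects beyond
random dummies, LD, non-Gaussian expression noise, or misregistration —
none of which the generator emulates.

## Numerical choices

* CCA is solved by whitening (Cholesky of the within-set covariances)
  and an SVD of the whitened cross-covariance; a singular covariance
  falls back to a logged 1e−8 ridge. Fold weights are sign-aligned to
  the full-sample solution; without alignment pooled variates would be
  meaningless.
* Louvain: move phase accepts the best strictly positive gain (ties
  keep the current community), sweep order is a seeded shuffle,
  convergence at ΔQ ≤ 1e−10 with a 100-outer-iteration guard.
  Interlayer edges are excluded from node strengths and layer totals
  (the null model is intra-layer) but included in 2μ.
* Fisher-z clipping at 1 − 1e−7 keeps z finite for duplicate series.
* Fold assignment is seeded and stratified by scanner site in the
  phenotype CCAs. Cross-validation requires ≥ 3 training observations
  per fold; leave-one-out is allowed.
* Bootstrap CIs are percentile; mediation endpoints use the
  closest-observation quantile so they are actual draws.
* The robust sigmoid divides by the raw IQR as printed in its defining
  formula (not IQR/1.349); zero-IQR samples are an error naming the
  sample.

## Problem sizes

Desk-scale defaults (the package's own choice for routine runs and the
acceptance script): 300 subjects, 100 parcels, 2,000 genes, 999
permutations, 199 spins, 500 bootstrap draws, 1,000 mediation
bootstraps, 5 community restarts per subject. `PipelineConfig(full=True)`
restores publication-scale counts (100,000 permutations/bootstraps,
50,000 mediation bootstraps, 100 restarts). Calibration simulations in
the acceptance suite use 199–999 permutations over 200 replicates, and
the overlap calibration uses large random gene sets so the counting
statistic is near-continuous (a valid permutation p of a small count is
too discrete for a uniformity check).

## Known limitations

* The enrichment power of the stress-overlap test against spin nulls is
  modest when the stress genes load on the same dominant spatial
  pattern as the rest of the transcriptome; at desk scale the planted
  enrichment is visible in the counts but its p-value is conservative.
* The behavioural-PLS variance-explained figure is the first LV's
  squared singular value over the sum of squares — one convention among
  several.
* The moderated-mediation mediator estimated from desk-scale brain data
  is a noisy proxy of the planted subject factor, so pipeline-level
  path estimates are attenuated relative to the direct-simulation
  recovery checks.
* Gene-PLS folds partition parcels, which are spatially dependent
  observations; the spin-based significance accounts for this, but the
  pooled r itself should be read descriptively.
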