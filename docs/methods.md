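# Methods

This note records the models, conventions and numerical choices behind
`radsurv`, and what the synthetic experiments do and do not demonstrate.

## Synthetic phantom cohorts

Each patient is a 3D phantom: three nested ellipsoids (necrosis inside an
enhancing rim inside edema) centered on the grid, with per-patient random
axis ratios (uniform 0.85–1.15, shared across subregions so nesting is
guaranteed), rendered into four modality volumes. Mean tissue intensities
follow the qualitative radiology of glioblastoma (necrosis hypointense in
T1C, hyperintense in T2/FLAIR; enhancement bright in T1C; edema bright in
T2/FLAIR). Texture is a unit-variance Gaussian random field (white noise
smoothed to a configurable correlation length, default 3 mm) scaled by a
per-modality contrast (default 12 intensity units) and added inside the
tumor; independent Gaussian noise (default SD 2) covers the whole volume.
Defaults: 48 mm³ grid at 1 mm isotropic spacing, subregion radii
6 / 11 / 16 mm.

**Planted prognostic structure.** Five standard-normal latent traits per
patient — necrosis burden, tumor volume, texture contrast, age, KPS — are
mapped *monotonically* into the rendered phantom (e.g. the necrosis latent
scales the necrosis radius by 1 + 0.35·tanh(z/1.5); the texture latent
multiplies the T1C contrast by exp(0.45 z); age = 55 + 12 z years clipped
to [18, 88]; KPS = 80 − 10 z rounded to the nearest 10 in [40, 100]).
Survival times are exponential with rate (1/s)·exp(Σ β_k z_k), baseline
scale s = 500 days (matching a mean overall survival near 500 days in
glioblastoma cohorts). Because the maps are monotone, rank statistics
(C-index) on a latent equal those on the rendered property, which is what
the recovery experiments exploit. The generator returns the latent table
on request so oracle checks can score the planted traits directly.

**Censoring.** Independent uniform censoring on [0, F]; the horizon F is
solved (Brent) so the expected censored fraction at the baseline hazard
equals the configured `censor_rate` (default 0.2). `censor_rate = 0`
disables censoring.

**Segmentation perturbation.** Repeated segmentations are emulated by
warping the label map with one smooth random displacement field
(correlation length 6 mm) scaled to a mean vector magnitude of the given
millimetres, sampled nearest-neighbor. Warping all labels with a single
field preserves nesting by construction; the same seed at different
magnitudes scales one fixed unit field, so overlap (Dice) degrades
monotonically with magnitude.

**What the phantom does not emulate**: anatomy (no brain, skull, or bias
field), inter-scanner intensity scales, non-ellipsoidal tumor shape,
infiltrative margins, or correlated multi-modality noise. Passing tests
demonstrate the *machinery* — extraction, selection, fitting, validation
discipline — recovers known planted effects; they do not certify
prognostic performance on clinical MR data.

## Preprocessing

Inputs are assumed co-registered and bias-free (bias correction, skull
stripping and registration are upstream, classical-tool territory).
Retained steps:

* **Isotropic resampling** — trilinear for scalars, nearest-neighbor for
  labels; output sample j sits at world coordinate j·target mm, so a
  volume already on target is returned unchanged. Coordinates are 0-based
  index × spacing; no orientation matrices.
* **Histogram matching** — quantile mapping onto a reference volume
  (scikit-image); a constant reference is rejected as undefined.
* **Gray-level quantization** — equal-width bins over each region's
  min–max range into 32 levels (fixed bin *count*; the discretization used
  by the original texture definitions is not documented anywhere we could
  find, and 32 equal-width bins is the common radiomics default). A
  constant region maps to level 1 by convention.

## Handcrafted features (1403)

23 geometry + 17 intensity × 20 region-modality + 52 texture × 20
= 23 + 340 + 1040. The full 1403-name catalog is frozen in code and
enforced at construction. Within the 23/340/1040 split the detailed
composition is this package's own choice: geometry is one
modality-independent set — 17 whole-tumor shape
descriptors plus necrosis/enhancement/edema volumes and volume fractions;
texture is 22 GLCM + 13 GLRLM + 12 GLSZM + 5 NGTDM per region-modality.

Texture matrices are computed in 3D at distance 1 over the 13 unique
26-neighborhood directions and **merged** (summed) across directions
before descriptor evaluation — the most common radiomics aggregation.
GLCMs are symmetrized. Run lengths use fixed-point propagation along each
direction (converges in max-run-length sweeps); zones are 26-connected
components per level; NGTDM uses the mean of in-region 26-neighbors.
Degenerate conventions, chosen so cohort extraction never aborts: no
co-occurring pairs → all GLCM descriptors 0 with a warning; zero NGTDM
difference mass (constant region) → coarseness capped at 1e6; GLCM
correlation with zero marginal variance → 0. Run percentage is normalized
per direction (runs / (voxels × directions)) so a checkerboard scores 1.
An empty subregion yields NaN features plus a warning; the pipeline
imputes 0 before z-scoring (the MAD filter removes columns that are
constant across the cohort).

## Deep features

The backbone is *injected*, not bundled: anything exposing deterministic
`F6`/`F7` activation vectors for a single-channel 224×224 [0, 255] image
satisfies the contract. The repo ships `RandomConvBackbone`, a fixed-seed
random convolutional network (7×7/stride-4 and 5×5/stride-3 ReLU
convolutions, then two fully-connected ReLU layers of configurable width;
He-scaled float32 weights drawn once from the seed; input normalization
x/255 − 0.5 on the first channel, color channels carrying zero weight).
It is a deterministic stand-in that exercises the extraction mechanics —
slice selection, patch preparation, activation harvesting, naming — at
any layer width; with width 4096 the feature count is the full 98304.
Random convolutional features are a legitimate (if weak) image embedding,
which is why planted *texture* effects remain partially visible to them.

Per modality and region (SN, SNE, ST — edema alone is not a deep-feature
input), the transverse slice with the largest region area is selected
(ties → lowest index), min-max rescaled to [0, 255] (constant slice → 0
with a warning), cropped to the region bounding box and resized to
224×224 with bicubic interpolation. Each region gets its own largest
slice (the alternative — one global tumor slice reused for all regions —
is equally defensible; per-region was chosen as the more
information-preserving reading). Neuron indices are 1-based.

## Four-step selection

Applied to z-scored features (n−1 SD; zero-variance columns flagged and
passed through as zeros; validation data always transformed with stored
discovery statistics):

1. **Robustness** — ICC(A,1) (two-way mixed effects, absolute agreement,
   single measurement: (MS_R − MS_E)/(MS_R + MS_E + (2/n)(MS_C − MS_E))),
   the standard form for segmentation-robustness studies; a feature must
   reach 0.85 in both the test-retest and the inter-rater analysis
   (default 30-patient random subsets, 1 mm perturbation magnitude).
   Zero between-patient variance defines ICC = 0 with a warning.
2. **MAD** — median absolute deviation must be nonzero.
3. **Prognostic value** — univariate Harrell C with the feature as a risk
   score, ties ½; the filter uses the direction-free max(C, 1−C) ≥ 0.580
   so protective features are retained (a literal one-sided ≥ 0.580 would
   silently discard them).
4. **Redundancy** — |Pearson r| ≥ 0.90 pairs visited in descending |r|
   (ties by name), dropping the member with the lower directional C
   (C ties resolved by name order). Deterministic by construction.

An empty survivor set at any stage short-circuits with a note in the
report rather than an exception.

## Survival modelling

* **LASSO-Cox** — `CoxnetSurvivalAnalysis` path (64 penalties,
  `alpha_min_ratio` 0.05, l1_ratio 1). The penalty minimizes the mean
  cross-validated partial-likelihood deviance in the Verweij–van
  Houwelingen form −2(pl(β; all) − pl(β; train)), which is stable for the
  small per-fold test sets that 10-fold CV produces at n ≈ 75. Folds are
  stratified by event status so no fold is event-free. Partial
  likelihoods use the Breslow tie convention; the synthetic generator
  produces continuous times, for which Breslow and Efron coincide. The
  signature keeps the LASSO coefficients at λ* directly (no refit). In
  pipeline use, if λ* zeroes every coefficient (typical on null cohorts)
  the deviance-minimal *non-empty* penalty is used with a warning so the
  downstream stages stay defined; library callers can opt out
  (`allow_empty=True` is the function default).
* **Cutpoint** — exhaustive scan of midpoints between consecutive sorted
  unique scores, standard (ρ=0) log-rank chi-square objective, both
  groups ≥ 10% of patients. This is a transparent reimplementation of
  X-tile-style optimal-cutpoint analysis; the 10% floor is our stand-in
  for that tool's internal rule. Maximally-selected statistics are biased
  optimistic on the cohort they were fit on — which is why stratification
  is always *tested* on the held-out cohort at the frozen cutoff. If the
  frozen cutoff fails to split a (small) validation cohort, validation
  reports the stratification as undefined rather than refitting.
* **Weighted log-rank** — hand-implemented G-rho family with weights
  S(t−)^ρ from the pooled left-continuous Kaplan–Meier estimate,
  hypergeometric variance, chi-square (1 df) reference; ρ=0 reduces to
  the standard log-rank (cross-checked against an independent
  implementation and lifelines in tests). ρ=1 (the default for
  stratification tests) emphasizes early differences.
* **C-index** — Harrell's C over comparable pairs (earlier time must
  carry an event; score ties ½) with a Noether-type standard error
  sqrt(C(1−C)/m) over m comparable pairs for the 95% CI. This SE is a
  large-sample approximation that ignores pair correlation; adequate for
  reporting, not for formal inference.
* **Hazard ratio / combined model** — unpenalized Cox fits (lifelines),
  Wald CIs. Constant covariates are excluded with a warning. The combined
  model (rad_score + age + KPS) is fitted on discovery and applied to
  validation through its linear predictor.

## Nomogram and calibration

Points are linear in each covariate's contribution:
points_i(x) = 100·β_i·(x_i − ref_i)/max_span with the reference at the
covariate's lowest-risk display-range end and max_span the largest
|β|·range; the largest covariate therefore spans exactly 100 points, and
total points map affinely back onto the Cox linear predictor, making
nomogram-predicted survival S_ref(t)^exp(lp − lp_ref) an *exact*
round-trip of the Cox prediction (verified to 1e-6; the sign is kept in
the points formula so the identity also holds out of display range).
Baseline survival at the reference patient comes from the fitted model's
Breslow-type baseline. Horizons are fixed at 365/730/1095 days.
Calibration groups patients into 3 predicted-probability quantile groups
(a display choice) and pairs each group's mean prediction with the
Kaplan–Meier estimate and Greenwood 95% CI at the horizon; groups with no
patient at risk through the horizon are flagged, and tied predictions
that collapse the quantiles produce a single group with a warning.

## Pipeline and reproducibility

`run_discovery` executes extract → z-score → robustness pairs → four-step
selection → LASSO-Cox → cutpoint → combined Cox → nomogram, logging
per-stage feature counts; `run_validation` applies the frozen artifacts
(discovery z-statistics, signature, cutoff, combined coefficients) with
no refitting, so no information flows from validation into the artifacts
(tested by hashing serialized artifacts before/after validation). All
randomness descends from explicit integer seeds through
`numpy.random.SeedSequence` spawning; same-seed reruns are byte-identical
down to the serialized JSON artifacts.

**Problem sizes.** The shipped experiments use a 32³ compact phantom
(subregion radii 4/7/10 mm) and a width-8 test backbone for cohort-scale
runs, which keeps a full 75/37 discovery/validation round — including the
two 30-patient re-segmentation analyses — to a couple of minutes on one
CPU while leaving every stage non-trivial (1595 features in, tens out).
The full-width (4096) configuration is exercised on single
patients for the structural counts. Statistical calibration uses 2000
null replicates at n = 60 for the weighted log-rank size and n = 500 for
the null C-index.

## Known limitations

* Random-weight deep features stand in for pre-trained transfer-learning
  features; adapters for real networks only need to satisfy the backbone
  contract, but no pre-trained weights ship with the package.
* The Noether C-index CI and the uniform-censoring generator are
  simplifications; no competing risks, time-dependent covariates, or
  elastic-net generalization.
* Geometry's marching-cubes surface slightly overestimates smooth-object
  area at coarse voxelizations (sphericity of a digital ball converges to
  1 from below as resolution grows).
* The selection thresholds (0.85 / 0.580 / 0.90) are study conventions,
  not optimized values; their interplay with cohort size is untested
  outside the n ≈ 30–400 range exercised here.
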