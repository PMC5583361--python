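# radsurv

Deep-feature and handcrafted radiomics survival modelling for
multi-modality MR tumor imaging.

`radsurv` is a tested, reusable implementation of a prognostic-imaging
workflow for glioblastoma-style studies: quantitative features are
extracted from four co-registered MR modalities (T1, T1C, T2, FLAIR) over
labeled tumor subregions (necrosis SN, enhancing rim, edema, tumor core
SNE, whole tumor ST), filtered down to a small robust set, and combined
into a sparse Cox survival signature that stratifies patients into
prognostically distinct risk groups. A synthetic phantom generator with
*planted* prognostic structure makes every stage testable end to end
without any patient data.

## The model

Per patient the pipeline extracts:

* **1403 handcrafted features** — 23 three-dimensional shape descriptors
  (volume, marching-cubes surface area, sphericity, axis lengths, subregion
  volume fractions, …) plus, for each of the 20 region x modality
  combinations, 17 first-order intensity statistics and 52 texture
  descriptors from four matrix families (22 GLCM, 13 GLRLM, 12 GLSZM,
  5 NGTDM), computed in 3D over the 13 unique 26-neighborhood directions
  on 32-level quantized gray values.
* **Deep features** from a pluggable convolutional backbone: for each
  modality and each of SN / SNE / ST, the largest-area transverse slice is
  min-max rescaled to [0, 255], cropped to the region's bounding box,
  resized to 224x224 (bicubic) and pushed through the network; the
  activation vectors of fully-connected layers F6 and F7 become named
  features (`T1C_SNE_F7_1508` = neuron 1508 of layer F7, tumor core, T1C).
  With 4096-wide layers that is 4 x 3 x 2 x 4096 = 98304 features, for
  99707 in total.

Feature selection is the four-step filter: (1) keep features with
intraclass correlation coefficient (two-way mixed, absolute agreement,
single measurement) >= 0.85 in *both* a test-retest and an inter-rater
re-segmentation analysis; (2) discard zero-MAD features; (3) keep features
with direction-free univariate concordance max(C, 1−C) >= 0.580;
(4) greedily prune feature pairs with |Pearson r| >= 0.90, keeping the
more prognostic member.

The signature is an L1-penalized Cox model over the survivors,

&nbsp;&nbsp;&nbsp;&nbsp;`rad_score(x) = Σ_k β_k x_k`,

with the penalty chosen by 10-fold cross-validated partial-likelihood
deviance (minimum criterion). Patients are split into high/low risk at
the optimal cutpoint (exhaustive log-rank scan with a minimum-group-size
constraint) fitted on the discovery cohort, tested with the G-rho
(rho = 1) weighted log-rank test, and summarized by Harrell's C-index and
the Cox hazard ratio. A combined Cox model (score + age + KPS) feeds a
points-based nomogram with 1/2/3-year calibration curves. Validation
cohorts are always scored with frozen discovery statistics — z-score
parameters, signature, cutoff — and nothing is refitted.

## Worked example

```python
from radsurv import PhantomSpec, SurvivalGenConfig, generate_cohort
from radsurv.phantom import STRONG_PLANTED_BETAS
from radsurv.pipeline import RunConfig, run_discovery, run_validation

phantom_kw = dict(grid_shape=(32, 32, 32),
                  subregion_radii={"necrosis": 4.0, "enhancement": 7.0, "edema": 10.0})
discovery = generate_cohort(75, PhantomSpec(seed=11, **phantom_kw),
                            SurvivalGenConfig(seed=12, betas=STRONG_PLANTED_BETAS))
validation = generate_cohort(37, PhantomSpec(seed=13, **phantom_kw),
                             SurvivalGenConfig(seed=14, betas=STRONG_PLANTED_BETAS))

config = RunConfig(seed=0, backbone_width=8)      # small test backbone
artifacts = run_discovery(discovery, config)
print(artifacts.signature_results.summary())
report = run_validation(validation, artifacts, config)
```

prints (abridged):

```
Radiomics signature (LASSO Cox, CV-minimum penalty)
  n = 75, events = 48
  lambda* = 0.127206, active features = 10
  discovery C-index = 0.802 (95% CI 0.785, 0.819)

  coefficients:
    T1_SNE_INT_p10                           -0.08983842
    T1C_SNE_INT_variance                     +0.48685249
    T1C_ST_GLCM_homogeneity1                 -0.14588844
    ...

stage counts: {'input': 1595, 'robustness': 197, 'mad': 197, 'cindex': 109, 'correlation': 45}
cutoff: 0.8948
validation C-index 0.756 (95% CI 0.715, 0.797)
G-rho (rho=1) log-rank p 5.44e-05; HR 9.14
combined (score+age+KPS) C-index 0.691
```

The generator planted log-hazard effects on necrosis burden, T1C texture
contrast and age; the trained signature recovers them well enough to rank
held-out survival (C = 0.756) and split the validation cohort into groups
with a nine-fold hazard ratio. The selection counts trace the four-step
filter from 1595 extracted features (1403 handcrafted + 192 from the
width-8 test backbone) down to 45 candidates.

A thin CLI wraps the same calls:

```bash
radsurv simulate --n 75 --seed 1 --out cohorts/discovery
radsurv simulate --n 37 --seed 2 --out cohorts/validation
radsurv run --discovery cohorts/discovery --validation cohorts/validation --seed 0 --out artifacts/
radsurv report --artifacts artifacts/
```

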