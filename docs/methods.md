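# Methods

This note documents the models, conventions and parameter choices behind
`radsurv`, in the spirit of a methods appendix: what is computed, under
which assumptions, and what the synthetic experiments do and do not show.

## Synthetic data model

**Phantom.** A tumor is a voxelized ellipsoid (semi-axes in mm, default
15 × 12 × 10 on a 64³ grid at 1 × 1 × 3 mm) on a uniform background
(40 HU). In-mask intensity is

```
I(x) = base + a · F(x) + ε(x),   F = unit-variance Gaussian-smoothed white noise
```

with base 100 HU, correlation length 4 mm (the Gaussian kernel scale of
the random field), heterogeneity amplitude `a` (HU) and i.i.d. Gaussian
noise ε (SD 5 HU). The field's smoothness directly modulates
co-occurrence entropy and contrast, so `a` is a controllable texture
latent. The intensity ranges are a design choice (plausible
contrast-phase CT values); nothing downstream depends on their absolute
scale because discretization is fixed-bin-count over the in-mask range.

**Second reader.** Inter-reader segmentation variability is simulated by
thresholding the mask's signed Euclidean distance map against a smooth
zero-mean random field with SD `jitter_mm` (default 1 mm), i.e. locally
correlated dilations/erosions of about that physical magnitude. At 1 mm
jitter on a 3 cm tumor the Dice overlap stays above 0.9.

**Cohort and outcomes.** Subjects draw age ~ N(53, 12.3²) years
(truncated to 18–95), AJCC stage with probabilities
(I, II, III, IV) = (0.40, 0.49, 0.08, 0.03), and heterogeneity amplitude
uniform on 4–24 HU (standardized to unit variance as the latent
`z_amplitude`). Survival times follow a Weibull-baseline proportional
hazards model, S(t|x) = exp(−(t/λ)^k · e^{β'x}) with shape k = 1.2 and
scale λ = 800 months, under administrative censoring at 120 months; the
defaults give an event fraction near 13%, typical of resected low-grade
tumor cohorts. Stage enters the linear predictor ordinally (equal
per-step log-hazard), age standardized. There is no dropout process —
censoring is purely administrative — which is sufficient to exercise the
IPCW machinery but does not probe covariate-dependent censoring.

What passing tests on these data do **not** show: robustness to scanner
effects, anatomic context, contrast-timing variation, non-ellipsoidal
shapes, or real segmentation behavior. The generator provides known
ground truth, not realism.

## Preprocessing

* Resampling to 1 × 1 × 3 mm (SimpleITK; trilinear for images,
  nearest-neighbor for masks). Physical extent is preserved to within one
  voxel.
* Discretization: fixed bin count, default Ng = 32, computed from the
  in-mask range: `level = 1 + floor(Ng (x − min)/(range + ε))` clipped to
  Ng; a constant region maps to level 1. Fixed-bin-count makes all
  texture features invariant to affine rescaling of in-mask intensities,
  which stands in for intensity normalization.
* Filters: Gaussian (default σ = 1 mm) and Laplacian-of-Gaussian
  (default σ = 2 mm), σ specified in millimetres and converted per axis
  by the spacing. The LoG uses explicitly sampled 1D kernels with the
  second-derivative kernel corrected to exact zero sum, so constants and
  linear ramps respond exactly zero; boundaries are mirror-padded.
  The filter scales are configurable; one scale per filter is the
  default.

## Feature definitions

Feature identity is `(phase, transform, family, name)`. Morphologic
features are mask-only and phase-agnostic (phase token `VOI`).

* **Morphology**: volume = voxel count × voxel volume; flatness =
  √(λ_least/λ_major) of the physical-coordinate covariance eigenvalues,
  bounded in (0, 1] (an isotropic ball gives 1, a 4:2:1 ellipsoid 0.25);
  elongation and the 4√λ axis lengths likewise.
* **First order**: moments, order statistics, energy; `robust_mad` is
  the mean absolute deviation from the mean over values inside the
  closed [10th, 90th] percentile range.
* **GLCM**: symmetric co-occurrence at Chebyshev distance 1 over the 13
  unique 3D directions, each direction's matrix normalized and the
  normalized matrices averaged. Entropies in log base 2.
* **GLSZM / GLDZM**: 26-connected equal-level zones; anisotropic spacing
  is ignored for connectivity (voxel topology). GLDZM distance is the
  Chebyshev distance to the nearest non-mask position (the grid exterior
  counts as outside; border voxels have distance 1), minimized over the
  zone.
* **NGLDM**: dependence count = number of in-mask 26-neighbors with
  exactly the same level (coarseness threshold α = 0). The matrix column
  index is `count + 1`, so inverse-moment features are defined for
  isolated voxels; all NGLDM features use that index.

All four families are verified against independent plain-loop oracles
(pair enumeration, BFS flood fill, exhaustive border search, neighbor
enumeration) to 1e-9 relative tolerance on small random VOIs.

The registry deliberately implements full standard family lists
(~480 features over two phases × three transforms) rather than any
particular historical inventory; the selection cascade is meant to face
realistic dimensionality.

## Selection cascade

1. **Reliability**: Lin's concordance correlation coefficient (population
   moments) between the two readers' feature values; features with
   CCC < 0.8 are removed (strict inequality — exactly 0.8 is retained).
   Undefined CCCs (features constant and identical across readers) carry
   no reliability information and are removed with a warning.
2. **Redundancy**: while any pairwise |r| > 0.9 remains, the worst pair
   is located and the member with the larger mean absolute correlation to
   all remaining features is dropped (ties keep the earlier column). The
   retained set has max |r| ≤ 0.9. This mean-correlation rule is the
   standard `findCorrelation`-style heuristic; the minimal-removal subset
   is NP-hard in general, but the greedy answer matches exhaustive search
   on small planted instances.
3. **LASSO-Cox**: glmnet-style L1 path (scikit-survival coxnet), penalty
   chosen by 10-fold cross-validation stratified by event status, scored
   with the Verweij–van Houwelingen partial-likelihood deviance
   −2(ll(all, β̂_k) − ll(train_k, β̂_k)) under the Breslow tie
   approximation. Default rule is deviance-minimizing λ; the 1-SE rule is
   available. Features are standardized (sample SD, ddof = 1) with the
   train parameters frozen for any held-out data.

The accounting identity `retained = total − removed_unreliable −
removed_redundant` is structural: the report computes the retained count,
it never stores it.

## Scores and Cox models

The radiomics score is a fixed linear combination of standardized
features. The published 15-term definition is shipped verbatim as a JSON
asset; fitted definitions produced by the cascade satisfy the same
contract. Cox fits use the partial likelihood with Breslow ties
(statsmodels PHReg) and carry the Breslow baseline cumulative hazard, so
absolute survival S(t|x) = exp(−H₀(t) e^{β'x}) can be predicted and new
outcomes simulated by inverting the baseline step function. The clinical
design is age (per year, linear) plus stage indicators against stage I;
indicator columns absent from a cohort are dropped with a warning. The
optimal risk cutoff at a horizon scans midpoints of sorted unique scores,
requires sensitivity and specificity both above 60%, and maximizes their
sum (ties toward the lower cutoff); subjects censored before the horizon
are excluded from the scan rather than reweighted, matching the plain
sensitivity/specificity construction.

## Evaluation

* **Harrell's C**: usable pairs per Harrell's conventions (shorter time
  has the event, or exactly one of a tied pair does); risk ties count
  0.5. CIs by subject-level percentile bootstrap (default 1000
  replicates).
* **Model comparison**: paired bootstrap of ΔC with a normal-
  approximation two-sided p-value.
* **AUC(t)**: cumulative-case/dynamic-control estimator with inverse
  probability of censoring weights from the reverse Kaplan–Meier
  censoring-distribution estimate (events and censorings swapped).
  Without censoring it reduces exactly to the Mann–Whitney AUC.
* **NRI / IDI**: category-free, at a fixed horizon (default 36 months),
  on the probability scale — each model's predicted event probability
  1 − S(t|x) comes from its own Breslow baseline. Status at the horizon
  is IPCW-weighted: events before t weigh 1/G(T−), subjects at risk past
  t weigh 1/G(t), subjects censored before t get weight 0. Percentile
  bootstrap CIs; p-values are two-sided bootstrap tail probabilities
  (resolution limited by the replicate count).
* **Calibration**: subjects binned by predicted S(t) quantiles; per bin
  the mean prediction is compared with the Kaplan–Meier estimate at t and
  its Greenwood CI; bins with nobody under observation at t merge with a
  neighbor (logged). Simulating a large cohort from a fitted model
  reproduces its own predictions within 0.05 per bin.

## Numerical choices and degenerate inputs

* Entropies: log base 2; 0·log 0 = 0.
* CCC and flatness raise on degenerate inputs (zero total variance,
  coplanar masks) rather than returning conventional fallback values.
* Cox fits raise on constant covariates, < 2 events, or non-finite
  estimates/SEs (separation).
* An empty LASSO signature (possible under a null effect) falls back to
  the densest end of the penalty path with a warning, so downstream
  stages always receive a score; under the null that score is noise, and
  held-out concordance stays at chance level.
* All randomness flows through explicit integer seeds; the pipeline
  expands one master seed into independent per-stage streams via
  `numpy.random.SeedSequence`.

## Problem sizes in the test suite

The end-to-end imaging experiment uses one cohort of 400 subjects on 64³
grids (single contrast phase, raw + LoG transforms), split 280
development / 120 held-out, with 30 development subjects segmented by the
simulated second reader; the null arm redraws outcomes on the same
extracted features, which is valid because under a zero effect outcomes
are independent of the images. The planted-signal LASSO recovery study
runs 50 seeds at n = 400 with 21 features. Calibration self-consistency
uses ~2400 simulated subjects. These sizes were chosen as the smallest
at which the Monte-Carlo error of each assertion is comfortably below
its tolerance.

## Known limitations

* Phantoms are single ellipsoids with stationary texture; no anatomy,
  no contrast kinetics, no multi-organ context.
* Only administrative censoring; IPCW correctness under informative
  censoring is untested.
* 2D (slice-wise) feature variants and wavelet transforms are out of
  scope; one filter scale per transform by default.
* The NRI/IDI p-values are bootstrap-based; very small p-values saturate
  at the bootstrap resolution.
* The published score asset maps names to this package's feature
  definitions; different discretization or aggregation conventions in
  other implementations will shift raw feature values, which is why
  scores are defined on standardized features.
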