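# radsurv

**CT-radiomics prognostic modelling for resected tumors, end to end and
fully testable on synthetic phantoms.**

Resected low-grade pancreatic neuroendocrine tumors (and many other solid
tumors) show widely varying post-surgical outcomes that anatomic staging
alone predicts poorly. Quantitative texture analysis of the preoperative
contrast-enhanced CT — *radiomics* — can capture intra-tumoral
heterogeneity that carries prognostic information. `radsurv` implements
the complete analysis pipeline for building and validating such a
prognostic signature:

1. **Synthetic cohorts** (`radsurv.synthdata`) — ellipsoidal tumor
   phantoms filled with a smoothed Gaussian random field whose amplitude
   is a known prognostic latent, boundary-jittered "second reader" masks,
   clinical covariates (age, AJCC stage I–IV), and right-censored
   Weibull–proportional-hazards outcomes. Every generator is seeded and
   exposes its ground truth, so parameter recovery is assertable.
2. **Preprocessing** (`radsurv.volume`, `radsurv.preprocess`) — NIfTI
   I/O, resampling to a uniform 1 × 1 × 3 mm grid (trilinear image /
   nearest-neighbor mask), Gaussian and Laplacian-of-Gaussian filtering
   at millimetre scales, and fixed-bin-count gray-level discretization.
3. **Features** (`radsurv.features`, `radsurv.texture`) — morphology
   (volume, flatness, …), first-order intensity statistics, and the four
   3D texture families GLCM, GLSZM, GLDZM and NGLDM following the IBSI
   reference definitions. Feature identity is
   `phase|transform|family|name`, e.g. `AP|LOG|glcm|cluster_shade`.
4. **Selection** (`radsurv.selection`) — the three-stage cascade:
   remove features with inter-reader Lin concordance correlation
   CCC < 0.8; greedily remove redundant features until all pairwise
   Pearson |r| ≤ 0.9; then LASSO-Cox with the penalty chosen by 10-fold
   cross-validated partial-likelihood deviance.
5. **Scoring** (`radsurv.scoring`) — the radiomics score
   `R = Σ_k β_k · z_k` over the selected standardized features. The
   published 15-term signature ships as a package asset
   (`published_rscore_definition()`); freshly fitted signatures satisfy
   the same contract. Cox proportional-hazards fits (Breslow ties,
   Breslow baseline hazard) build the clinical model
   (C-model: age + stage) and the combined model (CR-model: + R-score).
6. **Evaluation** (`radsurv.evaluation`) — Harrell's concordance index
   with bootstrap CIs, IPCW time-dependent ROC AUC, the category-free
   net reclassification improvement (NRI) and integrated discrimination
   improvement (IDI) at a fixed horizon under censoring, and
   Kaplan–Meier calibration in predicted-risk quantiles.

The statsmodels-style front door is `radsurv.model.ClinicalRadiomicsModel`
(`fit()` → results object with `summary()`, `evaluate()`, `simulate()`,
`plot_calibration()`); `radsurv.pipeline.run_development` /
`run_external_validation` orchestrate the whole cascade with frozen
artifacts, and the `radsurv` CLI exposes `simulate`, `preprocess`,
`extract`, `select`, `score`, `fit`, `evaluate` and `run-all`.

## Worked example

Fit the C- and CR-models on a seeded synthetic cohort of 400 subjects in
which the standardized image-heterogeneity latent (here used directly as
the radiomics score) and tumor stage both drive the hazard:

```python
import numpy as np, pandas as pd
from radsurv import CohortSpec, generate_cohort, ClinicalRadiomicsModel, EvalConfig

spec = CohortSpec(n_subjects=400, true_beta={"amplitude": 0.8, "stage": 0.5}, seed=7)
cohort = generate_cohort(spec, with_images=False)
rscore = pd.Series(cohort.latents["z_amplitude"].to_numpy(),
                   index=cohort.clinical["subject_id"], name="rscore")
results = ClinicalRadiomicsModel(cohort.clinical, rscore, cohort.survival).fit()
print(results.summary())
print(results.evaluate(config=EvalConfig(n_bootstrap=200, seed=0)).text_table())
```

prints (abridged):

```
Clinical-radiomics Cox models (Breslow ties)
n = 400, events = 64
...
CR-model  (partial log-likelihood -348.19)
              coef       se       HR  HR 95% lo  HR 95% hi        p
covariate
age         -0.015    0.011    0.985      0.964      1.008    0.201
stage_II     0.789    0.298    2.200      1.228      3.943    0.008
stage_III    1.171    0.440    3.227      1.362      7.644    0.008
stage_IV     1.287    1.041    3.624      0.471     27.890    0.216
rscore       0.960    0.148    2.611      1.953      3.491    0.000

Model performance (horizon 36 months)
Model         C-index              95% CI
R_score         0.738       (0.663-0.794)
C_model         0.607       (0.541-0.666)
CR_model        0.757       (0.693-0.808)
Delta C (CR - C): 0.150, p = 0.0001
NRI 0.754 (0.209-1.124), p = 0.0200
IDI 0.038 (0.005-0.061), p = 0.0300
```

Read: the true log-hazard coefficient on the score latent is 0.8 and the
CR-model recovers 0.96 ± 0.15 (hazard ratio 2.6 per SD); adding the score
to the clinical model raises the concordance index from 0.61 to 0.76, a
difference the paired bootstrap calls significant, with positive NRI and
IDI for 3-year outcome reclassification.

A full image-based run (phantom simulation → feature extraction →
selection → scoring → validation) is one call:

```bash
radsurv run-all --seed 1 --out run/
```

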