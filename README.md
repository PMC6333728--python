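# petrad

Radiomics survival analysis for FDG-PET tumor imaging.

Pre-therapy FDG-PET scans of non-small-cell lung cancer patients carry
prognostic information beyond stage and the routine PET variables
(SUVmax/mean/peak, MTV, TLG): the spatial texture of tracer uptake inside
the tumor predicts overall survival. `petrad` implements that pipeline as
a tested, reusable package:

* **PET IO and SUV statistics** — DICOM-series/NIfTI loading, body-weight
  SUV calibration, SUVmax/mean/peak, metabolic tumor volume (MTV) and
  total lesion glycolysis (TLG = SUVmean × MTV);
* **segmentation** — semi-automatic adaptive thresholding at 40% of the
  lesion SUVmax with stepwise lowering against a reference extent, manual
  edit hooks, and the ≥ 5 ml inclusion gate;
* **texture features** — a 665-feature 3D catalogue per gray level
  (G ∈ {4, 8, 16, 32, 64, 128, 256}): first-order, shape, fractal,
  GLCM/GLRLM/GLSZM/NGTDM matrices, with and without a one-level 3D wavelet
  transform, all matrix builders verified against brute-force oracles;
* **signature discovery** — Spearman volume-screening, L1-penalized Cox
  (LASSO) feature-vector discovery per gray level with cross-validated
  penalty selection, and the published classifier

      FVX = 0.128 · GLSZM_SzVarianc_64gl − 0.018 · NGTDM_Complex_64gl,

  shipped as `petrad/data/fvx_published.json`;
* **survival statistics** — Kaplan–Meier + log-rank, continuous and
  multivariable Cox (HR, 95% CI, Harrell's C), backward stepwise
  selection, median/Youden/optimal-log-rank dichotomisation, Schoenfeld
  power calculation, observer ICC, PCA scanner-invariance assessment;
* **synthetic data** — seeded PET phantoms with a tunable
  Gaussian-random-field texture and survival cohorts driven by planted
  feature effects, so the whole pipeline is testable without patient data.

Discovery follows the statsmodels idiom: a model object built from a
cohort whose `fit()` returns a results object with estimates, the
regularization path, the CV curve and a `summary()` table.

## Worked example

```python
import numpy as np
from petrad import *

# a ~30 ml textured phantom tumor, 4 mm voxels
vol, truth = make_phantom(PhantomSpec(seed=7))
voi = threshold_segment(vol, SegmentationParams(seed=(24, 24, 24)))
stats = compute_suv_stats(vol, voi.mask)
# SUVStats(suv_max=21.26, suv_mean=17.59, suv_peak=20.35,
#          mtv=29.504, tlg=518.98)   ... and tlg == suv_mean * mtv exactly

fsets = extract_all(vol, voi.mask)       # 7 gray levels x 665 features
row = feature_table(fsets)               # 4655 named values
score = score_fv(published_fvx(), row.to_dict())
# -89.83  = 0.128 * 1.466 - 0.018 * 5001.2

# a simulated 204-patient cohort with two planted prognostic features
cohort, _ = make_cohort(CohortSpec(seed=7))
res = lasso_cox_discover(cohort, gray_level=64, seed=7)
res.summary()
#            feature  gray_level    weight
# 0  GLSZM_SzVarianc          64  0.404555
# 1    NGTDM_Complex          64 -0.358087
# ... (plus a few small-weight noise terms at the minimum-deviance penalty)

scores = score_fv(res.fv, cohort.data)
groups = dichotomise(scores.to_numpy(), "median")
km = km_logrank(cohort, np.where(groups.high_risk, "high", "low"))
# log-rank p = 4.5e-12; median OS 47.0 months (low) vs 15.4 (high)
```

The discovered weights recover the planted signs (size-zone variance
harmful, complexity protective), and the median split separates survival
by ~32 months in this cohort — the package's own end-to-end check of the
discovery → scoring → stratification chain.

A command-line interface mirrors the library:

```sh
petrad simulate --out fixtures/ --seed 7
petrad segment  --pet fixtures/phantom.nii --seed 24,24,24 --out mask.nii
petrad suvstats --pet fixtures/phantom.nii --mask mask.nii --out stats.csv
petrad extract  --pet fixtures/phantom.nii --mask mask.nii --out features.csv
petrad discover --features fixtures/features.csv --clinical fixtures/clinical.csv --out model.json
petrad score    --model fixtures/fvx_published.json --features fixtures/features.csv --out scores.csv
petrad evaluate --scores scores.csv --clinical fixtures/clinical.csv --cutoff median --out report.json
```

## Documentation

`docs/methods.md` describes the models and every documented convention:
the SUV and SUVpeak definitions, the segmentation schedule, the exact
catalogue composition summing to 665, matrix direction handling, the
penalty-selection and dichotomisation rules, the frozen power-calculation
variant, and what the synthetic generators do and do not emulate.
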