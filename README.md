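# segqc

Automated quality control for 3D prostate segmentations on T2-weighted MRI.

Fully automated prostate segmentation (e.g. by a CNN) still needs a human to
spot the occasional badly failed contour. `segqc` replaces that visual check
with a number: a 0–100 quality score for a segmentation mask on a T2W volume.
It is aimed at researchers and engineers running automated segmentation at
scale who need a safety net that flags poor masks without a reference
contour.

## The method

Two scores are involved:

**Reference quality score (rQS)** — requires a manual reference mask.
Four segmentation metrics are computed in each of three regions (whole
gland, apex, base — the inferior and superior thirds of the
mask-containing slices):

- DSC = 2|A∩B| / (|A|+|B|)
- aRVD = |V_auto/V_ref − 1| × 100 (%)
- 95HD = max of the two directed 95th-percentile surface distances (mm)
- ASD = pooled mean of all directed surface distances (mm)

Each of the 12 metric cells is mapped to a 0–100 score by a linear function
anchored at two points: the ideal metric value maps to 100 and the mean
performance of a second observer (re-contouring a calibration cohort) maps
to 85. Cell scores are clipped to [0, 100] and averaged into the rQS.

**Estimated quality score (eQS)** — no reference mask needed. 107 radiomics
features (18 first-order, 14 shape, 75 texture: GLCM/GLRLM/GLSZM/GLDM/NGTDM,
fixed bin width 64, 13 directions at distance 1) are extracted from each of
whole/apex/base of the automated mask — 321 features per case — and fed to
a LASSO linear regression

```
min_b (1/2n) ‖rQS − Xb‖² + λ‖b‖₁ ,
```

with λ chosen by 5-fold cross-validation at the patient level, minimizing
CV-MSE subject to a Bland–Altman bias tolerance on out-of-fold predictions.
Predicted scores are clamped to [0, 100].

No external dataset is required: a phantom module generates prostate-like
ellipsoidal masks in textured volumes plus graded mask perturbations
(erosion, dilation, translation, dropped apex/base slices, leaking blobs,
boundary jitter) that span the quality range, and simulated second-observer
masks for calibration.

## Worked example

```python
import numpy as np
import segqc
from segqc.phantom import PerturbationSpec, generate_observer_cohort, perturb_mask
from segqc.metrics import metric_panel

# calibrate the metric->score maps on a synthetic second-observer cohort
cohort = generate_observer_cohort(
    50, segqc.PhantomSpec(), PerturbationSpec("boundary_jitter", 1.0), seed=1
)
panels = [metric_panel(c.observer, c.gold) for c in cohort]
calibration = segqc.fit_calibration(panels, anchor=85.0)

# score a degraded segmentation of a fresh phantom
image, gold = segqc.generate_phantom(segqc.PhantomSpec(seed=7))
auto = perturb_mask(gold, PerturbationSpec("erode", 2, seed=7))
panel = metric_panel(auto, gold)
print(round(panel.values[("whole", "DSC")], 3))       # 0.877
print(round(segqc.score_panel(panel, calibration).value, 1))  # 28.3
```

The whole-gland Dice of 0.877 looks tolerable, but the composite score of
28.3 reflects what the observer-anchored calibration knows: a 2-voxel
erosion is far outside the variation between two human observers (whose
average scores 85 by construction), and the distance metrics in the thin
apex/base regions punish it hard.

Training and applying the feature-based model end to end (here on phantom
data via the CLI):

```bash
segqc simulate data/ --n-patients 20 --seed 1
segqc calibrate calibration.json --n-cohort 50 --seed 1
segqc rqs data/ calibration.json scores.csv
segqc extract data/ features.csv
segqc train features.csv scores.csv model.json --out-folds folds.csv
segqc predict features.csv model.json predictions.csv
segqc evaluate predictions.csv scores.csv report.json --manifest data/manifest.csv
```

`report.json` contains MAE, the SD/IQR of the absolute error, Spearman's
rho, the eQS-on-rQS linear fit with its 95% prediction interval, the
Bland–Altman mean difference and the outlier case ids, pooled and per
dataset × method subgroup.

## Layout

- `segqc.phantom` — synthetic volumes, gold/observer masks, perturbations
- `segqc.imaging` — NIfTI/MetaImage I/O, preprocessing (N4, normalizers)
- `segqc.regions` — apex/middle/base slice partition
- `segqc.metrics` — DSC, aRVD, 95HD, ASD and the 12-cell panel
- `segqc.scoring` — observer-anchored calibration and the composite score
- `segqc.radiomics` — the 321-feature extractor
- `segqc.model` — `QualityRegression` / `QualityRegressionResults` (LASSO)
- `segqc.evaluation` — agreement reports and outlier flagging
- `segqc.pipeline`, `segqc.cli` — file-based pipeline stages and the CLI

See `docs/methods.md` for modelling assumptions, parameter choices and
limitations.
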