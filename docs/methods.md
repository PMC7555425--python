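# Methods

This note documents the modelling choices behind `segqc`: what each stage
computes, the conventions fixed where several were defensible, what the
synthetic phantoms do and do not emulate, and the package's limitations.

## Regions

The apex and base are defined operationally, not anatomically: with `n`
mask-containing slices (slice axis = third array axis, slice 0 inferior),
the apex is the first `floor(n/3)` of those slices and the base the last
`floor(n/3)`; remainder slices go to the middle, keeping apex and base
symmetric. A mask spanning fewer than 3 slices therefore has empty apex
and base regions; downstream code treats these as degenerate rather than
as errors.

Which mask defines the thirds depends on the consumer. The metric panel
partitions on the *reference* mask and applies that frame to both masks,
so a mis-localized automated mask is punished rather than re-framed. The
feature extractor partitions on the *automated* mask, because at
prediction time no reference exists.

## Segmentation metrics

Surfaces are sets of border voxel centres under 6-connectivity, with the
grid boundary counting as outside; distances are Euclidean, in mm, between
voxel centres. Conventions fixed here:

- **95HD**: maximum of the two directed 95th percentiles; percentiles use
  linear interpolation between order statistics.
- **ASD**: a single pooled mean over both directed distance lists, not a
  mean of the two directed means (the two differ when the surfaces have
  unequal sizes).
- **Degenerate cells**: if a region of either mask is empty, the distance
  metrics are flagged invalid; DSC (0) and aRVD (100 for an empty
  automated region) remain defined. Scoring maps invalid cells to the
  floor score 0 — the conservative choice for quality control, where an
  undetected catastrophic failure is the expensive error.
- Two empty masks have DSC 1 by convention (identity before perturbation
  bookkeeping); aRVD requires a nonempty reference.

Both distance metrics are verified against a brute-force all-pairs
implementation on random masks up to 16³ voxels (200 seeded instances,
agreement to 1e-9 mm).

## Score calibration

Each of the 12 metric cells gets a linear map to a 0–100 score fixed by
two points: the ideal value (DSC 1; aRVD, 95HD, ASD 0) maps to 100 and the
cell's mean over a second-observer cohort maps to the anchor (default 85).
Cell scores are clipped to [0, 100] *before* averaging; the order matters
and is fixed so that every cell contribution stays on the stated scale. An
exact consequence used as a system-level check: the cohort's mean
composite score under its own calibration equals the anchor whenever no
cell clips. A cohort that matches the gold standard exactly in some cell
leaves that cell's line underdetermined and is rejected.

## Radiomics features

107 features per region, 321 per case, in a frozen order (region-major:
whole, apex, base; class order first-order, shape, GLCM, GLRLM, GLSZM,
GLDM, NGTDM; alphabetical within class) because the regression stores
coefficients by position.

- **Discretization**: fixed bin width (default 64 intensity units),
  anchored at the in-mask minimum: `bin(x) = floor((x − min)/w) + 1`. Each
  region is an independent ROI and is re-discretized on its own range;
  this makes texture features invariant to global intensity shifts.
- **First order** (18): population moments; kurtosis is the raw fourth
  standardized moment (no −3 offset); zero-variance ROIs get skewness and
  kurtosis 0; entropy and uniformity use the discretized histogram.
- **Shape** (14): surface area and mesh volume from a marching-cubes
  isosurface of the binary mask at level 0.5 with physical spacing; axis
  lengths are `4·sqrt(λ)` from the sample covariance eigenvalues of the
  in-mask voxel centres; maximum diameters are the largest pairwise
  distances between mesh vertices (2D variants ignore one axis). Masks too
  small for a mesh fall back to voxel-face surface area; masks with fewer
  than two voxels get axis lengths 0.
- **Texture** (75): GLCM (24) and GLRLM (16) are built per direction along
  the 13 unique offsets of the 26-neighbourhood at distance 1, and every
  feature is the mean of its 13 per-direction values — not a feature of
  the direction-summed matrix, which is a different (and rejected)
  estimator. GLSZM (16) zones are 26-connected equal-level components and
  direction-free. GLDM (14) uses the 26-neighbourhood, distance 1,
  similarity tolerance 0; the dependence size counts the centre voxel, so
  it runs 1–27 and the small/large-dependence emphases never divide by
  zero. NGTDM (5) uses 26-neighbour means; voxels with no in-mask
  neighbour are excluded.
- **Degenerate conventions**: features of an empty texture matrix are 0;
  an empty region emits 107 zeros with a flag, so a thin mask still yields
  exactly 321 finite values.

Feature definitions follow the IBSI-style formulations popularized by the
pyradiomics extractor (v2.2 conventions), and the matrix builders are
verified exactly against brute-force enumeration on random ROIs up to 6³.

## Quality-score regression

LASSO objective `(1/2n)‖y − Xb‖² + λ‖b‖₁` (scikit-learn's coordinate
descent), predictors standardized to zero mean / unit SD on training data
(constant predictors are dropped and reported with coefficient 0),
responses left on the score scale. Predictions are clamped to [0, 100].

λ selection: grid of 100 log-spaced values from λ_max (the smallest λ
zeroing all coefficients, `max|Xᵀ(y−ȳ)|/n`) down four decades; 5-fold CV
with folds assigned at the patient level (a seeded permutation of patients
split into k groups), so all segmentations of one patient share a fold.
The "unbiased Bland–Altman distribution" requirement is automated as a
filter: eligible λ must have out-of-fold mean difference within ±1 score
point (configurable); among eligible λ the CV-MSE minimizer wins, ties
going to the larger (sparser) λ; if nothing is eligible the unconstrained
minimizer is used with a warning. The out-of-fold difference-vs-mean slope
is reported as a trend diagnostic but not used as a hard constraint.

## Evaluation

MAE, SD and IQR (linear-interpolated quartiles) of the absolute error,
Spearman's rho with average ranks, and an OLS fit of eQS on rQS (the
regression direction is a documented choice) with the standard pointwise
95% prediction interval
`ŷ ± t₀.₉₇₅,ₙ₋₂ · s · sqrt(1 + 1/n + (x−x̄)²/Sxx)`. Cases outside the band
are flagged as outliers. Subgroup reports are produced per dataset ×
method combination; combinations with fewer than 3 cases are skipped.

## Synthetic phantoms

The phantom is a voxelized ellipsoid (default radii 20×25×22 mm on a 64³
grid at 1 mm isotropic spacing — a realistic gland volume of ≈46 cm³ at a
desk-scale grid) with three intensity compartments (gland ≈180, a brighter
peripheral-zone shell ≈260 for the outer 20% of the normalized radius,
background ≈80, arbitrary units) and multiplicative Gaussian-correlated
noise (correlation length 3 voxels, SD 0.15), so texture features take
nontrivial, mask-sensitive values. Per-case anatomy varies by scaling the
radii ±10%.

Simulated observers apply boundary jitter: the mask's signed Euclidean
distance field plus a smoothed noise field scaled to the jitter magnitude
(default 1 voxel), re-thresholded at zero. At that magnitude the
observer-vs-gold whole-gland DSC sits near 0.98 — the "good second
observer" regime the 85-point anchor presumes. Automated segmenters are
emulated by four perturbation recipes (observer-like jitter,
erosion-dominated undersegmentation, dilation-dominated oversegmentation,
and a sloppy recipe mixing heavy jitter, dropped apex slices, leaking
blobs and translations) whose magnitudes are drawn per case, spanning
composite scores from ≈100 down to below 30.

What the phantoms do **not** emulate: MR physics (coil profiles, strong
bias fields), anatomical shape variation beyond ellipsoids, zonal anatomy,
inter-scanner intensity distributions, and the failure modes of real CNNs.
Passing tests therefore demonstrate the correctness and internal
consistency of the machinery — metric math, calibration identities,
feature definitions, model selection — not clinical performance on real
cohorts, which must be established per dataset and segmenter.

## Preprocessing

Bias-field correction (SimpleITK's N4, optional, off by default) and an
intensity normalizer (`none` | `zscore` over the 3-voxel-dilated mask
region | 1st/99th `percentile` rescale) run in that order; each step is
recorded in the volume's provenance. The reference-tissue normalization
used in clinical prostate pipelines is deliberately out of scope; the
normalizer slot accepts a drop-in replacement.

## Problem sizes

Defaults throughout are chosen for desk-scale reproducibility: 64³
phantoms for metric/calibration experiments (50-case cohorts run in
seconds), 40³ phantoms for feature-extraction tests (≈0.3 s per case per
region set), and n = 500 × 321 synthetic design matrices for the
regression recovery checks.

## Known limitations

- Marching-cubes diameters chamfer cube corners; maximum-diameter features
  are mesh-vertex quantities, not voxel-centre quantities (both are
  defensible; the mesh convention was chosen and is tested by bounds).
- The GLDM dependence-size convention (centre voxel included) is one of
  two in circulation; it is fixed, documented and oracle-tested.
- The Bland–Altman "trend" (difference-vs-mean slope) is reported but not
  enforced during λ selection.
- Phantom "patients" contribute one gland each; longitudinal or
  multi-sequence structure is not modelled.
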