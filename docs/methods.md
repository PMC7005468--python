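# Methods note

Conventions, models and design decisions behind the `pedmri` pipeline.
Class order throughout is (pilocytic astrocytoma, medulloblastoma,
ependymoma), default cohort sizes (22, 17, 10); pilocytic astrocytoma is
the low-grade class, the other two high-grade.

## DSC perfusion quantification

Signal is converted to a relaxation-rate change per voxel,
`dR2*(t) = -ln(S(t) / S_baseline) / TE`, with the baseline taken as the
mean signal over the pre-bolus window.  The first-pass bolus is modelled as
a gamma-variate, `C(t) = A (t - t0)^alpha exp(-(t - t0) / beta)`, whose
area has the closed form `A * beta^(alpha + 1) * Gamma(alpha + 1)`; blood
volume maps are this analytic integral, never a numerical quadrature of the
fit.

**Leakage correction (K2).**  Contrast extravasation through a disrupted
blood-brain barrier is corrected Boxerman-style: each voxel's `dR2*(t)` is
regressed on the mean curve of non-enhancing reference tissue (the brain
minus the dilated tumour ROI) and on its running time-integral; `K2` is the
negated coefficient of the integral term, and the corrected volume adds the
leaked area back, `CCBV = UCBV + K2 * double-integral of the reference
curve`.  We adopt the T1-dominant sign convention: leakage *depresses* the
apparent `dR2*` tail, and positive K2 restores it.

**Order of operations.**  K2 is estimated first (it needs only the linear
regression above), the gamma-variate is then fitted to the
*leakage-corrected* curve, CCBV is its integral, and UCBV removes the
add-back again.  Fitting the corrected curve matters: a leaky voxel's raw
curve departs from the gamma-variate shape by an amount far exceeding the
noise floor, so fit residuals would conflate extravasation with noise and
the residual-based QC below would systematically discard exactly the
tumour voxels of interest.  On the corrected curve the residual is noise
alone.  `UCBV = CCBV - K2 * double-integral` makes the two volumes agree
exactly wherever K2 = 0.

**Calibration and normalisation.**  Fitted areas are in arbitrary relaxation
units; they are calibrated to mL/100g/min by pinning the mean over
normal-appearing white matter (NAWM) to a reference of 0.1, matching the
scale on which whole-brain UCBV means of roughly 0.11-0.13 are reported for
this kind of acquisition.  All downstream maps are then NAWM-normalised
(NAWM mean = 1), so features are insensitive to the absolute reference.

**Quality control.**  A voxel survives QC iff its fit RMSE is at or below
the cohort-configurable quantile threshold (default: the 90th percentile of
in-brain RMSE) *and* both |UCBV| and |CCBV| are at most 3.0 mL/100g/min
(pre-normalisation).  Masking is bookkeeping only — values are untouched —
and therefore idempotent.

## ADC

Two-point log-linear estimate from a low/high b-value pair:
`ADC = ln(S_low / S_high) / (b_high - b_low)`, reported in units of
1e-3 mm^2/s.  Non-positive signal yields NaN (the model is undefined
there); negative estimates from noise are retained, not clipped, since
clipping would bias region means upward.

## Features

33 features per subject: {ADC, UCBV, K2, CCBV} x {tumour ROI, whole brain}
x {mean, SD, skewness, kurtosis}, plus tumour volume in cm^3.  SD is the
sample SD (ddof = 1); skewness is `m3 / m2^1.5` and kurtosis the Pearson
(non-excess) `m4 / m2^2` from direct central moments.  Perfusion features
honour the QC mask; ADC features use the map's own NaN-based validity.
Regions with fewer than 8 usable voxels make the subject's features
undefined and the subject is dropped with a warning.

## Univariate statistics

Per feature: Shapiro-Wilk on every group at alpha = 0.05 gates the omnibus
test — one-way ANOVA when all groups pass, Kruskal-Wallis otherwise (note
that under a 3-group Gaussian null the ANOVA branch is taken with
probability 0.95^3, about 86%).  Post-hoc pairwise comparisons are Tukey
HSD after ANOVA and a tie-corrected, Bonferroni-adjusted Dunn test after
Kruskal-Wallis.  Battery-wide significance is Bonferroni at alpha / 33.
Pairwise class separation is summarised by the Mann-Whitney AUC (rank
formula, ties at one half), reported as-is for the stated positive class
without folding around 0.5.

## Classification protocol

Two tasks: 3-class tumour type and the binary grade dichotomy.  Evaluation
is stratified 3-fold cross-validation with pooled test predictions;
reported metrics are BAR (balanced accuracy, %), macro F1 and macro
precision.  Per training fold, entirely inside the fold:

- optional oversampling of the ependymoma class by +100% (replication or a
  hand-rolled SMOTE: synthetic points uniform on segments to one of the
  k = min(5, n-1) nearest minority neighbours).  Test rows never pass
  through the oversampler; the driver hash-verifies them before and after.
- dimensionality reduction: either PCA (train-fitted scaler + PCA, keeping
  the smallest component count reaching 95% variance, capped at
  N_min - 1 of the smallest class) or univariate selection
  (Bonferroni-significant features ranked by max |AUC - 0.5|, falling back
  to the single best-AUC feature).
- classifiers: AdaBoost on decision stumps, random forest, RBF-SVM, kNN
  with `k = round(sqrt(n_train))`, and a single-hidden-layer MLP.
  Features are z-scored (train statistics) for the scale-sensitive
  classifiers.  Small hyperparameter grids are tuned by inner stratified-CV
  macro one-vs-rest AUC.

## Synthetic phantoms

Two levels of synthesis serve different purposes:

- **Image-level** (`generate_cohort`): an ellipsoidal brain on a small
  grid, a spherical tumour ROI sized from the class-conditional volume
  distribution, a NAWM sphere, voxel-wise DSC time series from the
  gamma-variate forward model (with per-subject tumour K2 and the
  T1-dominant leakage term) and mono-exponential DWI.  Voxel noise is
  gamma-skewed and empirically re-centred so each subject's ROI mean equals
  its drawn class target; with noise off, the full pipeline inverts the
  generator essentially exactly, which is what the acceptance suite
  checks.
- **Feature-level** (`sample_feature_table`): direct class-conditional
  Gaussian draws of all 33 features.  This is the fast path for
  experiments needing many cohort realisations (statistical calibration,
  the 25-seed classifier-ordering check), where voxel-wise simulation
  would dominate runtime without adding information.

## I/O and reproducibility

Volumes travel as NIfTI (.nii.gz), tables as CSV, reports as JSON, configs
as YAML.  Every artefact carries the cohort-config hash and seed (NIfTI
`descrip` or a `.meta.json` sidecar).  All randomness flows from the
configured seeds; re-running any stage reproduces its outputs
byte-for-byte.
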