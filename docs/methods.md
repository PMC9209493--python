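# Methods

This note documents the models, conventions and numerical choices behind
`apvpipe`, and what the synthetic-phantom test machinery does and does not
demonstrate.

## Image model and grid conventions

A `Volume` is a 3D intensity grid with per-axis voxel spacing (mm) and an
origin; a `LabelMap` is an aligned integer grid in which 0 is background
and every nonzero id must appear in the `RegionTable`.  Images are
reoriented to canonical (RAS) axis order on read, so all downstream
geometry uses one internal convention with 0-based voxel indices.

All feature extraction assumes an isotropic grid.  `resample_isotropic`
(default target 1 mm, configurable) interpolates intensities trilinearly
and labels by nearest neighbour — the standard pairing that cannot invent
label ids.  The interpolation scheme is a package decision; it is exposed
in the run configuration rather than buried.

The shipped 115-region table (45 white-matter + 70 cortical entries,
FreeSurfer-style names) is a default naming convention for consumers of
recon-all-like parcellations; any table with the same columns can be
substituted.  Segmentation itself (FreeSurfer recon-all) is out of scope:
the package consumes precomputed label maps.

## The feature catalogue

The default catalogue totals exactly

    8 shape + 9 channels × (18 first-order + 22 GLCM + 11 GLRLM
                            + 11 GLSZM + 5 NGTDM + 5 NGLDM)
      = 8 + 9 × 72 = 656 features per region,

i.e. 29,520 per subject on a 45-region mask.  The 9 channels are the
original volume plus the 8 sub-bands (LLL…HHH) of a one-level separable 3D
stationary (undecimated) wavelet transform.  Choices that the catalogue
pins down, all serialized alongside fitted models (with a content hash):

* **Wavelet family**: `coif1`, applied by 1D convolution along each axis
  with symmetric (reflect) boundary padding.  Channel labels read
  axis-by-axis, e.g. LHL = low-pass along axis 0, high-pass along axis 1,
  low-pass along axis 2.
* **Discretization**: 32 equal-width bins over the region's own [min, max]
  (half-open bins, last closed; a constant region collapses to one level).
  Relative min–max binning makes every histogram/texture feature invariant
  to adding a constant to the image.  The bin count bounds all texture
  matrices at 32×· and keeps small-region statistics stable.
* **Texture geometry**: GLCM at distance 1 over the 13 unique 3D
  directions, each direction's matrix symmetrized and normalized before
  direction-averaging; GLRLM run counts averaged over the same 13
  directions; GLSZM zones 26-connected; NGTDM/NGLDM use the 26-voxel
  neighbourhood with only in-region neighbours counted, NGLDM with
  dependence tolerance α = 0.
* **Shape** is computed on the original channel only (wavelet filtering of
  a binary mask is not meaningful): volume, voxel count, exposed-face
  surface area, sphericity π^⅓(6V)^⅔/A, compactness V/(√π·A^{3/2}),
  maximum 3D diameter (convex-hull accelerated), and PCA-based elongation
  and flatness.  A box-counting fractal dimension is available as an
  optional shape-family feature (least-squares slope of log N vs log 1/s
  over dyadic box sizes); it is undefined (NaN-masked) below 2 voxels.
* **First-order** moments use the population (1/n) convention; kurtosis is
  non-excess (normal ≈ 3); entropy (bits) and uniformity are computed on
  the discretized levels.

Degenerate denominators in texture formulas are ε-guarded and flagged
rather than raised; NGTDM coarseness, defined as 1/Σpᵢsᵢ, is capped at
10⁶ on constant regions.  Regions with fewer than 27 voxels (including
absent regions) are fully masked — texture statistics on tiny supports are
noise.  Masked values standardize to 0 (the training mean), the neutral
value under a z-scored linear model.

Feature columns are named `region__channel__family__name` in a
deterministic order (regions in table order, features in catalogue order).

## Screening

Features are z-scored with training-split means and sample (n−1) standard
deviations; zero-variance features are flagged and map to 0.  The
univariate screen is a two-sided Mann–Whitney rank-sum test per feature
(robust to the heavy skew of radiomic features; Welch's t is available),
exact for group sizes ≤ 8 without ties and a tie-corrected normal
approximation otherwise.  The continuity-corrected approximation tracks
the exact null to within 0.011 at n₁ = n₂ = 8 (exhaustive worst case over
all U, attained near p ≈ 0.44); agreement is far tighter at small p where
screening decisions happen.  Selection is Benjamini–Hochberg with strict
q < 0.05 ("FDR < 5%").  Screening is computed on each stage's own training
contrast.  Clinical scores and age bypass the screen and are offered to
the LASSO directly; the LASSO is free to give them zero weight.

## The two-stage LASSO and ApV

Each stage fits an L1-penalized model over a geometric λ grid running from
λ_max (the smallest λ with all-zero coefficients, max|Xᵀ(y−ȳ)|/n) down
three decades (40 points).  The default family is binomial (logistic) with
the cross-validated deviance as the selection loss; a gaussian/MSE variant
is available by configuration.  Folds are stratified by class, shuffled
reproducibly from the seed; the chosen λ minimizes the CV loss with ties
resolved toward the sparser (larger) λ.  The final model is refit on the
full training split at the chosen λ.  The implementation maps
λ to scikit-learn's liblinear parameterization (C = 1/(nλ)) with a fixed
solver seed, so refits are bit-reproducible; on orthonormal designs the
gaussian path reduces to the soft-threshold closed form, which the tests
assert.

The ApV score is the linear predictor (not a probability).  Orientation is
fixed so the disease class has the higher mean training score.  The
operating threshold maximizes the Youden index on the training ROC, ties
broken toward the smaller threshold.  The cascade routes subjects with
ApV₁ below threshold to nADrp; the rest are split by ApV₂ into MCI_AD and
AD.  Stage 2 is trained on true MCI_AD/AD labels; routing only happens at
deployment.  A stratified 70/30 train/validation split utility is
provided.

The subset-robustness analysis re-scores the evaluation split with the
fitted weights restricted to: all selected features (Ftot), the top-4 by
|weight| (Ftest4, ties broken by feature name), every 3-subset
(Ftest3-p1..p4) and every 2-subset (Ftest2-p5..p10) of the top-4 — 12 rows
— re-deriving each subset's threshold by the Youden rule on the evaluation
split.

## Diagnostics

The positive-call convention is score ≥ threshold (ties positive); it must
be fixed for reproducible confusion counts.  The ROC sweeps the unique
observed scores; its trapezoid AUC equals the Mann–Whitney U statistic
over n₁n₀ with tie midranks (all-tied scores give 0.5).  For hold-out
operating points where only sensitivity and specificity are available, the
single-point AUC convention (sens+spec)/2 is provided; it equals the
trapezoid AUC of the one-threshold ROC.  Any metric whose defining ratio
divides by zero is reported as a typed NA (exported as the literal "NA"),
never an exception.  Repeatability uses ICC(1,1) — the one-way
random-effects, absolute-agreement, single-measurement form,
(MSB−MSW)/(MSB+(k−1)MSW) — and Bland–Altman bias ± 1.96·sd limits.

## The phantom generator

`make_cohort` produces labelled cohorts from a `PhantomSpec`: a central
"brain" ellipsoid tiled into connected regions by a seeded Voronoi
partition (region seed points fixed by the geometry seed so the region
vocabulary is cohort-wide; a 0.5-voxel per-subject jitter varies the
boundaries).  Group effects are planted per region:

* **atrophy** — morphological inward erosion (deepest-voxel retention via
  the distance transform) to a target volume fraction, eroded voxels
  becoming background, mimicking boundary shrinkage;
* **intensity** — a mean shift in units of the global noise sd;
* **texture** — a stationary Gaussian random field obtained by smoothing
  white noise with a Gaussian kernel whose sd is the stated correlation
  length, normalized to unit variance, scaled by the noise sd.

White noise (sd 1, base intensity 10) is added everywhere.  Generation is
bit-reproducible from (spec, seed); per-subject seeds derive from the
cohort seed.

The canonical strong-signal study conditions (`study_spec`) are: 64³ grid,
8 regions, 3 signal regions, AD at full strength (intensity shift 1.0
noise-sd, volume scale 0.7, texture correlation length 1.5 voxels) and
MCI_AD at half strength — a prodromal-to-late severity gradient; cohorts
of 60 subjects per group (CN, MCI_AD, AD).  The null spec plants nothing
and is evaluated at 30/group on a 48³ grid.  The recovery experiments use
the original-channel catalogue (80 features per region): the planted
signal is intensity/shape/texture on the native image, so the wavelet
channels add computation without changing what the experiment
demonstrates; the full 656-feature catalogue is exercised by the
45-region extraction check.

What the phantoms do **not** emulate: anatomy, MR physics (bias fields,
k-space artefacts), inter-scanner and field-strength effects, partial
voluming, or correlated multi-region disease gradients.  Passing the
recovery tests shows the pipeline detects and localizes planted
volumetric/intensity/texture group differences at realistic sample sizes
— not that it reproduces clinical accuracy on real cohorts, which require
access-restricted data.

## Known limitations

* The catalogue's exact membership (which 22 GLCM scalars, which wavelet
  family, which discretization) is a set of package conventions pinned by
  construction to the 656 total; alternative catalogues are first-class —
  fully configurable and serialized (with a content hash) alongside any
  fitted model.
* Binomial-vs-gaussian loss for the published fits is ambiguous in the
  source material ("mean squared error" vs "deviance"); the default
  follows the deviance reading, the alternative is one configuration flag
  away.
* Confidence intervals for AUC/ICC and DeLong comparisons are not
  implemented.
* Thresholds re-derived by the Youden rule are training-set optimal and
  optimistic on small validation splits, as usual.
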