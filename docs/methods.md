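# Methods

`halophen` implements an image-based, non-destructive phenotyping pipeline for
succulent halophytes grown along a salinity gradient, together with the
statistical layer that turns per-plant traits into a salinity-tolerance
classification and into biomass / substrate-salinity predictions. This note
documents the models, the defaults, the numerical choices, and what the
synthetic generators do and do not emulate.

## Colorimetry

Device RGB is decoded with the standard sRGB transfer function and converted
to CIELab under illuminant D65 (2° observer), via scikit-image. On the mean
Lab colour of the plant pixels the package computes

* chroma `S* = sqrt(a*² + b*²)`,
* hue angle `Hue = atan2(b*, a*)`, reported in degrees on [0, 360). The
  quadrant-aware arctangent matters: green foliage has a* < 0, b* > 0 and
  sits near 120°; a naive `atan(b/a)` would report −60°.
* colour differences `ΔE = sqrt(ΔL*² + Δa*² + Δb*²)`. ΔE1 is measured
  against a white standard, taken as perfect diffuse white L* = 100,
  a* = b* = 0 (the conventional reference when no chart white is supplied;
  it is a `RunConfig` field and can be replaced by a measured white). ΔE2 is
  measured against the mean colour of the plants grown without salt (NO-S),
  computed per population from the data at hand rather than shipped as a
  constant, since the no-salt baseline is a property of each cohort.

Colour-feature summaries are computed from the *mean* L*, a*, b* over the
mask (not per-pixel and then averaged); S*, Hue, ΔE1, ΔE2 are derived from
those means, so the invariant `S*² = a*² + b*²` holds exactly on the
reported numbers.

Camera correction is an affine map (3×3 matrix + offset) from device RGB to
reference RGB, fitted by least squares on the 24 patches of a colour-checker
chart, in *linearized* sRGB. Affine is the simplest family that contains the
identity and absorbs exposure/black-level offsets; fitting in linear RGB
keeps the model physically sensible. Rank-deficient patch sets (fewer than 4
independent colours) are rejected. The fitted residual (RMS patch error in
linear units) is reported and can only be at or below the uncorrected error
on the training patches.

## Morphometry

Segmentation is a grayscale band threshold, inclusive on both ends
(default [135, 240], the band appropriate to the photographic light-box
setup; it is a config parameter because any change of background or
exposure moves it). Post-processing fills holes and drops 8-connected
components smaller than 0.5 % of the largest, which reproduces a cropped
single-plant silhouette without manual editing. An all-background image
yields an explicit empty mask rather than an error.

On the mask (pixel scale in mm/pixel, default 0.1):

* **PA / CPA** (cm²) — foreground pixel count × pixel area. Hole-filled
  foreground is used, i.e. pixels enclosed by the plant's perimeter count.
* **Ht** (cm) — vertical extent (base = largest row index, apex = smallest).
* **Sd** (cm) — per-row maximum run length of the largest component within
  the 45–55 % band of its vertical extent, summarized by the median. The
  band pins the measurement to the middle segment of the primary shoot;
  the median makes it robust to a branch clipping the band edge.
* **FD** — box-counting fractal dimension. The mask is cropped to its
  bounding box and covered with boxes of side 2, 4, 8, … up to ¼ of the
  longer side (at least 3 sizes required). For each size the occupied-box
  count is taken as the geometric mean over grids anchored at the four
  bounding-box corners, and FD is the least-squares slope of log N(s)
  against log (1/s). The four-corner construction was chosen because the
  corner set is permuted by translations, 90° rotations and flips, making
  FD *exactly* invariant under those symmetries, while grid-aligned
  phantoms keep their analytic values (filled square 2.0, one-pixel line
  1.0, Sierpinski triangle log 3/log 2 ≈ 1.585); a single-origin grid was
  measured to drift by up to ±0.03 under rotation on realistic silhouettes.

Stem anatomy: a labelled cross-section (palette 0 background, 1 epidermis,
2 palisade, 3 water-storage parenchyma, 4 vascular + sclerenchyma, 5 pith)
is summarized as per-tissue pixel percentages (summing to 100) and an
equivalent-circle section diameter. Tissue recognition itself is out of
scope; input is a labelled mask.

## Statistics layer

* **Pearson matrices** with two-sided p-values from the t distribution on
  n − 2 degrees of freedom, significance flagged at α = 0.05, no
  multiple-testing correction (deliberately, matching common practice for
  descriptive trait matrices). Zero-variance columns are rejected.
* **PCA** on the correlation matrix of standardized variables. Reported
  quantities: eigenvalues (summing to the number of variables), percent
  variance (100·λ/p), factor loadings (eigenvector·√λ, so `L Lᵀ` rebuilds
  the correlation matrix) and variable contributions (100·loading²/λ, each
  component column summing to 100). Eigenvector signs are fixed so the
  largest-magnitude loading of each component is positive.
* **Discriminant classification** ("MDA") is canonical linear discriminant
  analysis with pooled within-class covariance and priors proportional to
  class sizes — the design is unbalanced (24/48/12/12 for NOS/OS/CSS/ISS).
  Classes follow the salinity/tolerance scheme: NOS = 0 mM, OS = 200 +
  400 mM (both populations), CSS/ISS = 1000 mM in the lower-/higher-
  tolerant population. A singular pooled covariance is ridge-regularized
  by 1e-6·trace(Σ)/p with a warning. Cross-validation is leave-one-out;
  reported percentages are rounded half-up to 2 decimals. sklearn's LDA is
  used only as an independent cross-check in the tests; the classifier
  here is self-contained so its covariance, priors and ridge behaviour are
  exactly as documented.
* **Regression**: OLS through statsmodels (coefficients, two-sided t-based
  p-values, R²); polynomial biomass–area calibrations of degree 1 or 2
  via least squares. The published fixed equations (projected-area model;
  substrate-salinity models per population; biomass calibrations per
  population) live in `halophen.published` as versioned constants —
  predictions from them are exact evaluations, never re-fits, and
  substrate-salinity predictions outside [0, 1000] mM are flagged invalid
  rather than clipped. Units throughout: PA cm², Sd cm, Ht cm, Sal.s. mM,
  ΔE1 dimensionless — the only scaling under which the printed
  coefficients have commensurate magnitudes.

## Synthetic data

The generators define the study conditions the tests run under.

* **Feature tables** use the 2-population × 4-treatment factorial with 12
  replicates per cell (96 plants) and a 3-replicate validation layout (24
  plants). Group trait means are mid-points of the reported ranges: L*
  rising with salinity (more steeply in the lower-tolerant population),
  a* falling (−6 → −10 lower; −6 → −7 higher), b* rising to ~19 at severe
  salinity for the lower population and flat ~10.5 for the higher, shoot
  diameters 0.20–0.35 cm, and a severe-salinity collapse of area/height in
  the lower-tolerant population only. Traits are drawn from independent
  per-group Gaussians; S*, Hue, ΔE1, ΔE2 are derived from the drawn Lab so
  the colour identities hold row-wise. Optional destructive covariates
  (FW, DW via the published calibrations plus noise; ACS tracking Sd;
  proline, H₂O₂ and pigments as simple monotone salinity trends) are
  plausibility-level approximations only.
* **Rendered plants** are recursive branched-segment silhouettes (main
  shoot + secondary shoots at ~35°, thinning by 0.6 per order) rasterized
  at a stated mm/pixel on a light background, coloured per segment in Lab
  around the group mean and converted to sRGB. Branch tips are kept below
  the apex so silhouette height equals the stem length, and enclosed
  pockets between crossing shoots are painted as fleshy overlap so the
  silhouette is hole-free — keeping the rasterizer's ground truth (area,
  height, stem diameter, mean Lab before 8-bit quantization) consistent
  with what the measurement pipeline defines. The rendered foliage is
  darker than the photographic setup the default threshold band targets,
  so closure tests pass a band bracketing the rendering; the band is an
  explicit segmentation parameter either way.
* **Model datasets** draw predictors uniformly from stated ranges (discrete
  sets for the salinity levels) and add Gaussian noise to the fixed-model
  response.
* **Cross-section phantoms** are concentric annuli sized so class pixel
  shares match requested proportions (within ~0.5 points at the default
  200 px radius).

What the generators do *not* emulate: illumination gradients and shadows,
specular highlights, soil/pot pixels, camera noise and chromatic
aberration, overlapping neighbour plants, or correlated trait structure
beyond the group means. Passing closure and classification tests on this
material therefore demonstrates correctness of the measurement and
statistics code, not field robustness of segmentation on real photographs.

## Problem sizes and determinism

Coefficient-recovery runs use n = 400 rows (published linear models, noise
sd 1 mM-scale 5) and n = 200 pairs (biomass calibrations, noise sd
0.5/0.05 g); at those sizes the recovered leading coefficients have
standard errors of roughly 0.1 % and 1 % of their values respectively.
Because the calibration standard error is ~1 %, single-draw estimates
scatter at that scale, and the test suite checks calibration recovery on
an estimate averaged over 9 replicate datasets at the same conditions.
Every generator takes a single integer seed and is bit-reproducible; no
global random state is used. Pipeline outputs (CSV) embed the software
version and the SHA-256 of the run configuration, and reruns are
byte-identical.

## Known limitations

* Segmentation is a fixed global band; it has no robustness to uneven
  illumination (the intended capture setup is a light box).
* Shoot diameter assumes a single dominant, roughly vertical primary shoot
  crossing mid-height; prostrate or multi-stem habits would need a
  different estimator.
* The affine colour correction cannot capture strongly non-linear camera
  response; it presumes a roughly calibrated camera.
* The fixed published models are used as printed, without uncertainty
  intervals (no coefficient covariance is published).
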