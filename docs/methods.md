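# Methods

This note documents the models, numerical choices and limitations behind
`rnfltex`.  It is the package's own account of its science; every number
quoted here is computed by the code or its tests.

## The analysis model

The working hypothesis is that the visual appearance of the retinal nerve
fiber layer in a fundus photograph carries quantitative information about
its thickness: thicker fiber bundles reflect more light in the green–blue
band and show a more organized striation, so local mean intensity, local
standard deviation and the shape of the local intensity histogram should
all co-vary with OCT-measured thickness.  The package operationalizes this
as (i) rank correlations between first-order histogram features and
thickness, and (ii) a second-order polynomial regression

y = β₁ + β₂µ_GB + β₃σ_GB + β₄µ_GB·σ_GB + β₅µ_GB² + β₆σ_GB²

predicting thickness y (µm) from the GB-channel ROI mean and standard
deviation.  First-order features are used deliberately: they depend only on
individual pixel values, which keeps their physical interpretation direct
(µ — reflected intensity; σ — striation contrast; E — histogram shape) at
the cost of ignoring spatial arrangement.

### Assumptions

* **Linear intensities.** Pixel values are proportional to reflected
  light.  Gamma-compressed images change every feature's relation to
  thickness, so `make_channels` refuses nonlinear input unless explicitly
  overridden (`allow_nonlinear=True`).  Decoding camera RAW files into
  linear rasters is upstream of this package.
* **Vessel-free ROIs.** Blood vessels are dark, high-contrast structures
  unrelated to RNFL texture; any ROI window containing a masked vessel
  pixel is rejected.
* **Axis-aligned B-scans.** OCT B-scan columns are assumed to coincide
  with SLO columns; only the row position varies between scans.  Oblique
  scan patterns are out of scope.
* **Samples treated as independent.** ROIs from one eye are statistically
  dependent in reality; pooled statistics treat them as independent
  samples of retinal positions, and the per-eye analyses exist precisely
  to expose the difference.

## Parameters that matter

| parameter | default | units | role |
|---|---|---|---|
| CLAHE tile | 20 | px | locality of contrast normalization; not critical |
| CLAHE clip limit | 0.01 | fraction of tile count | caps noise amplification |
| fundus ROI (fROI) | 41 × 41 | px | texture window; compromise between statistics and vessel avoidance |
| histogram bins | 256 | — | gray-level resolution of H(g); entropy scales with it, so fix it per study |
| thickness window (tROI) | 7 × 7 | px | local thickness estimate on the SLO grid |
| interpolation | bilinear | — | across B-scan rows; spline available |
| axial scale | 3.87 | µm/px | OCT depth pitch; must be supplied for real volumes |
| transform kind | quadratic | — | 12-parameter polynomial; affine available for comparison |
| normalization | z-score | — | predictor scaling before the regression fit |

The CLAHE clip limit and the histogram bin count have no canonical
published value for this analysis; both are configuration parameters with
the defaults above.

## First-order features

Features are moments/functionals of the probability histogram
H(g) = n_g / N over `n_bins` gray levels.  Intensities are uniformly
quantized by nearest level over a value range (by default the block's own
min–max; the pipeline uses the channel's full bit-depth range), so integer
data on [0, n_bins − 1] is tallied exactly.  Conventions:

* σ is the **square root** of the second central moment, so it is a true
  standard deviation in intensity units.
* Kurtosis is **excess** kurtosis µ₄/µ₂² − 3 (Gaussian → 0).  One
  published rendering of this formula places the −3 inside the
  denominator, which is dimensionally inconsistent for a shape
  descriptor; the standard definition is implemented.
* 0·log₂0 ≡ 0 in the entropy sum; constant blocks get σ = 0, E = 0 and
  NaN-flagged skewness/kurtosis (undefined, never an exception).

Note that a *flatter* histogram has *higher* Shannon entropy under this
definition; entropy rises with thickness in practice because striation
widens the histogram's support, not because it sharpens peaks.

## Registration

Both coordinate rows of the quadratic transform share the monomial design
[x², xy, y², x, y, 1], so the landmark fit is linear least squares; it is
solved by `numpy.linalg.lstsq` (QR/SVD) rather than by forming normal
equations — the same minimizer with better conditioning (the tests verify
agreement with an explicit normal-equations solve to 1e-8).  Six landmark
pairs determine the 12 parameters; twelve are the protocol default.
Rank-deficient configurations (e.g. collinear landmarks) raise a
`SingularLandmarkError` naming the deficiency.

Warping needs the inverse map, which has no closed form; it is computed
per point by Newton iteration on the 2 × 2 Jacobian, seeded with the
inverse of the affine part, tolerance 1e-6 px, with non-converged or
out-of-raster pixels flagged invalid rather than zero-filled.  Coordinates
are 0-based, (x, y) = (col, row), pixel centers at integers.  The SLO is
the floating image and the fundus GB the reference by default; both
directions work.  Thickness is always *sampled* in the SLO frame (the
fROI center is mapped through the inverse transform); warping the
interpolated thickness map into the fundus frame is for visualization
only, to avoid interpolating an interpolation.

## Thickness maps

Per-scan thickness is (ONFL − ILM) × axial scale, validated to be
nonnegative column by column.  The dense map interpolates column-wise
across scan rows; both methods are exact at the scan rows, and the linear
method is bounded by the input profiles.  Rows outside the scanned band
and a configurable optic-disc circle are masked invalid; `sample_troi`
refuses windows touching invalid pixels and names the cause.  The linear
interpolation error between rows is bounded by h²/8·max|∂²T/∂row²| (h =
scan spacing); the round-trip tests compute this bound from the generated
field itself instead of asserting a fixed tolerance.

## Regression and error analysis

The quadratic model is linear in β, so the default fit is an exact OLS
solve (statsmodels); an iterative Levenberg–Marquardt option mirrors
nonlinear-regression workflows and reaches the identical optimum (tested
to 1e-7).  Predictors are z-scored by default (min–max and none
available); the constants are stored in the fitted estimator so prediction
and serialization round-trip.  Diagnostics: MAE in µm; MCI as the mean
half-width of the 95 % confidence interval of the *mean response*
(prediction-interval variant selectable); R² from the OLS fit.  Per-eye
error is the median over ROIs of |ŷ − y|/y, summarized across eyes by mean
and SD; rows with y = 0 are excluded with a warning.  Spearman p-values
use the large-sample approximation with midrank ties and are reported
raw — no multiple-testing correction, so interpret borderline values
accordingly.

## The synthetic scene generator

`generate_scene` builds, from one seeded `numpy` generator, a co-registered
eye with full ground truth:

* **Thickness field**: smooth analytic surface around a synthetic optic
  disc — peak near twice the disc radius, superior/inferior angular
  lobes (sin²θ), decaying peripherally — spanning 20–180 µm by default,
  the physiological peripapillary range.
* **Fundus channels**: G and B follow baseline + effect_mean·T̃ +
  effect_contrast·T̃·stripe + Gaussian noise (clipped to range), where T̃
  is normalized thickness and the stripe is an oriented sinusoid fanning
  radially around the disc like fiber-bundle striation (integer angular
  harmonic, so the pattern closes smoothly).  R carries a fivefold-weaker
  mean effect, near-zero stripe contrast and strong low-frequency
  "reflection" blobs, emulating deep-layer reflections that spoil the red
  channel; this is what makes GB features outrank R features in the
  cohort tests.  The optic disc itself is not rendered — ROI placement
  avoids it geometrically.
* **Vessels**: dark curvilinear arcades stamped from parametric curves,
  smoothed into a soft profile that darkens all channels and thresholded
  into the exclusion mask used for ROI placement.
* **SLO + warp**: a known quadratic SLO→fundus warp (similarity part
  placing the 30° SLO footprint on the central ⅔ of the 45° fundus, plus
  a few px of quadratic distortion, small enough to stay invertible);
  each SLO pixel evaluates the fundus-frame fields at its warped
  position.  Landmarks are a quasi-uniform grid mapped through the true
  warp, optionally jittered.
* **B-scans**: 61 (up to 121) evenly spaced rows; ILM is a smooth
  baseline and ONFL = ILM + T/axial-scale, so reconstruction is exact at
  scan rows by construction.

Default geometry is desk-scale — 480 × 480 fundus, 320 × 320 SLO, 15-eye
cohorts with ~20 ROIs per eye (~300 paired samples); the tests use
288 × 288 scenes.  These sizes preserve the 45°/30° field-of-view ratio
and the B-scan sampling density of a clinical protocol while keeping the
full cohort analysis under a few seconds.  The fundus pixel pitch in µm is
deliberately a free parameter (`slo_pixel_pitch_um` for the SLO side):
published protocols specify fields of view, not pitches.

**What passing tests do and do not show.**  The generator produces an
idealized monotone texture–thickness link with modest noise; pipeline
correlations near 0.95 and within-eye errors near 2 % demonstrate that the
*machinery* is correct (features measure what they claim, registration and
sampling pair the right locations, the model recovers planted
coefficients), not that real fundus photographs support such strength.
Real data adds media opacity, illumination gradients beyond CLAHE's reach,
anatomical texture unrelated to the RNFL, segmentation error and
between-subject variability; published correlations on clinical datasets
sit near 0.5–0.7 pooled, with within-eye median errors around 17 %.  The
generator makes no attempt at photorealism, optical modeling or RAW
sensor simulation.

## Numerical details and degenerate inputs

* CLAHE preserves the input intensity range (internally rescaled to
  [0, 1] for `skimage.exposure.equalize_adapthist`); constant images pass
  through unchanged; partial border tiles use the library's reflective
  padding.
* GB is kept in floating point after averaging — no requantization before
  feature extraction.
* Scene seeds in batch runs are `seed + eye_index`; a fixed pipeline
  config reruns byte-identically (reports contain a config hash and no
  timestamps).
* `interpolate_map` requires ≥ 2 scans and strictly increasing rows;
  spline output is clipped at 0 µm (natural cubic splines can undershoot
  between rows).
* Ties in Spearman inputs are handled by midranks; per-eye sets below 5
  ROIs are skipped and reported, pooled analyses require ≥ 10 rows.

## Known limitations

* ILM/ONFL segmentation is consumed, not performed; segmentation error
  propagates directly into the thickness ground truth.
* ROI centers are an input (manual in clinical practice); the annulus
  helper proposes vessel-free centers but does not mimic a grader's
  anatomical judgment.
* The regression uses the fixed (µ_GB, σ_GB) predictor pair; no feature
  selection, and no glaucoma classification — the package studies normal
  anatomy's texture–thickness link only.
* Published β coefficients can be wired into `RnflRegressor` for checks,
  but without the original normalization constants they only make
  predictions at the normalized origin meaningful.
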