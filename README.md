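# rnfltex

Texture analysis of the **retinal nerve fiber layer (RNFL)** in color fundus
photographs, and its quantitative relation to RNFL thickness measured by
optical coherence tomography (OCT).

The RNFL — the layer of ganglion-cell axons converging on the optic disc —
produces a faint striated reflectance pattern in fundus photographs,
strongest in the green–blue spectral band.  Because RNFL thinning is an
early structural sign of glaucoma, a quantitative link between that cheap,
widely available photographic texture and OCT-measured thickness is
clinically interesting.  This package implements the full analysis chain
needed to study that link, for image-analysis researchers working with
paired fundus/OCT data (or, out of the box, with its own synthetic scenes):

1. **Preprocessing** (`rnfltex.preprocess`) — split a linear-intensity RGB
   fundus raster into R, G, B channels, contrast-normalize each with CLAHE
   (20 × 20 px tiles, clip limit 0.01, bilinear inter-tile blending), and
   form the red-free-like **GB** image as the mean of enhanced G and B.
2. **First-order texture features** (`rnfltex.features`) — from 41 × 41 px
   peripapillary regions of interest (ROIs) placed away from blood vessels,
   compute five statistics of the intensity histogram H(g) = n_g / N:

   µ = Σ g·H(g)   σ = √(Σ (g−µ)²H(g))   E = −Σ H(g)·log₂H(g)
   γ₁ = µ₃/µ₂^{3/2}   γ₂ = µ₄/µ₂² − 3

3. **SLO→fundus registration** (`rnfltex.register`) — a 12-parameter
   second-order polynomial transform
   (x′, y′)ᵀ = A·(x², xy, y², x, y, 1)ᵀ, A ∈ ℝ^{2×6},
   fitted to ≥ 6 landmark pairs by least squares (minimizing the energy
   ℰ = Σᵢ‖A·m(xᵢ,yᵢ) − (Xᵢ,Yᵢ)‖²), with point mapping, numerical
   inversion and image warping.
4. **Thickness-map reconstruction** (`rnfltex.thickness`) — per-B-scan
   ILM/ONFL boundary curves → thickness profiles → dense µm map on the SLO
   grid (linear or spline interpolation across scan rows, optic disc
   masked), sampled by the mean of a 7 × 7 window (tROI).
5. **Statistics** (`rnfltex.model`) — per-eye and pooled Spearman rank
   correlations of every feature against thickness, and a second-order
   regression predicting thickness from GB mean and standard deviation:

   y = β₁ + β₂µ_GB + β₃σ_GB + β₄µ_GBσ_GB + β₅µ_GB² + β₆σ_GB²

   fitted on z-scored predictors, with MAE, MCI (mean half-width of the
   95 % CI of the mean response) and R² diagnostics, plus per-eye median
   relative prediction errors.

A synthetic-scene generator (`rnfltex.synthetic`) produces co-registered
fundus/SLO/boundary data with known ground truth (thickness field, warp,
vessel mask), so the whole pipeline is testable without any clinical data.

`RnflRegressor`, `QuadraticLandmarkTransform` and `FirstOrderFeatures` are
scikit-learn-style estimators (`fit`/`predict`/`transform`, `get_params`)
and compose with sklearn tooling; the module-level functions (`fit_eq4`,
`fit_transform`, `first_order_features`, …) are thin wrappers over them.

## Worked example

```python
from rnfltex import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(output_dir="demo", n_eyes=5, seed=42))
pooled = report["correlations"]["pooled"]
print(pooled["mu_GB"]["r_s"], pooled["mu_R"]["r_s"])
print(report["model"]["mae"], report["model"]["r2"])
```

On the default synthetic cohort (5 eyes, ~20 ROIs each, 100 paired
samples) this prints, among others:

```
pooled R_S mu_GB: 0.951      pooled R_S mu_R: 0.104
pooled R_S sigma_GB: 0.995   pooled R_S sigma_R: 0.352
pooled R_S entropy_GB: 0.990 pooled R_S entropy_R: 0.349
per-eye mu_GB: mean 0.940 sd 0.034 min 0.896 max 0.980
MAE 2.58 µm   MCI 1.49 µm   R² 0.988
within-eye median relative error: mean 2.3 % (sd 0.7 %)
```

Reading: GB-channel features rank-correlate strongly with thickness while
the red channel — carrying mostly deep-layer reflections — stays below 0.5,
reproducing the expected channel ordering; the quadratic model then
predicts thickness from (µ_GB, σ_GB) with a 2.6 µm mean absolute error *on
this clean synthetic cohort*.  On real clinical data the same statistics
are substantially weaker (noise, biological variability, segmentation
error); see `docs/methods.md` for what the synthetic scenes do and do not
emulate.

The same run is available from the shell:

```sh
rnfltex run-all --out demo --seed 42 --n-eyes 5
```

along with per-stage subcommands (`synth`, `preprocess`, `register`,
`thickness`, `correlate`, `fit`, `evaluate`); see `rnfltex --help`.

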