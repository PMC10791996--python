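# Methods

## The estimation problem

The package estimates leaf area index (LAI, m²/m², one-sided leaf area per
unit ground area) of winter wheat at the jointing stage from a co-registered
UAV data set: a four-band reflectance orthomosaic (green 550 nm, red 660 nm,
red edge 735 nm, NIR 790 nm, 0.1 m grid), two digital surface models (bare
soil and crop stage), and a table of ground samples with measured LAI and
plant height. The pipeline is purely empirical: features extracted at the
sample locations are screened by correlation and fed to regression models;
no radiative-transfer inversion is attempted. Inputs are assumed
co-registered and radiometrically calibrated — mosaicking, georeferencing
and calibration happen upstream.

## Features

**Vegetation indices.** Seventeen standard indices are evaluated per pixel
from the band reflectances. Where published typesettings are ambiguous the
standard literature forms are used, stated explicitly in
`wheatlai/indices.py`: MSR = (NIR/R − 1)/√(NIR/R + 1),
MSAVI = 0.5[(2·NIR+1) − √((2·NIR+1)² − 8(NIR−R))], MTVI2 with the
square-root denominator, CARI = (RE−R) − 0.2(RE+R), CLgreen = NIR/G − 1,
CLre = NIR/RE − 1, RERDVI = (NIR−RE)/(NIR+RE). REOSAVI uses the red-edge
band, 1.16(NIR−RE)/(NIR+RE+0.16); the red-band analogue is registered
separately as OSAVI and used only by the mask classifier. Singular pixels
(zero denominators, negative radicands) become nodata.

**Texture.** Each band is linearly quantized to 64 gray levels over its
valid min–max (nearest level, ties rounded down — the unique rule under
which endpoints map to the extreme levels, a two-level quantization
thresholds at the midpoint, and a value midway between two levels takes the
lower one). A symmetric, normalized gray-level co-occurrence matrix is
formed in a 3×3 moving window with a one-pixel diagonal offset (1, 1) —
the common default when only "distance one pixel" is specified — and eight
Haralick statistics are computed per window: MEA, VAR, HOM, CON, DIS, ENT,
SEC, COR. Gray levels enter the statistics as 0-based integers.
Numerical conventions: 0·ln 0 ≡ 0 in the entropy; a zero-variance window
reports COR = 0 rather than undefined so constant regions stay usable; a
fully constant band is treated as a single gray level (flat texture) rather
than an error; border pixels without a complete window are nodata. The
raster path is a vectorized re-expression of the per-window statistics over
co-occurring pixel pairs and is tested to agree with the explicit
co-occurrence-matrix construction and with a brute-force pair-enumeration
oracle to 1e-12.

The 32 texture layers combine pairwise into texture indices. NDTI and DTI
are antisymmetric in their arguments, so only unordered pairs are
enumerated (C(32,2) = 496 each); RTI(T₁,T₂) and its reciprocal are distinct
predictors, so ordered pairs are kept (992). The total is 1984 candidate
indices. Because all three forms are pointwise, per-sample TI values are
computed from the 32 layer values extracted at the sample pixels instead of
materializing 1984 rasters; only indices needed for the final map are
rendered. Sign-equivalent duplicates are *not* removed before screening —
both members of an antisymmetric pair appear among candidates via RTI's
ordered enumeration, matching how such candidate lists are usually
reported.

**Plant height.** PH = (DSM₁ − DSM₀) × 100 cm, negative differences
clipped to zero (surface-model noise artifacts). Spectral and texture
features are read at the single 0.1 m pixel containing each sample point
(the measurement footprint is ~10×10 cm); PH averages pixels whose centers
fall within 0.5 m, mirroring a field protocol that averages plants within a
50 cm radius.

## Screening, partitioning, evaluation

Features correlate with measured LAI by two-sided Pearson test; a feature
is kept when |r| rounded to two decimals ≥ 0.80 and p < 0.01. The inclusive
threshold-after-rounding keeps features whose r prints as 0.80. No
multiple-testing correction is applied across the 1984 TI candidates — the
screening is a ranking device feeding regularized learners, not an
inferential claim. PH is always included in the PH-bearing combinations.

SPXY splits samples 70/30. Features are z-scored before the feature-space
distance (the table mixes unitless indices with cm heights; the distance
definition gives no per-feature scaling), configurable off. The calibration
size is round(0.7·N), nearest with half up (79 → 55). Selection starts
from the pair with maximal joint distance and greedily adds the sample
whose minimum distance to the selected set is largest; ties break to the
lowest sample index, making the split fully deterministic. The distance is
computed on the post-screening feature set of each combination. The
implementation is verified against an exhaustive O(N³) reference on random
tables.

R² is the squared Pearson correlation of measured and predicted values
(the 1 − SSE/SST variant is also reported for reference); RMSE is the root
mean squared residual — the conventional form, used here because a
printed "RMSE" formula lacking the measured values reduces to the SD of
predictions and cannot serve as an error; RPD = SD(measured)/RMSE with the
population SD. Perfect predictions report RPD = +inf.

## Regressors

| algorithm | defaults |
|---|---|
| RF | 500 trees, min 8 samples per leaf |
| XGBoost | η = 0.5, depth 1, γ = 0.01, α = 0.02, λ = 0.1, subsample 0.3, colsample_bytree 0.5, 200 rounds |
| SVM | RBF; C, γ ∈ {2⁻⁸ … 2⁸}, 5-fold CV on the calibration set, standardized inputs |
| BPNN | one hidden layer, one node (configurable), L-BFGS, standardized inputs |
| CNN1D | one valid convolution, kernel ⌈J/2⌉, 8 filters, ReLU, 20 % dropout, dense output; SGDM lr 0.01, momentum 0.9, 300 full-batch epochs |
| LSTM | hidden size 16 read out at the last step, same dropout/optimizer/epochs |

The XGBoost round count is not part of the published setting set and is
fixed at 200, ample for stumps at η = 0.5. The single hidden node for the
BPNN is kept as printed though it is a probable typo; it is a plain
hyperparameter override away. The CNN/LSTM are compact numpy networks with
manual backprop (the feature vector is read as a length-J, one-channel
sequence); their exact layer stacks are not published, so a minimal
one-block architecture is used. RF/XGBoost/SVM are bit-reproducible for a
fixed seed; the neural fits are seeded but only tolerance-tested. All fits
standardize internally where the estimator needs it; predictions are
returned on the LAI scale.

The wheat/soil mask is a random-forest classifier with library-default
hyperparameters on eight per-pixel features (four bands + NDVI, EVI2,
REOSAVI, OSAVI), trained on at most 20 000 reproducibly subsampled labeled
pixels and scored by overall accuracy and Cohen's kappa.

## The synthetic scene generator

The generator replaces the (undeposited) field campaign and defines the
conditions under which the pipeline is exercised:

* **LAI field** — smoothed white noise (Gaussian filter, σ = 15 px)
  rank-mapped through the quantile function of a truncated normal on
  [0.61, 8.57] whose truncation parameters are solved so the *truncated*
  distribution has mean 3.89 and SD 1.93 (moment matching; a naive
  truncation of N(3.89, 1.93²) loses ~13 % of the SD). Only summary
  statistics of the real campaign are known, so the spatial model is a
  generic smooth random field.
* **Plant height** — PH = 5·LAI + 15 cm + N(0, 1 cm) canopy roughness on
  wheat pixels, zero on soil: heights of ~18–58 cm, typical of jointing
  wheat, with the strong positive PH–LAI relation such campaigns report.
  DSM₀ is gentle smooth terrain; DSM₁ = DSM₀ + PH/100 + N(0, 5 mm) survey
  noise.
* **Reflectance** — two-endmember mixing
  ρ = f·ρ_veg + (1−f)·ρ_soil + N(0, 0.004), with Beer–Lambert cover
  f = 1 − exp(−0.5·LAI), which saturates spectrally at high LAI (the
  motivation for adding PH). The canopy red-edge endmember decays with LAI
  toward a floor of 0.20 at rate 0.15 per LAI unit, emulating deepening
  chlorophyll absorption — without this, red-edge indices (MTCI, CLre)
  would be artifacts of pure cover mixing and nearly uninformative,
  contrary to how they behave over real canopies. A sinusoidal pattern at
  the 0.15 m seeding-row spacing modulates cover by ±8 % to give the
  canopy its row texture; bare-soil strips (tramlines, 0.8 m every 4.8 m)
  provide the soil class.
* **Sampling** — n points (default 79) by stratified grid jitter over the
  wheat mask eroded by 0.6 m, so the whole 50 cm height-measurement
  neighborhood lies in the crop (samples sit inside plots, not at tramline
  edges). Measured LAI adds N(0, 0.15) instrument noise (the real
  campaign's triplicate-averaged instrument error is unreported — this is
  a free parameter); measured PH adds N(0, 0.5 cm) tape noise.

What the generator does **not** emulate: atmospheric and BRDF effects,
photogrammetric DSM artifacts (it writes smooth truth + white noise),
mixed soil/vegetation pixel geometry beyond linear mixing, lodging,
varietal spectral differences, and spatial autocorrelation of measurement
error. Consequently, passing tests show the pipeline's machinery is
correct and that it recovers a known signal under realistic noise — not
that the specific accuracies transfer to any real field.

## Numerical and design choices

* Cubic-convolution resampling uses the Keys kernel (a = −0.5), applied
  separably, with the 4-tap neighborhood clamped at edges; it reproduces
  constants and linear ramps exactly away from the clamped border. (The
  installed scientific stack offers B-spline interpolation, which is a
  different kernel, so this one is implemented directly.)
* Raster conventions: north-up grids, pixel-center containment for point
  extraction, NaN as the in-memory nodata that propagates through all
  arithmetic; GeoTIFF I/O through tifffile with ModelPixelScale /
  ModelTiepoint / GDAL nodata tags, round-tripping bit-exactly.
* `run_experiment` with a fixed config and seed produces byte-identical
  result tables for the RF/XGBoost/SVM paths; the map stage reuses the
  feature names frozen in the fit, so the serving features cannot drift
  from the training features.
* Test and acceptance problem sizes — scenes of 96–256 px squared, 40–300
  sample points, three to five seeds per property — were chosen so the
  whole suite runs in a couple of minutes on one CPU while every stage is
  exercised at full feature dimensionality (all 17 VIs, all 1984 TIs).

## Known limitations

* A single phenological window: nothing here models growth dynamics.
* The SPXY split is deterministic, so "validation" error has no split
  randomness; replicate scenes (different seeds) are the way to get
  spread, as `scripts/acceptance.py` does.
* The CNN/LSTM implementations are didactic-scale; on tables of a few
  dozen features they train in seconds but are not a substitute for a
  framework implementation at image scale.
* With 79 samples the 24-point validation metrics are noisy (observed
  validation R² for XGBoost VI+TI+PH varies by ±0.15 across scene seeds);
  conclusions should rest on medians across replicates.
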