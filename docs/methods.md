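# Methods

This note documents the models, parameter choices and numerical conventions
behind `agbupscale`, and what its synthetic scenes can and cannot establish.

## The upscaling chain

The package implements a two-stage statistical upscaling. Stage 1 regresses
plot-level AGB (Mg/ha) on LiDAR canopy metrics by ordinary least squares,
per species stratum, and evaluates by exact leave-one-out cross-validation
(computed with the OLS hat-matrix identity `e_i/(1−h_ii)`; the test suite
verifies equivalence with an explicit fold loop). Stage 2 regresses the
stage-1 AGB of amplified sampling plots on satellite features with random
forests. Variable selection in both stages is the same two-step rule:
two-sided Pearson test at α = 0.05, then permutation-importance ranking from
a seeded random forest (ntree = 1000, mtry = max(1, round(p/3)), impurity
importance kept as a secondary index) cut at the dominant relative
importance gap — the largest drop within the first five ranks is taken when
it exceeds twice the mean drop in that window, otherwise five variables are
kept, with a floor of two. Ties break lexicographically so selections are
reproducible. Selection runs once on the full training table, not inside CV
folds; this is a known optimism source and is deliberate, matching the
workflow being modelled.

## LiDAR processing conventions

* Noise: height-threshold flagging; points are marked, never deleted.
* Ground model: lowest return per 2 m cell seeds a Delaunay TIN; the TIN is
  rasterised once at the cell size and returns are normalised against the
  bilinear-sampled DEM raster (exact for affine terrain, verified to 1e-6 m;
  far cheaper than a barycentric walk per return). Outside the seed hull a
  least-squares plane extrapolates — adequate for synthetic terrain, crude
  for real ridgelines.
* Classes: vegetation iff normalised height strictly exceeds 0.2 m.
* Intensity: `I_C = I_raw·R_i²/(R_ref²·cos θ_i)`, R_ref default 1000 m;
  an error is raised when cos θ ≤ 0.
* Metrics: percentiles interpolate linearly between order statistics, for
  heights and intensities alike (intensity statistics use vegetation returns
  by default; configurable to all returns). Skewness and kurtosis are
  population moments, kurtosis non-excess; cv = population sd / mean.
  Density slices split [0, Hmax] of the plot's vegetation returns into ten
  equal slices, lowest = D01; boundary heights belong to the upper slice
  except Hmax itself (D10). The extinction coefficient in the LAI formula
  defaults to k = 0.5 (spherical leaf-angle convention) and `ang` is the
  mean absolute scan angle; both are undocumented in the emulated workflow
  and configurable here. Gap fraction 0 makes LAI undefined (NaN with a
  warning); Hmax = Hmin does the same for the canopy relief ratio.

## Raster features

* Grids are north-up, row-major, 10 m pixels owning `[x, x+10)`; a pixel's
  value represents its full area. Nodata is NaN.
* C correction regresses each band on cos i over all valid pixels (a mask is
  accepted); |slope| below tolerance — e.g. flat terrain, where cos i has no
  variation — skips the band with the reason recorded. Corrected reflectance
  is clipped to [0, 1] with clip counts logged. Slope/aspect come from
  Horn's 3×3 gradient.
* The Sym5 filter pair is hard-coded from the standard orthonormal tables
  and validated in-repo by QMF identities and perfect reconstruction
  (< 1e-8). Default boundary mode is periodization, so level-j subbands
  have exactly ceil(N/2^j) coefficients and replicate cleanly (nearest,
  factor 2^j) onto the pixel grid; symmetric half-point extension is
  available for analysis. Texture bands are subband magnitudes.
* GLCM textures use the one configuration of the emulated workflow: 3×3
  window, 45° offset, 32 grey levels by per-band min–max quantisation,
  symmetric matrix, reflected edge padding. A constant window has undefined
  correlation; the convention is 0.
* Group arithmetic: a = 10 + 19 + 5 = 34, b = 120, c = 3 + 16 = 19, d = 24;
  154 optical + 43 SAR = 197. The five biophysical variables default to
  documented monotone NDVI/infrared surrogates (FVC = clip(NDVI,0,1)²,
  LAI = −2·ln(1−min(FVC,0.99)), FAPAR = 0.95·FVC, Cab = 60·FVC,
  Cwc = 0.2·(II+1)/2 clipped); they are stand-ins for an external
  biophysical processor, flagged as such, and can be supplied as bands.
  The VH/VV ratio is formed in linear power.

## Evaluation

r is the Pearson correlation of predictions and observations, R² = r²,
rRMSE = 100·RMSE/ȳ, and "overall accuracy" = 100 − rRMSE. Predictions are
clamped at 0 Mg/ha (clamp counts recorded) since biomass is nonnegative.

## The synthetic world

The generator states a world with the statistical structure the analysis
assumes, not a radiative-transfer simulation:

* Stands: Poisson stem placement (optionally an inhomogeneous lognormal
  density field, sd 0.5 on the log scale, 250 m correlation length — an
  age/site mosaic that gives plots a realistic 30–350 Mg/ha spread);
  truncated-lognormal DBH ≥ 5 cm (the field measurement floor); saturating
  species-specific height–DBH curves; single-tree allometry a·DBH^b with
  generic conifer defaults (a = 0.1, b = 2.4, kg on cm) and per-species
  overrides. Only relative recovery behaviour is meaningful, not absolute
  biomass.
* Point clouds: one return per pulse at ~40 pts/m² (reduced to 4 pts/m² in
  the scaled-down end-to-end runs; at 625 m² support that still leaves
  ~2,500 returns per cell, so per-cell metric noise stays small); crowns are
  envelopes around stems, ground returns elsewhere on the DEM; scan angle
  and range follow a single nadir sensor at 280 m; raw intensity is the
  exact inverse of the range/scan-angle correction plus optional Gaussian
  noise (default 20 in the pipeline so intensity metrics are informative
  rather than two-valued).
* Imagery: every optical band is a saturating exponential in AGB
  (floor + range·(1−exp(−AGB/S)), S = 150 Mg/ha) modulated by the
  cos i/cos sz illumination ratio (so the C correction has signal to
  remove), a small per-species gain (larch 1.06, Chinese pine 0.94 — species
  differ in canopy reflectance, and this gives stratification something to
  exploit in stage 2), and autocorrelated Gaussian noise. SAR rises in dB
  with a 2× higher saturation scale and carries multiplicative gamma
  speckle. Note the exponential response has 13.5% of its initial slope at
  exactly 2S; "asymptotic flatness above 2S" is therefore asserted as the
  secant slope over [2S, 4S] < 10% of the low-AGB slope, which the model
  satisfies.
* Masks: strips are rectangles (default two east–west strips crossing all
  stratum bands), roads are buffered polylines, species strata are
  contiguous vertical bands with widths proportional to layout weights.

What a green end-to-end test establishes: the chain recovers known
structure — stage-1 coefficients, the experiment-D advantage, the shrinking
high-AGB bias, the stage-1 stratification benefit under distinct
allometries — in a world where those effects exist by construction. It does
not establish absolute accuracies on real forests: crown shape, mixed
pixels, phenology, atmospheric residuals, geolocation error and allometric
model error are all absent, and the plot sampler is a deterministic rule
standing in for an analyst's visual interpretation (stratum purity ≥ 90%
plays the role of "visually pure stands"; minimum plot spacing defaults to
100 m, unstated in the emulated campaign).

## Design choices in open territory

* Metric grids for strip prediction are computed at 25 m cells, matching
  plot support; the spatial support of the emulated strip product is not
  stated. Stage-2 models train at 25 m plot support and predict 10 m pixels
  — a deliberate, documented support mismatch.
* Plot sampling is grid-based (25 m candidate lattice) with seeded
  random-order acceptance under a hard-core minimum-distance constraint —
  quasi-uniform, reproducible, and re-verified geometrically in tests.
* Stage-2 strata are larch and Chinese pine where ≥ 20 plots exist; other
  conifers pool into the non-stratification model, which also serves as the
  fallback for unrouted pixels in the map.
* The stage-2 RF uses the same hyperparameters as the importance ranking
  (ntree = 1000 by default; 300 trees and a 150-tree ranking forest in the
  scaled-down pipeline configuration, where the candidate set is already
  filtered).

## Known limitations

Single-return LiDAR only; no tree segmentation or waveform metrics; GLCM
only at the 3×3/45° configuration; the DWT inverse is implemented for the
periodization mode; GeoTIFF export is plain multi-page TIFF with grid
metadata (no CRS tags); the stage-2 stratification contrast is noisy at
desk-scale sample sizes (n ≈ 40 plots per stratum) and is therefore
asserted at stage 1, where the allometric contrast acts directly.
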