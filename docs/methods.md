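# Methods

This note documents the models and procedures implemented in
`isomigrate`, the assumptions behind them, the defaults and why they
were chosen, and what the synthetic test worlds do and do not
demonstrate.

## Problem setting

A butterfly's wing chitin records the isotopic composition of the site
where the larva developed and is essentially inert after metamorphosis.
Given a spatial model of expected isotope values across a landscape (an
*isoscape*, a mean grid plus a per-pixel SD grid), a measured wing value
can be inverted into a probability surface over candidate natal
origins.  Hydrogen isotopes (δ²H, ‰ VSMOW-SLAP) follow precipitation
climatology and resolve mostly latitude; bioavailable strontium
(⁸⁷Sr/⁸⁶Sr) follows geology, is independent of δ²H, and adds
longitudinal resolution.  The package chains: isoscape construction →
isotope-scale calibration → per-specimen dual-isotope assignment →
population-level movement and connectivity statistics.

## Spatial carrier

`GeoGrid` is a regular, north-up, square-cell raster with NaN as
nodata.  Two coordinate conventions coexist: an abstract equal-area
Cartesian plane (km units, planar metric) used for most desk-scale
tests, and a geographic lon/lat grid on a sphere of authalic radius
6371.0088 km (great-circle distances, initial bearings, forward
geodesics) used wherever distance or direction is the quantity under
test.  Rasters serialize as ESRI ASCII grids — a plain-text format any
GIS ingests — with an isoscape stored as a `*_mean.asc`/`*_sd.asc`
pair.  Correctness of the method does not depend on the map projection;
the equal-area assumption enters only through per-cell area weights,
computed exactly per latitude row on geographic grids.

## Ensemble isoscape regression

The strontium isoscape is fit by stacked ensemble regression from
point observations and predictor rasters.

**Variable selection.** A random forest is fit on all candidate
predictors plus 5 decoy columns (random permutations of real columns,
so the decoys keep realistic marginals but carry no signal).
Permutation importance is evaluated on a 30% holdout — in-sample
importance flatters smooth-but-uninformative layers — and `auto`
selection keeps predictors whose importance exceeds the maximum decoy
importance, falling back to the single best predictor if none do.

**Spatial covariates.** Spatial position is encoded as distances to
anchor points ("oblique distances"): 25 anchors subsampled from the
training points (seeded), the training-point distance matrix reduced by
PCA to 8 components, and the grid distance matrix projected onto the
same components.  Because the PCA is fit at the training locations, the
component scores there are exactly orthogonal.  This lets nonspatial
learners express spatial dependence at a fixed, small feature cost.

**Base learners and stacking.** Four base learners are fit by default:
random forest (200 trees), gradient boosting (xgboost, 200 rounds,
depth 4), an RBF support-vector machine, and cross-validated
elastic-net regression; a multilayer perceptron is implemented but off
by default because it is high-variance at desk-scale sample sizes.
SVR and MLP standardize the *target* as well as the features: SVR's
ε-tube (default 0.1) is scale-dependent and ⁸⁷Sr/⁸⁶Sr spans only
~0.07 in absolute units.  Stacking weights come from an OLS
meta-learner fit on spatially blocked held-out base predictions: points
are partitioned into k-means blocks of coordinates (default 5), each
learner predicts every block while fit without it, and the OLS of
observations on those out-of-fold predictions gives the weights, their
t-values, and honest stacked residuals.  The reported spatial-CV RMSE
and R² are computed on these stacked held-out predictions; the
meta-learner's handful of coefficients, fit on hundreds of points,
contributes negligible optimism.  Prediction at a pixel is exactly
`intercept + Σ weight·learner(pixel)`, nodata wherever any predictor is
nodata.

**Per-pixel uncertainty.** For each pixel, the held-out residuals of
the `k = 30` nearest training points are pooled; the SD is the
quadrature combination of (i) the half-width of the pool's central 67%
interval (≈1 Gaussian SD), (ii) the absolute local median residual,
and (iii) an intra-site SD floor (default 0.001, the typical
within-site spread of bioavailable ⁸⁷Sr/⁸⁶Sr).  The median term is
this package's choice: under spatial block CV the local residual pool
is generally off-centre (extrapolation bias), and a symmetric ±1 SD
band built from the half-width alone empirically covered only ~50-55%
of held-out residuals; including the offset restores ~65-70% coverage.
An arithmetic-sum mode is available behind `combine="sum"` for users
who read "added to the prediction errors" literally.

## Calibrations

* **Reference-scale rescaling.** Legacy δ²H data measured against
  superseded standard values are mapped to the current scale by the
  least-squares line through the standards' (old, new) value pairs;
  with two standards (e.g. KHS −54.1 → −35.3, CBS −197 → −157) this
  is the exact two-point line, so anchors map exactly.
* **Inter-method bridge.** OLS of one analytical method's duplicate
  measurements on the other's, with residual SD = √(SSR/(n−2)).
  Coefficients are fit from user data, never hard-coded.
* **Precipitation → wing transfer.** The wing isoscape is the
  growing-season precipitation isoscape mapped through a linear
  transfer (the published Afro-Palearctic wing-chitin relation
  δ²H_wing = −39.80 + 0.80·δ²H_GSP, r² = 0.53, ships as a constant);
  the wing SD combines |slope|·GSP-SD with the transfer residual SD in
  quadrature.  The residual SD is a required user input — r² alone
  does not determine it.
* **Resampling.** Mean grids resample bilinearly, SD grids by nearest
  neighbour (interpolating SDs would understate local uncertainty);
  nodata is preserved and disjoint extents error.
* **Strontium blank uncertainty.** The procedural-blank term is
  blank-measurement SD × (blank signal / sample signal), combined with
  the sample measurement SD in quadrature (arithmetic-sum mode behind a
  flag).  The instrumental mass-fractionation correction itself needs
  raw beam intensities and is out of scope.

## Assignment

Per specimen and isotope system, the likelihood at each pixel is the
normal density of the measured value with SD
√(isoscape SD² + specimen total SD²).  δ²H and ⁸⁷Sr/⁸⁶Sr
likelihoods multiply (climate- and geology-driven systems treated as
independent), and the product is normalized over land (non-nodata)
cells into a posterior origin surface — a uniform prior over land.

The **2:1 odds region** is the smallest set of highest-probability
cells whose cumulative mass reaches 2/3, with ties at the boundary
probability all included, so containment is at least twice as likely as
non-containment; its mass therefore lies in
[2/3, 2/3 + max cell probability].  An alternative reading — the top
third of *cells* by rank — is available as `odds_mode="cell_rank"`;
the mass reading is the default because it is the one that actually
delivers 2:1 containment odds.

Derived metrics: **minimum migration distance** (0 if the capture cell
is in the region, else the minimum great-circle distance to region cell
centres — a deliberately conservative displacement estimate);
**putative-local screen** (capture cell in the region or minimum
distance strictly below 100 km — such specimens cannot be
distinguished from residents and are excluded from connectivity);
**region centroid** (3-D unit-vector mean of cell centres, robust
across the antimeridian); **travel-bearing distribution** (initial
bearing from each candidate origin cell to the capture point,
accumulated into 1° half-open bins with weight posterior mass ×
origin-capture distance by default — distant origins imply more travel
— reported with circular mean, degrees clockwise from north, and
resultant length); and **stacked maps** (per-pixel percent of
individuals whose region includes the pixel).

## Connectivity statistics

The **Mantel test** correlates the strictly-upper-triangle entries of
the capture-site and origin-centroid great-circle distance matrices;
the null distribution jointly permutes rows and columns of the origin
matrix, and p = (1 + #{r_perm ≥ r_obs})/(1 + n_perm) with 9999
permutations by default.  The default alternative is one-sided
(connectivity is a positive-association hypothesis); two-sided is a
flag.  **Centroid clustering** groups specimens in (δ²H, ⁸⁷Sr/⁸⁶Sr)
space by agglomerative clustering with centroid linkage, z-scoring each
axis first (the scales differ by ~10⁴); `k="auto"` maximizes the
silhouette over k ∈ 2..min(6, n−1).  The **seasonal trend** is OLS of
migrant δ²H on capture day-of-year (years pooled), with the two-sided
t-test p-value for the slope; on a landscape where δ²H falls with
latitude, a positive slope means later captures originated farther
south — the leapfrog signature.

## Synthetic worlds

The generator builds what the downstream stages need, with full ground
truth: isotope fields made by Gaussian-smoothing white noise and
rescaling affinely to an exact range; predictor layers constructed as
corr·z(field) + √(1−corr²)·z(independent noise) so their expected
correlation with the field is exactly `corr` (noise layers are white,
not smoothed — smoothing would induce spurious sample correlation at
desk-scale grids); training points sampled uniformly (or 90%
concentrated in the western half to emulate literature-compilation
density bias) with Normal site-level noise; and specimens whose true
origin is displaced from a capture site by a configurable
distance/bearing distribution, with wing values equal to the local
field value plus transfer-residual and analytical noise.  By default
the local field value itself deviates from the smooth isoscape mean by
the per-pixel SD, so the assignment model is *exactly* correctly
specified — the property that makes coverage of the 2:1 region testable
against its nominal 2/3.

The standard world is a 40×40, 1° geographic grid spanning lon
[−10°, 30°], lat [0°, 40°] (a western Afro-Palearctic footprint), with
δ²H on [−150, −20] ‰ (SD 2 ‰) and ⁸⁷Sr/⁸⁶Sr on [0.704, 0.774]
(SD 0.0005) — the observed ranges of wing values and bioavailable
ratios in the region.  Default noise: analytical δ²H ±2 ‰ and
⁸⁷Sr/⁸⁶Sr ±0.0001 (instrument reproducibility), site-level Sr 0.001,
wing-transfer residual 12 ‰ (a calibration with r² ≈ 0.5 over a
continental δ²H range implies residual scatter of that order).  EML
experiments use 500 training points and predictors at corr 0.9.

**What the synthetic worlds do not emulate:** real geology (Sr fields
are smooth, real ones have sharp lithological contacts and heavy
spatial redundancy), spatially structured calibration bias, non-uniform
specimen priors, habitat availability, or multi-year heterogeneity.
Passing tests demonstrate that the *inference machinery* is correct and
calibrated under its own assumptions — not that real-data assignments
attain the same coverage or precision.

## Numerical choices and degenerate inputs

Seeds: every stochastic routine takes one integer seed; multi-learner
fits derive per-learner substreams via `SeedSequence.spawn`, keeping
all derived seeds below 2³¹.  Odds-region ties are broken by including
every cell tied with the boundary probability.  A posterior whose joint
density underflows to zero everywhere raises a degenerate-posterior
error rather than renormalizing noise.  A bearing is undefined for a
cell whose centre coincides with the capture point; distance weighting
zeroes that cell naturally, and in unweighted mode its mass is spread
uniformly over bins (logged).  K-means CV blocks with fewer than two
points are merged into the nearest block (logged).  Base learners that
fail to fit are dropped (logged); fewer than two survivors is an error.
Meta-identity holds to float32 tolerance (the gradient-boosting backend
predicts in single precision).

## Problem sizes

Test and acceptance runs use 32-40² grids, 300-500 training points,
118-200 specimens, 999 permutations (9999 in the analysis drivers), and
5-seed replication for stochastic claims — sizes at which every
statistic above is stable to within the tolerances asserted, while the
whole suite completes in minutes on one CPU.

## Known limitations

The neighbour-pool error model assumes residual exchangeability within
a spatial neighbourhood; it cannot see uncertainty sources absent from
the training residuals (e.g. covariate shift far from all training
points).  Assignment assumes isotope-system independence and a uniform
land prior; informative priors (habitat suitability) are deliberately
out of scope.  The origin *centroid* can fall far from every highly
probable cell when the region is fragmented — the Mantel statistic
inherits that imprecision, which is why it is interpreted as relative
longitude/latitude structure rather than point accuracy.  Only two
isotope systems are supported.
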