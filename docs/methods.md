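# Methods

## The problem and the model

Two-season transhumance splits a region's pastures into warm-season grounds
(grazed during the growing season, typically higher and remoter) and
cold-season grounds (winter, lower, near settlements), with each household's
seasonal parcels allocated inside its township. Livestock numbers, however,
are censused per county. `grazemap` maps those county totals onto seasonal
pixels in three modelling steps and one accounting step.

**Seasonal classification.** Because pasture allocation happens within
townships, absolute predictor values are not comparable across townships —
4 800 m is "high" in one township and "low" in another. Every predictor is
therefore transformed to its relative value

    RV_ij = (X_ij − X̄_i) / X̄_i

where `X̄_i` is the predictor's mean over the masked pixels of township `i`.
The transform is scale-free (invariant under positive rescaling of X) and
has exact township-mean zero. It is undefined when `X̄_i ≈ 0`, which really
happens for winter temperature in °C; townships with `|X̄_i| < 1e-6` get
RV = 0 with a warning rather than unbounded features. A ten-fold
stratified-by-label random-forest classifier (100 trees per fold) is fitted
to labelled warm(1)/cold(0) samples; each fold model classifies every masked
pixel and the pixel's class is the mode of the ten votes, with 5–5 ties
going to warm iff the mean warm probability is ≥ 0.5. Fold performance is
the rank-based (Mann–Whitney) AUC of the held-out tenth, ties counting 1/2,
banded excellent (0.9–1) / very good (0.8–0.9) / good (0.7–0.8) / average
(0.6–0.7) / poor (0.5–0.6), lower edge inclusive.

**Density model.** The county response is

    y_c = ln(SSU_c / A_c),   SSU_c = 5·cattle_c + sheep_c,

with `A_c` the county's masked-pasture area on a spherical Earth
(R = 6371.0088 km; a pixel of angular size Δ centred at latitude φ has area
(RΔ)²·cos φ). Counties flagged agricultural, with no masked pixels, or with
zero stock are excluded. Predictor features are county zonal means over the
mask. Before fitting, pairs with |Pearson r| > 0.7 are screened: the member
with the weaker absolute univariate correlation to y is dropped, repeatedly,
until no pair exceeds the threshold (ties break alphabetically; constant
columns drop first). A ten-fold random forest (200 trees per fold) is
fitted; folds are stratified on quantile bins of y, with the bin count
capped at `n/10` so every bin can appear in every fold, and a plain shuffled
K-fold fallback when even two bins are infeasible (tiny fixtures). A
backward-elimination ladder (`prune_by_importance`) and partial-dependence
curves support predictor selection.

**Headline CV metrics are pooled out-of-fold.** Each fold's model predicts
its held-out counties; R², MAE and MSE are computed once over all counties'
out-of-fold predictions. With 24 counties a per-fold R² is computed on 2–3
points and is numerically meaningless (it can be arbitrarily negative when
the held-out pair happens to be close in y); the pooled form is well defined
at any sample size and is what a single reported R² per ten-fold model has
to mean. Per-fold metric lists are retained for diagnostics.

**Pixel weights and the uncertainty layer.** Each fold model predicts
ln-density for every masked pixel; predictions are exponentiated *before*
averaging, because the dasymetric weights and the product are density-scale
quantities and ln-scale weights could be negative. The across-fold
coefficient of variation uses the sample SD (ddof = 1) divided by the fold
mean, defined as 0 where the mean is 0, so the uncertainty raster is total
on the mask.

**Disaggregation.** Livestock are assumed to sit entirely on warm-season
pastures in the warm season and cold-season pastures in the cold season, so
for each season the *full* county total is spread over that season's pixels:
`v_ij = total_c · w_ij / Σw`. The last target pixel absorbs the residual
float error, making the pixel sum equal the census total to ≤ 1e-9 relative
by construction (observed ~1e-16). Degenerate counties follow a fallback
ladder: zero total weight on the season's pixels → uniform weights there;
no pixels of that season's class → spread over the county's full mask with
a warning; no mask pixels → excluded as agricultural-type. Values stay
fractional (float64 accumulation, float32 on disk): the product is a
density-weighted expectation, and integer rounding would break conservation.
Cattle, sheep and total livestock use the same weight surface by default;
per-species weight rasters can be supplied.

**Validation.** Products are re-aggregated to townships (pixel sums) and
scored against independent township censuses. R² is the coefficient of
determination 1 − SS_res/SS_tot on raw totals — not a squared correlation —
and is reported even when negative; MAE is in head or SSU. Both seasons are
compared against the same season-agnostic township total and both reported,
since seasonal township censuses do not exist.

## The synthetic landscape

The generator is a pure function of a seeded config and plants exactly the
structure the method assumes:

- **Admin units** are rectangular pixel-aligned tiles (counties tiled
  `n_county_rows × n_county_cols`, each split into near-square township
  tiles), so nesting and rasterization are exact. Realistic boundary shapes
  would add nothing testable.
- **Predictors** are Gaussian-smoothed white-noise fields (correlation
  length `smoothness` = 25 px by default) plus deterministic cross-variable
  trends: temperature falls with elevation (lapse-rate-like), NDVI rises
  with growing-season rain and falls with elevation, travel time rises with
  elevation, snow days rise where winters are cold. Coupling strengths are
  set so that distinct predictors sit *below* the |r| = 0.7 screen at the
  county-mean level while GStem is a deliberate near-duplicate of Tmp
  (r > 0.95) — the one planted pair the screen must always catch.
- **Seasonal truth**: warm exactly where DEM exceeds the within-township
  `warm_quantile` (default 0.5) quantile among suitable pixels — the
  higher/remoter-in-summer pattern of transhumance, in its sharpest testable
  form.
- **Density truth**: `exp(β·z)` over standardized predictors, rescaled so
  the regional mean over suitable pixels is `mean_density` (default
  30 SSU/km², a mid-range stocking level for alpine rangeland; the planted β
  makes greenness attract and elevation/snow/remoteness repel stock, NDVI
  and DEM dominant).
- **Censuses** integrate the truth over each unit's suitable pixels and
  perturb multiplicatively by `exp(N(0, σ_y))` (default σ_y = 0.3;
  log-normal keeps totals positive and matches the ln response). Head counts
  follow the SSU rule with `cattle_fraction` = 0.55 of SSUs as cattle, and
  the SSU identity is re-enforced after integer rounding. Township censuses
  use an independent noise stream, making them genuinely external validation
  data. Units with no suitable pixels are flagged agricultural and excluded,
  mirroring how farm-based counties cannot be modelled dasymetrically.
- **Training samples** are drawn uniformly without replacement from suitable
  pixels, labels flipped independently with `label_noise` (default 0.05).

Default problem sizes — 200×200 pixels, 24 counties, 96 townships, 2000
samples — are the package's reference study conditions: large enough that
AUC, out-of-fold R² and cross-scale R² are stable to a few hundredths across
seeds, small enough that the whole pipeline runs in seconds.

**What passing tests do and do not show.** The synthetic fields are
smooth, stationary and fully observed; the planted seasonal rule is a crisp
threshold; census noise is homoscedastic on the log scale. Real rangeland
data have anisotropic terrain, measurement error in predictors, fuzzy and
policy-driven pasture allocation, and census biases that are not log-normal.
Recovery here therefore demonstrates that the *pipeline* is correct and
mass-conserving and that the estimators behave as designed — not that any
particular real-world accuracy will be achieved.

## Numerical and design choices

- **Grid convention**: north-up, pixel-is-area, origin at the upper-left
  pixel corner; polygon→pixel assignment by pixel-center containment
  (strict interior; rectangular fixtures never place centers on edges).
  Grid shape is always derived from extent + resolution.
- **GeoTIFF I/O** is built directly on `tifffile` with the standard geo
  tags (ModelPixelScale, ModelTiepoint, a minimal WGS84 geokey directory,
  GDAL_NODATA); round trips are bit-exact and writes are byte-deterministic,
  which makes whole-pipeline determinism testable by file comparison. The
  nodata tag is omitted when the sentinel is unrepresentable in the output
  dtype (e.g. uint8 masks). Projected CRSs and multiband files are rejected.
- **Resampling**: bilinear for continuous fields, nearest/majority for
  categorical; majority takes the most frequent source class whose center
  falls in the target pixel, ties to the smallest class code.
- **Determinism**: every random element (landscape, census noise, label
  flips, fold splits, forests) derives from named integer seeds; rerunning a
  config reproduces byte-identical products, and the run manifest records
  the config hash, seeds and per-stage wall time.
- **Vector formats**: GeoJSON only. Exclusion provenance is attributed in
  input order, making overlap accounting deterministic.
- **Pipeline stages communicate through files** in the run directory, so
  any stage can be rerun or inspected in isolation; the density stage clamps
  the fold count to the number of available counties (with a warning) so
  4-county toy regions still run end to end.

## Known limitations

- Spherical pixel areas (no ellipsoid); fine for model weights, ~0.3%
  biased for absolute areas.
- The relative-value ε-guard zeroes features in near-zero-mean townships
  instead of, say, switching to an additive anomaly; those townships lose
  that predictor's contrast.
- The classifier applies the relative-value transform uniformly to all its
  predictors, including NDVI.
- Species share one weight surface by default; fitting species-specific
  density models is supported but not wired into the default pipeline.
- Seasonal validation reuses the season-agnostic township census for both
  seasons; a township whose stock genuinely splits across seasons would be
  over-counted in both comparisons.
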