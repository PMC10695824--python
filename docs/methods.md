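# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `borealshift`.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Problem and scope

The pipeline quantifies the albedo-mediated climate feedback of boreal
forest composition change.  Two fractional surfaces are mapped per epoch
at 30 m — deciduous fraction *d* (share of tree basal area contributed by
deciduous species, independent of canopy density) and tree canopy cover
*c* (fractional areal canopy coverage) — from seasonal multispectral
composites.  Seasonal surface albedo is then modelled as a function
α(*d*, *c*), and the epoch-to-epoch change in modelled albedo is
converted to top-of-atmosphere shortwave forcing by multiplication with a
radiative kernel *K* (W m⁻² per unit albedo; negative under our sign
convention, since raising albedo reduces absorbed shortwave).  Results
are stratified by fire-age class and region.  Winter is excluded
throughout: the pipeline carries spring (March–May), summer
(June–August) and fall (September–November) only, and the "non-winter"
aggregate is the unweighted mean of the three seasonal maps on their
common mask (no insolation weighting; a deliberate, documented choice).

## Synthetic landscape

The generator produces a seeded ground truth with the statistical
structure the analysis assumes; every renderer is a pure function of
(config, seed), with independent RNG substreams per product.

**Base fields.**  Long-term deciduous fraction d₀ and mature canopy
cover c₀ are Gaussian-blurred white noise (blur σ = 8 px), scaled to
mean ± sd 0.35 ± 0.15 and 0.60 ± 0.15 and clipped to [0, 1].  The
256×256 default grid at 30 m keeps a full run in minutes on one CPU.

**Fire history.**  24 random ~10–45-px-radius polygons with years
uniform on 1950–2018.  Pre-fire composition inside perimeters is drawn
from the same base fields as unburned terrain (the real-data pre-fire
statistics are unknown).

**Succession (relay floristics).**  For a pixel whose most recent fire
was *t* years ago:

    c(t) = c₀ · (1 − e^(−t/τ_c))                       τ_c = 25 y
    d(t) = d_late + (d_peak − d_late) · (t/τ_d) · e^(1 − t/τ_d)
                                                        τ_d = 15 y,
                                                        d_peak = 0.75,
                                                        d_late = 0.10

The deciduous pulse peaks at exactly d_peak when t = τ_d and relaxes to
the evergreen-dominated late state; canopy closes on a 25-year e-folding
scale.  These functional forms are inventions consistent with the
qualitative boreal chronosequence (deciduous fraction initially
increasing after fire, then progressively declining), not fitted curves.

**Reflectance.**  Six bands (blue, green, red, NIR, SWIR1, SWIR2) as a
linear mixture r = c·[d·E_dec + (1−d)·E_eve] + (1−c)·E_bg per season,
plus i.i.d. Gaussian noise (default sd 0.01) and seeded per-date cloud
masks (default 8% per date, 4 dates/season).  Endmembers are chosen so
the deciduous/evergreen NIR contrast is largest in summer (0.45 vs 0.25)
and smallest in leaf-off spring (0.22 vs 0.18), and the spring
background is bright (residual snow/litter).  Band values are synthetic;
no real sensor wavelengths or BRDF effects are modelled.

**Inventory plots.**  2,000 plots on pixels with c > 0; total basal area
scales with cover (40 m²/ha at full cover) and the deciduous share is
the pixel's *d* plus Gaussian noise (sd 0.05, clipped) — representing
plot measurement and plot/pixel mismatch error.

**Albedo.**  α = b₀ + b_d·d + b_c·c + b_dc·d·c per season with defaults

| season | b₀ | b_d | b_c | b_dc |
|--------|----|-----|-----|------|
| spring | 0.62 | +0.10 | −0.38 | +0.05 |
| summer | 0.16 | +0.06 | −0.04 | 0 |
| fall   | 0.40 | +0.08 | −0.20 | +0.03 |

b_d > 0 every season; b_c < 0 with the largest spring magnitude (canopy
masks snow most in spring) and |b_dc| < |b_c| so ∂α/∂c < 0 for all *d*
outside summer.  Fine albedo is block-averaged by 16 (≈500 m from 30 m)
and a seeded 5% of coarse cells per day is flagged invalid, standing in
for the solar-zenith screen (< 70°) of a real daily product.

**Kernels.**  Smooth negative fields with means −120 (spring), −150
(summer) and −70 (fall) W m⁻² per unit albedo and 8% relative spatial
sd.  These magnitudes are implementer-chosen plausible values for
synthetic use, not a climate-model product; units are W m⁻² per *unit*
albedo (a per-0.01 kernel must be rescaled on load).

## Compositing and features

"NDVI-based median" compositing is interpreted as per-pixel selection of
the date whose NDVI is the order-statistic median of that pixel's valid
dates, carrying all of that date's bands together — this preserves
spectral coherence, unlike per-band independent medians.  Even counts
take the lower median date.  Indices use standard constants (SAVI
L = 0.5; EVI G = 2.5, C1 = 6, C2 = 7.5, L = 1); NDWI is the NIR/SWIR1
moisture variant used in forestry.  Terrain uses Horn's 3×3
finite-difference slope and aspect (degrees; flat cells get aspect 0;
edges are edge-replicated).  The 36-layer order is frozen in a
module-level registry so fitted models are portable.  Correlation
pruning scans layers in registry order and drops a layer iff |Pearson r|
> 0.95 against any already-retained layer on a seeded 2,000-pixel
sample; zero-variance layers are retained with a logged flag.  One-season
(summer + terrain) features are pruned separately so the fallback model
is never starved by cross-season correlations.

## Cover models

The ensemble is a bagged collection of CART regression trees (scikit-
learn trees, own bootstrap) that retains, per leaf, the count, sum,
sum-of-squares, min and max of the mean-centred training responses
routed there with bootstrap multiplicity.  Predictions average per-tree
leaf means, so they always lie within the training response range.  The
**leaf-spread uncertainty** of a prediction pools the training responses
of the one leaf reached in each tree (concatenation with multiplicity
across trees) and reports the n−1 sample standard deviation of the
pooled multiset; a pooled count of 1, or a pooled multiset with a single
distinct value, gives exactly 0 (the min/max tracking makes this exact
despite the sum-of-squares update).  A bootstrap-weighted pooling
variant was considered and rejected for simplicity.

Hyperparameters are selected by repeated 5-fold cross-validated grid
search maximizing mean CV r², ties broken by lower RMSE, then lower RMSE
sd, then grid order.  The desk-scale default grid is n_trees {100, 300}
× max_features {√p, p/3} × min_samples_split {2, 5} × min_samples_leaf
{1, 3}; the pipeline configuration uses a reduced grid (n_trees 150,
max_features {√p, p/3}, min_samples_split {2, 5}) with 2 repeats — the
problem sizes here are chosen so a full run takes minutes, and CV
repeats re-seed the fold partition (the repeat semantics is a documented
choice).  Deciduous-fraction training balances the response by binned
under-sampling (0.1-wide bins, per-bin cap 80; with the cap, sparse
extreme bins keep all their members, giving a near-uniform rather than
exactly uniform histogram).  The 70/30 split uses a floor rule on the
training count; validation plots are thinned to one seeded-random plot
per 1-km grid cell before computing adjusted r² (adjusting for the
retained-feature count) and RMSE.  Canopy cover is trained on a
stratified sample (10 equal-width cover bins, 250 per stratum) of a
reference cover raster — synthetically, the true 2010 cover field plus
0.02 Gaussian noise — against the 2010 feature stack, then applied to
all epochs.  One global model is fitted by default; a zones option can
partition plots and apply the same machinery per zone.

Map prediction scores complete-mask pixels with the three-season model
and summer-only pixels with the one-season model, records a per-pixel
source mode, and logs the three-season share.

**Recovery evaluation.**  Map accuracy against synthetic truth is
evaluated on the tree-dominated domain (true cover ≥ 0.25).  Where
cover → 0 the reflectance collapses to the background endmember
regardless of *d*, so deciduous fraction is not spectrally identifiable;
the analysis itself is masked to tree-dominated pixels for the same
reason, and the recovery metric follows the analysis domain.

## Albedo modelling and forcing

Daily coarse albedo is composited to per-pixel seasonal medians over
valid days (the validity mask is an input; the real-data path accepts a
per-day mask rather than computing solar geometry).  Downscaling uses
Keys bicubic convolution (a = −0.5) with clamped edges, implemented
directly in separable matrix form — cubic-spline resamplers are a
different interpolant — with albedo clipped to [0, 1] and kernels left
unclipped.  Invalid coarse cells are filled from their nearest valid
neighbour before interpolation and re-masked afterwards.  Training
records (*d*, *c*, α) are stratified samples capped at 200 per 0.1
albedo interval; the seasonal model is the same bagged ensemble with
exactly two predictors (100 trees, max_features 1.0, min_samples_split
5, min_samples_leaf 2) and reports 5-fold CV r² and impurity-reduction
importance shares.  Forcing is the exact per-pixel product
(α_end − α_start)·K on the intersection of the two albedo masks.

## Change analysis

A change in *d* or *c* is "unchanged" iff it rounds to 0.00 at two
decimals with half-away-from-zero rounding (|Δ| < 0.005); otherwise it
takes its sign.  Significance uses |Δ| > z·√(sd₀² + sd₁²) with the two
epochs' leaf-spread uncertainties and z = 1.96 by default; pixels with
zero combined sd are significant iff Δ ≠ 0.  This z-test is a stand-in
for a significance procedure that is not fully specified upstream, and z
is configurable.  The tree-dominated mask keeps pixels with cover ≥ 0.25
in either epoch plus the pre-fire rule (cover > 0.25 in the earlier
epoch and burned between epochs), with per-pixel rule provenance.
Fire-age classes use the disjoint ranges 1950–1978 / 1979–1998 /
1999–2018 so every burned pixel belongs to exactly one class;
rasterization is pixel-centre-in-polygon (`covers`, so boundary centres
count) with most-recent-year priority.  Areas are count × 0.09 ha per
30 m pixel, reported in Mha; conservation (increase + decrease +
unchanged = masked stratum area) is asserted exactly in pixel counts on
every report row, and significant area never exceeds the corresponding
change area by construction.  All fire perimeters are summarized
regardless of size; a ≥10,000-ha display filter exists as an off-by-
default report option.  Regions must form a partition (overlap is an
error); uncovered pixels report as "unassigned".

## What the synthetic tests do and do not show

Passing tests demonstrate that the estimators recover a known truth
under the generator's assumptions: linear spectral mixing, i.i.d.
Gaussian noise, deterministic succession clocks, a bilinear albedo law
and spatially smooth fields.  Real Landsat/MODIS data violate all of
these (BRDF and atmosphere residuals, mixed pixels, burn-severity
heterogeneity, unburned islands, inventory georeferencing error), so
synthetic recovery rates are upper bounds, not forecasts of real-data
skill.  The chronosequence sign pattern (recent burns cool, intermediate
burns warm in spring) is a structural consequence of the succession and
albedo models and tests the plumbing end-to-end, not the ecology.

## Numerical conventions and degenerate inputs

Rasters are float32 TIFFs with NaN nodata and a JSON grid sidecar; a
single planar equal-area reference grid per run (pixel centres at
(col + 0.5, row + 0.5)) avoids CRS machinery, and every read validates
against it.  Grid-search ties break deterministically (RMSE, RMSE sd,
grid order).  Index layers with zero denominators are masked and drop
out of the composite masks.  Plots with zero total basal area are
excluded with a logged count rather than coerced to 0.  All random
draws flow from `numpy` Generators keyed on (seed, stream tag), so a
fixed config and seed reproduces the change report bit-for-bit.

## Known limitations

No atmospheric/BRDF modelling, cloud detection, sensor calibration or
real CRS handling; no winter forcing; no trend fitting beyond two
epochs; no understory (< 1.5 m) component; fire perimeters are treated
as uniformly burned (no unburned-island detection); the significance
procedure is a documented stand-in; east/west zonation is available but
not exercised by the default configuration.
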