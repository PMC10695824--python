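# borealshift

Post-fire shifts between deciduous and evergreen trees change the energy
budget of boreal forests: deciduous stands are brighter, especially in
spring when leafless canopies expose snow, so a compositional shift alters
surface albedo and hence the shortwave radiation balance.  `borealshift`
is a tested pipeline for quantifying that feedback at landscape scale.  It
is aimed at remote-sensing and land-surface scientists who want to map
**sub-pixel deciduous fraction** *d* and **tree canopy cover** *c* from
seasonal multispectral composites, model seasonal surface albedo
α(*d*, *c*), and convert epoch-to-epoch albedo change into shortwave
radiative forcing with radiative kernels:

```
RF = (α_end − α_start) · K        [W m⁻²],   K < 0
```

so an albedo increase produces a negative forcing (biophysical cooling).
Changes are stratified by fire-age chronosequence — old (1950–1978),
intermediate (1979–1998) and recent (1999–2018) burns — to expose the
relay-floristics pattern: deciduous fraction pulses upward after fire and
declines as evergreen conifers re-establish.

A seeded synthetic-landscape generator stands in for the satellite,
inventory, albedo, kernel and fire-perimeter archives, so every stage is
testable end-to-end on one CPU with no downloads.

## What the pipeline does

1. **Simulate** (`synthetic`) — spatially autocorrelated base composition,
   dated fire perimeters, succession dynamics (saturating-exponential
   canopy recovery, pulsed deciduous fraction), linear-mixture reflectance
   with seasonal phenology contrast, inventory plots, coarse albedo with a
   validity screen, and negative albedo kernels.
2. **Composite** (`compositing`) — per-pixel median-NDVI-date seasonal
   composites, five vegetation indices (NDVI, NDWI, SAVI, VARI, EVI),
   Horn slope/elevation/aspect: a 36-layer predictor stack per epoch,
   pruned of layers with |r| > 0.95.
3. **Map cover** (`inventory`, `cover_mapping`) — deciduous fraction from
   plot basal-area ratios, balanced by binned under-sampling, 70/30
   train/validation split with 1-km validation thinning; bagged
   regression-tree ensembles (three-season model plus a summer-only
   fallback) with per-pixel leaf-spread uncertainty; canopy cover from a
   stratified reference-raster sample.
4. **Albedo and forcing** (`albedo`) — seasonal median albedo composites,
   bicubic-convolution downscaling to the 30 m grid, a two-predictor
   ensemble α(*d*, *c*) per season, and kernel multiplication of the
   modelled albedo change.
5. **Change report** (`change`) — tree-dominated analysis mask (cover ≥
   0.25 in either epoch, plus pre-fire inclusion for pixels burned between
   epochs), two-decimal change classification, per-pixel z-test
   significance, and stratified areas (Mha) and warming/cooling forcing
   statistics by fire-age class and region.

## Worked example

The numbered drivers under `analysis/` run the stages on the default
256×256, 30 m landscape (2,000 plots, reflectance noise 0.01):

```
$ python analysis/01_simulate_landscape.py --seed 1
landscape (256, 256) with 24 fires; 39.6% burned since 1950
  truth ddec 2000->2015, old burns: -0.187
  truth ddec 2000->2015, intermediate burns: -0.051
  truth ddec 2000->2015, recent burns: +0.303

$ python analysis/05_change_report.py --seed 1
           stratum  n_pixels  ddec_mean  dcover_mean  forcing_spring_mean ...
            domain     63503  -0.017189     0.008942             0.431445
         fires_old     12138  -0.158434     0.078229             4.153500
fires_intermediate      5495  -0.088448     0.180931             8.322923
      fires_recent      6344   0.204436    -0.217577           -10.833028
         fires_all     23977  -0.046384     0.023500             1.143801
```

Reading the report: inside recent burns the mapped deciduous fraction
rose (+0.20) and canopy cover fell (−0.22), raising spring albedo, so the
mean spring forcing is strongly negative (−10.8 W m⁻², cooling).
Intermediate and old burns show the opposite — canopy closure and
evergreen succession darken the surface, a warming forcing — and the
domain-wide mean is small because the two regimes largely offset.
`analysis/03_map_cover.py` prints the model skill behind those maps
(deciduous fraction recovered against truth with RMSE ≈ 0.075 / r² ≈ 0.80
on the tree-dominated domain; canopy cover RMSE ≈ 0.02 / r² ≈ 0.98), and
`analysis/04_albedo_forcing.py` the seasonal albedo models (cv r² 0.76 to
0.96, with canopy cover the dominant predictor in spring and fall and
deciduous fraction in summer).

A `borealshift` CLI exposes the same stages
(`simulate`, `composite`, `train-cover`, `predict-cover`, `train-albedo`,
`forcing`, `change`, `run-all`), e.g.
`borealshift run-all --seed 1 --outdir scratch/run1`.

## Layout

```
src/borealshift/   library (all computation lives here)
analysis/          numbered narrative drivers writing tables to results/
tests/             pytest suite incl. end-to-end acceptance checks
scripts/           acceptance.py
docs/methods.md    model and design notes
```
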