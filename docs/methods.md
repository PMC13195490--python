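# Methods

## Scope and model structure

The package estimates the carbon sequestration of semi-arid sea buckthorn
plantations by two independent routes and compares them.

The **remote-sensing route** is a light-use-efficiency (CASA) model run at
a monthly timestep.  Absorbed photosynthetically active radiation is the
product of total solar radiation, the canopy absorption fraction FPAR and
a fixed PAR share of 0.48.  FPAR is a linear stretch of NDVI between
*theoretical* shrubland bounds (0.023–0.636) onto [0.001, 0.95]; because
the bounds are theoretical rather than observed, NDVI outside them is
clamped to the boundary FPAR, never extrapolated.  Actual light-use
efficiency down-regulates a shrubland maximum of 0.429 gC·MJ⁻¹ by three
factors: a low-temperature quadratic in the (uniform, 22 °C) optimum
temperature, a high-temperature double-logistic in monthly temperature,
and a water factor 0.5 + 0.5·E/Ep bounded in [0.5, 1].  Net ecosystem
productivity subtracts heterotrophic respiration, obtained from total soil
respiration Rs = f·exp(b·Ta)·P/(k+P) (P in cm) through the empirical
log-log relation ln Rh = 0.22 + 0.87 ln Rs.  Multi-year cumulative NEP is
the carbon-sequestration-density proxy; no discounting or decay is
applied.  Negative NEP (carbon source) is preserved.

The **field route** builds a five-pool per-plot ledger (above- and
below-ground woody biomass, herb, litter, soil; gC·m⁻²).  Woody pools come
from dual-factor allometric models W = a·D^b·H^c + d applied to every
measured individual and summed per 25 m² quadrat, times carbon fractions
0.5465 (above) and 0.4526 (roots).  Herb and litter carbon use fresh
weights scaled by oven-dry subsample ratios and fractions 0.40 / 0.37.
Soil organic carbon density integrates SOCᵢ·ρᵢ·Hᵢ·10 over 10/10/30 cm
layers.  Net sequestration subtracts a native-grassland control ledger
(pool-wise; a total-wise option exists and is numerically identical by
linearity) and machinery-fuel leakage, 3.31 tCO₂·ha⁻¹ applied in the first
year.

## Numerical and unit conventions

* Precipitation is supplied in mm everywhere; the respiration model owns
  the mm→cm conversion.  The evapotranspiration formulas are implemented
  exactly as printed, including the ×30 factor in the potential-ET
  expression and the dimensional asymmetry of the actual-ET formula (it
  mixes mm and MJ·m⁻² with no harmonising constant); only non-negativity
  guards are added.  Degenerate denominators resolve to the conservative
  limits: E = 0 when P + Rn = 0, Wε = 0.5 (maximum stress) when Ep = 0,
  Rh = 0 at Rs = 0 (the continuous limit of the power law).
* NEP + Rh ≡ NPP holds bitwise per cell; the ledger total is the exact
  pool sum.
* gC·m⁻² → tCO₂·ha⁻¹ conversion multiplies by 44/12 and 0.01; the inverse
  round-trips to 1e-12 relative.
* Rasters are single-band float32 GeoTIFFs (one file per variable per
  month, YYYY-MM in the filename) with an explicit nodata sentinel; masks
  propagate through all arithmetic.  The GeoTIFF georeferencing tags
  (pixel scale, tiepoint, geokey directory, GDAL nodata) are written and
  read directly on top of tifffile.
* Slope/aspect use Horn's 3×3 method (the conventional GIS default), with
  edge replication at borders; aspect is masked where slope is zero.
  Site-type windows: gully bottom below 5°, shrub slopes 5–25° split by
  aspect with half-open intervals ([0°, 90°) ∪ [270°, 360°) shady,
  [90°, 270°) sunny) because closed endpoints would overlap at 90°/270°;
  slopes above 25° are explicitly UNCLASSIFIED.
* Jenks natural breaks are solved exactly by dynamic programming
  (minimum within-class sum of squares); ties break toward the smaller
  upper class.  Exactness matters because class membership feeds plot
  stratification.
* The power-law allometric fit uses Levenberg–Marquardt least squares with
  a log-linearised start (offset taken as min(W)/2) plus four seeded
  jittered restarts; the cubic-in-height form is linear in its
  coefficients and solved directly.  R² is 1 − SSE/SST; constant-biomass
  samples (SST = 0) are rejected.  Outlier removal is an explicit
  per-sample analyst flag, never automated.
* Validation RMSE is reported about the 1:1 line (root mean squared
  estimated − measured), with the residual RMSE about the fitted line
  emitted alongside.  Per-pixel trends use OLS slope on year with a
  two-sided t-test at α = 0.05.
* The age projection regresses mean pool density on stand age: plain OLS
  for herb and soil (which may decline), OLS with the slope floored at
  zero for the woody pools (stocks cannot shrink with age in these
  stands), and the cross-age mean for litter, whose measured densities
  show no consistent temporal trend.  The first year with positive
  cumulative net density is reported as a structural output.

## The synthetic watershed

The generator emulates the study system the pipeline targets: a small
Ordos-plateau watershed with a continental semi-arid climate (annual mean
8 °C, seasonal half-range 14 °C peaking in July; 320 mm·yr⁻¹ of
summer-concentrated rain), elevation around 900–1000 m with a cosine
ridge-valley terrain whose flanks face due north/south and whose
crests/troughs are near-flat — producing contiguous shady-slope,
sunny-slope and gully-bottom regions by construction.  NDVI is a spatial
gradient times a growing-season weight plus a deterministic per-year
greening increment (0.012 yr⁻¹) and seeded noise; the annual-max NDVI
product is derived from the monthly series, not generated separately.

The plot design mirrors a stratified survey over stand ages 5–10:
36 plots (7/4/6/7/6/6 by age), two 5 m × 5 m quadrats, four 1 m × 1 m
herb/litter subplots and three soil points per plot (72/144/108 in
total), plus grassland controls (two subplots and one soil point per
plot).  Soil bulk density and organic carbon means per age and layer are
the surveyed stand values; woody pool means are anchored to the reported
net stand-age pattern (above-ground rising ~169 → ~693 gC·m⁻² from age 5
to 10) by solving mean plant height from the target pool through the
above-ground allometric truth — the below-ground pool then *follows* from
the same (D, H) through the below-ground form, preserving allometric
consistency rather than being dialled independently.  Control-pool means
are chosen so net (baseline-subtracted) densities reproduce the reported
pattern, including the negative net herb pool at age 7.  One global seed
splits into independent substreams (climate, NDVI, DEM, plots, biomass
samples), so adding a generator never perturbs another's draws; every
generator is a pure function of (spec, seed).

Noise defaults: multiplicative lognormal σ = 0.15 on individual plant
D and H, σ = 0.1 on destructively sampled biomass, additive Gaussian
6 / 3 gC·m⁻² on herb/litter subplot densities, 0.08 g·cm⁻³ / 0.5 g·kg⁻¹
on soil samples, 0.8 °C on monthly temperature and lognormal σ = 0.25 on
monthly precipitation.  The surveyed study reports no within-plot variance
components, so these scales are plausible field values, not calibrated
ones.

What the generator does **not** emulate: sensor physics, cloud
contamination and revisit gaps, species mixtures, spatially correlated
noise, drought years, and interannual climate anomalies.  Two
consequences worth noting when reading test results: the deterministic
greening increment in every cell means the trend classifier flags
essentially the whole synthetic watershed as significantly increasing
(a real watershed is mostly stable), and passing the closed-loop tests
demonstrates internal consistency of the accounting, not accuracy on real
imagery.

## Validation design

The paired remote-sensing-vs-field check follows the study design itself:
"measured" plot densities are constructed as the pipeline's cumulative
density at each plot's grid cell plus Gaussian measurement noise
(σ = 1.5 tCO₂·ha⁻¹, a plot-scale field-measurement uncertainty), and the
recovered regression slope is required to fall within two standard errors
of 1.  Because the noise sits on the regressor side, the slope carries a
small attenuation bias of var(x)/(var(x)+σ²); with the default spread of
~8 tCO₂·ha⁻¹ across plots this bias (<2%) is well inside the 2-SE band.

## Problem sizes

The default study conditions use a 36 × 36-cell, 30 m grid over 11 years
(132 monthly layers), 36 plots and 28 standard plants; the trend type-I
simulation uses 10,000 cells over 11 years.  These sizes make every
statistic well-resolved while the full suite and the acceptance script
each run in seconds.

## Known limitations

* The actual-evapotranspiration formula's unit asymmetry is reproduced
  as printed; its water-stress output should be read as an index, not a
  water balance.
* T_opt is a uniform constant; the NDVI-maximising definition of optimum
  temperature is not implemented.
* Whether monthly CASA should consume monthly composites or an
  interpolated annual-max NDVI series is ambiguous in the source
  workflow; this implementation consumes monthly NDVI and derives
  annual-max composites for the trend path.
* Gully bottoms are defined purely by the low-slope rule; no
  flow-accumulation delineation.
* The projection sub-models reproduce structure (linear-in-age pools,
  constant litter, first-year leakage), not published coefficients, which
  are not printed in the source material.
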