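# Methods

This note documents the models, procedures, and design choices behind
`tnflux`, in the order data flows through the pipeline.

## The loading model

TN flux is modelled on the natural-log scale as a linear function of four
predictors: transformed net anthropogenic nitrogen input
f_NANI = asinh(NANI/2), annual precipitation P_Annual (mm), extreme
springtime precipitation P_MAM,p>0.95 (mm), and developed-plus-cropland
percent cover LU_D,C. The default coefficients are
(0.538, 0.438, 0.0012, 0.0033, 0.0213); they are stored at printed
precision and all arithmetic is done in double precision. Predicted flux is
the plain exponential of the linear predictor. No log-retransformation
(smearing) correction is applied: the model is used directly as an
exponential response surface, which keeps scenario ratios exact and
matches how the calibration is deployed; a smearing factor would rescale
all runs by a common constant and cancel from every percent change the
pipeline reports.

**Calibration** is ordinary least squares of ln(observed flux) on the four
predictors (statsmodels), with rank checks that reject constant or
collinear columns. **Model selection** searches land-use predictor
structures exhaustively: each candidate is a summed percent-cover variable
over a nonempty subset of the six aggregated categories (cropland,
developed, forest, other, pasture, rangeland), optionally two disjoint such
variables, always alongside the three fixed predictors and an optional
no-land-use candidate. The criterion is minimum BIC. Because category
fractions sum to one, the complement of a subset yields an exactly
equivalent fit; BIC ties are therefore detected with an absolute tolerance
of 1e-6 and broken by fewer land-use predictors, then lexicographic subset
order, which deterministically prefers {cropland, developed} over its
complement. The selection search uses a fast lstsq inner loop and refits
the winner with statsmodels for standard errors.

A note on the two-variable search: adding a spurious second disjoint
variable to the true model is a nested comparison whose deviance gain is
~χ²₁ regardless of the noise level, while the BIC penalty is ln(n) ≈ 5.6
at n = 280. Minimizing BIC over ~300 pair candidates therefore admits a
spurious second variable in roughly 10% of replicates no matter how small
the noise. Recovery of the generating subset is consequently assessed over
the single-variable candidate space (63 subsets), matching the structure of
the generating model, where recovery at low noise is essentially perfect.

## NANI accounting

NANI = fertilizer + fixation + deposition + net food/feed import − nonfood
crop export, all in kg N km⁻² y⁻¹. Import is a signed net term (negative =
net export), so NANI itself may be negative. Two assembly modes:

* **Observation mode** (historical baseline): component tables at annual
  resolution, built from census-year values by piecewise-linear
  interpolation; years before the first census year extrapolate the OLS
  trend through all census points (fixation floored at zero, import
  unrestricted), deposition before 1979 is held at the 1979 level, and
  nonfood export is held at its 2007 value afterward.
* **Scenario mode** (projections): fertilizer is the area-weighted sum of
  application rates over five crop types (C3/C4 annual, C3/C4 perennial,
  C3 nitrogen-fixing); fixation is the nitrogen-fixing crop area times a
  constant rate calibrated so a reference-year continental total is
  matched exactly; import is predicted from a per-HUC2 OLS of historical
  import on fertilizer and fixation (intercept included, standard OLS
  practice); deposition follows the climate pathway; nonfood export is
  constant.

Two scaling steps anchor scenario-mode inputs to references: fertilizer
series are rescaled by one multiplicative factor per HUC2 (reference
1987–2012 total over input total, applied to all years including the
future), and modelled deposition is rescaled per watershed by the ratio of
reference to modelled means over a five-year overlap window (2002–2006 by
default). Per-watershed deposition scaling preserves the spatial pattern of
the reference data; a coarser regional factor would be an equally
defensible reading of the procedure. Negative predicted fertilizer or
fixation is clamped to zero with a warning; negative predicted import is
legal.

## Precipitation features

Daily series are reduced to the two model predictors per watershed, year,
and climate model. The extreme threshold is the 95th percentile (linear
interpolation between order statistics) of all in-season (March–May) daily
values over the 1981–2010 baseline — zeros included by default, with a
wet-day-only switch since the percentile population convention is genuinely
ambiguous in this literature. Exceedance is strict (> threshold).
Thresholds are computed independently per watershed and climate model,
frozen from the baseline, and reused for all historical and future years,
so a future season is judged extreme relative to the fixed historical
climatology. Each RCP ensemble reuses the leading historical model ids, so
every future member has a baseline threshold from its own model.

## Scenario engine

Each scenario couples an SSP land pathway with a fixed paired RCP
(SSP1-2.6→RCP2.6, SSP2-4.5→RCP4.5, SSP4-6.0→RCP6.0, SSP5-8.5→RCP8.5,
SSP4-3.4→RCP2.6, SSP3-7.0→RCP8.5). Projections are evaluated over 30-year
periods (historical 1976–2005, mid-century 2031–2060, end-of-century
2071–2100). When a driver is held at historical levels while evaluating a
future period, its value for year t is taken from the historical table at
hist_start + (t − future_start); this offset mapping preserves interannual
variability (needed by the ensemble t-tests) and makes the all-historical
configuration reproduce the baseline bit-for-bit.

Three factor flags drive the factorial decomposition, with precipitation
held historical: the cropland flag moves the cropland share of land use
*and* the crop areas embedded in NANI (fertilizer usage, fixation, import);
the developed flag moves only the developed share of LU_D,C; the
fertilizer-rate flag moves application rates (and import through the
regression). NANI is scenario-mode for both periods in decomposition runs,
and deposition is held at historical levels there — the decomposition
varies exactly the three land factors, and letting deposition drift with
the pathway would fold a climate-policy signal into a land-use
attribution. In land-management-only runs every historical ensemble member
is used, so ensemble spread reflects how one land scenario manifests under
different models' historical precipitation; ensemble sizes may differ per
RCP and all statistics use the actual member count.

## Robustness and aggregation

Regional loads are exact area-weighted sums of period-mean fluxes
(kg N km⁻² y⁻¹ × km²), which makes aggregation additive over arbitrary
partitions to rounding error. A change is robust when, across climate
models, the fraction with a significant future-vs-historical difference
strictly exceeds 50% and the majority-sign fraction strictly exceeds 80%.
The per-model test is a Welch (unequal-variance) two-sided t-test on the
two 30-value annual samples — Welch because between-period variance change
is exactly what a trending climate produces, and the samples are treated as
independent since years are not physically paired between periods. A zero
mean difference counts toward neither sign; p = 0.05 exactly is not
significant; identical samples (p undefined) count as no evidence of
change. Percent changes are computed per model first (each model's own
historical mean as base), then summarized as ensemble mean ± sample SD
(n−1). The cross-scenario direction mask emits a unit's mean change only
when at least five of six scenarios agree on the sign.

## Synthetic worlds

The generator produces the statistical structure the analysis assumes, not
geography:

* **Watersheds**: log-normal areas (median 2000 km², σ = 0.6), round-robin
  HUC2 assignment, a MARB-like region (~40% of watersheds) and a disjoint
  Northeast-like region (~15%).
* **Precipitation**: per watershed and model, wet-day occurrence
  Bernoulli(p ≈ 0.3) with Gamma(0.7, ~11.7 mm) wet-day amounts, giving
  ~900 mm mean annual totals; per-watershed and per-model multiplicative
  jitter; future scenarios scale the Gamma scale (mean and tail together)
  along a linear ramp reaching the per-RCP multiplier at 2100 (1.03–1.10).
* **Land use**: Dirichlet base fractions at the 2015 junction; a mild
  multiplicative drift into the junction over the historical era; future
  archetypes (bioenergy expansion, food-demand expansion, stable/decline)
  move cropland and developed land along linear ramps that are continuous
  at 2015 and hit configured 2100 deltas, with the remaining categories
  rescaled so fractions always sum to one. Application rates ramp from
  0.8× (1976) to 1× (2015) and on to the archetype multiplier (0.85–1.25)
  by 2100.
* **Nitrogen budget**: component magnitudes are anchored so area-weighted
  continental mean shares match the observed structure
  (+72/+45/+14/−30/+0.78% of NANI); the fixation rate is calibrated from
  2007 nitrogen-fixing areas; import follows a known linear per-HUC2 rule
  whose census-table regression recovers it exactly; deposition declines
  under the RCPs (0.60–0.85× by 2100).
* **Calibration data**: predictors over realistic ranges, ln-flux from the
  model plus Gaussian noise whose SD is set from the empirical signal
  variance to hit a target population R² (0.67 by default, mirroring the
  published explanatory power at n = 280).

Everything is deterministic under one seed via independent named RNG
streams, and ground truth is returned alongside the data. The default
world is small (50 watersheds, 5 HUC2s, 7 historical models with 5/6/4/7
per-RCP ensembles, preserving the 21/16/20/12/21 proportions of the full
archive); `WorldConfig.full_scale()` provides the 2105-watershed,
full-ensemble preset. For linear-limit decomposition experiments,
`flat_history()` removes the historical drift so the entire
future-vs-historical perturbation scales with one factor, and
`with_scaled_scenario(ssp, eps)` shrinks a scenario's deltas by ε.

What the generator does **not** emulate: spatial correlation between
watersheds, realistic geography or drainage topology, IAM economics,
sub-annual nitrogen dynamics, and any systematic bias between the loading
model and reality (synthetic fluxes are generated by the same model family
that is fitted). Passing tests therefore demonstrate the correctness and
statistical calibration of the machinery — recovery, oracle agreement,
error rates, conservation — not the predictive skill of the empirical
model on real watersheds. Scenario archetypes are qualitative: they
reproduce the *direction* and rough ordering of pathway effects, not
published magnitudes, and because the default historical era has upward
land-use and rate drift into 2015, even "stable" pathways show small
positive changes relative to 1976–2005.

## Numerical choices and degenerate inputs

* Percentiles: numpy linear interpolation between order statistics.
* BIC: n·ln(RSS/n) + k·ln(n); ties at 1e-6 absolute tolerance.
* Zero-over-zero scaling factors (fertilizer, deposition) default to 1;
  zero-over-nonzero raises an unscalable-region error.
* Rank deficiency anywhere raises a degenerate-design error rather than
  silently dropping columns.
* t-test p-values on identical samples are treated as 1 (no evidence).
* All tables are sorted before writing, so identical configurations yield
  byte-identical outputs.

## Problem sizes

Tests and the acceptance script run on deliberately small worlds: 10–12
watersheds for engine checks, the 50-watershed default world for
end-to-end directional checks, 200 calibration replicates at n = 280, 100
selection replicates, and 300 synthetic ensembles for robustness error
calibration. These sizes give stable statistics for every property
asserted while keeping a full run to tens of seconds.

## Known limitations

* NetCDF input/output is not provided; long-format CSV is the only
  interchange format.
* Coefficient uncertainty is not propagated into projections; ensemble
  spread is the only uncertainty reported, mirroring the analysis design.
* The food/feed import regression extrapolates a historically fitted
  linear relationship into scenario space; structural change in trade is
  out of scope.
* The NLCD-based predecessor model and mappings between land-cover
  taxonomies are out of scope.
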