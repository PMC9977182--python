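# Methods

This note documents the models, the synthetic world they are tested in,
the numerical choices, and the limits of what passing tests demonstrate.

## Chamber flux, WFPS, and Q10

Fluxes come from ordinary least squares of headspace mixing ratio on time;
for the two-sample field protocol (ambient draw at closure, one sample at
30 min) OLS reduces exactly to the endpoint difference, so accepting ≥2
points generalizes the calculation without changing the two-point result.
Mass conversion uses the ideal gas law with CH₄ molar mass 16.04 g mol⁻¹
and the CODATA gas constant; deployment pressure defaults to one standard
atmosphere (101,325 Pa) and is overridable per deployment, since chamber
campaigns rarely log pressure. Negative fluxes (uptake) are returned —
exclusion of non-positive values is a modelling decision made at fitting,
not at calculation.

Q10 is estimated by 1 °C binning and log-linear regression of bin means on
bin midpoints rather than an endpoint ratio: regression is robust to
individual noisy bins, and the two coincide when only two bins exist (an
`endpoint` mode is provided). Bins are unweighted, so sparse tail bins
inflate the estimator's variance — the Q10 recovery test therefore uses a
temperature-only generating response with reduced noise, which is the
regime where the binned estimator is actually identifiable.

## Synthetic chamber campaign

The generator emulates a large multi-year static-chamber campaign in a
depressional-wetland region: 143 wetlands × 5 chambers × 26 biweekly steps
(~18.6k rows) by default, wetland sizes log-normal (median 0.5 ha, log-sd
1.4, majority < 1 ha), hydroperiod increasing with size, a two-class
grassland/cropland surrounding, seasonal soil-temperature sinusoid
(~6–23 °C), wetland-specific WFPS drawdown from near saturation, and an
NDVI greenness hump with an adjustable WFPS–NDVI noise coupling (the real
campaign's covariate correlation structure is not knowable, so it is a
knob, default 0.3).

The generating response on the log-flux scale is built from closed forms
chosen to be analytically invertible in recovery tests: a logistic WFPS
rise centred at 80% (scale 6%), an exponential temperature term with
Q10 = 3 (linear in T on the log scale), a smooth NDVI step at zero (scale
0.08), a log-quadratic size curve peaking at 3 ha, a saturating
hydroperiod benefit (e-folding 60 days), a +0.30 grassland and +0.20
late-season offset, and lagged copies of the WFPS/temperature/NDVI curves
at weight 0.3. Every curve is exactly zero at its reference covariate, so
the all-reference record emits exp(intercept); the intercept (−1.2 log
mg m⁻² h⁻¹) puts regional mean rates near 1 mg m⁻² h⁻¹. First-step lags
equal current values (no prior step exists). Noise is Gaussian on the log
scale with wetland (σ = 0.35), chamber (σ = 0.25) and residual components;
the residual σ = 1.64 was calibrated once so the generating signal
explains ~60% of log-flux variance under the default campaign — the
signal-to-noise regime the whole study design assumes — and is not
adjusted per experiment.

What the generator does **not** emulate: negative (uptake) fluxes,
ebullition spikes, salinity gradients, within-wetland zonation of
covariates, instrument error structure, or missing-data patterns of real
campaigns. Passing recovery tests shows the estimators work at realistic
dimensionality and noise, not that they would be unbiased under those
additional real-data features.

## Plot-scale additive model

Log flux of positive-flux rows is fit by penalized least squares with:
cubic B-spline bases (default dimension 10, knots at quantiles) per
continuous covariate with second-difference (P-spline) penalties and
sum-to-zero constraints absorbed by a null-space reparameterization;
unpenalized dummy-coded categorical effects; and identity-penalized
(ridge) random intercepts for wetland and chamber-within-wetland.
Wetland size is smoothed on a log axis since areas span four orders of
magnitude.

Smoothing parameters minimize the profiled Gaussian restricted likelihood
(REML), evaluated from one Cholesky factor per candidate; optimization is
cyclic coordinate descent with bounded golden-section line searches
(log-λ ∈ [−12, 18], two sweeps — more sweeps changed nothing measurable).
GCV is available as an alternative criterion but retains spurious terms
noticeably more often. Term selection uses the double-penalty device: each
smooth's curvature-penalty null space gets its own penalty, so a term's
EDF can shrink to ~0; a term below EDF 0.5 is reported as removed.
Categorical terms are never subject to removal. A complexity inflation
γ = 2.5 divides the likelihood part of the REML criterion; this is the
package's default because at γ ≈ 1 a planted pure-noise covariate kept
1–2 EDF in roughly a third of replicate campaigns, while γ = 2.5 removes
it in ≥90% without costing any of the four generating-shape recoveries.

Uncertainty uses the Bayesian posterior covariance σ²(XᵀX+S)⁻¹; partial
effects are centred by construction and carry pointwise 95% bands.
Prediction clamps covariates to the training range (boundary-value
extrapolation) — needed when projecting warmer futures — and logs how many
values were clamped. Deviance explained is 1 − RSS/TSS on the log scale
(Gaussian deviance), identical in spirit to the fraction of log-flux
deviance the smooths and random effects capture.

Lag covariates get their own smooths rather than sharing their parents'
(the alternative was a tensor constraint with no identification gain);
this is flagged for sensitivity analysis.

## Landscape model

Wetland objects are 8-connected components of the union (wet at any step)
water mask — depressions are roughly convex, so diagonal splits are raster
artifacts; 4-connectivity is switchable. The union mask also defines the
"wetland size" predictor, while per-step wet area is reported as inundated
extent. The WFPS surrogate is 100% for wet pixels and 50% (configurable)
for currently-dry wetland pixels; hydroperiod is the per-pixel wet-step
count × 14 days; season interval splits at the frost-free-window midpoint;
lags reference the previous step (self-referential at step 0).

The flux model is a scikit-learn random forest on log flux: 500 trees,
⌈p/3⌉ features per split (regression convention), bootstrap fraction 2/3,
out-of-bag variance explained and mean squared residual reported on the
log (training-response) scale. Training pairs chamber rows with their
field covariates; the schema is shared with the landscape predictor
records, so the same forest predicts per (pixel, step). Predictions are
exponentials of tree means, hence strictly positive, and row-wise — tiled
evaluation is bit-identical to whole-array evaluation by construction.

## Synthetic wetlandscape

Disjoint elliptical depressions (1-pixel moat) are placed largest-first by
rejection sampling on a 30-m grid; requested areas are realized exactly as
the n smallest-elliptical-radius pixels, so truth tables and delineation
agree to the pixel. Each wetland's wetted fraction follows a seasonal
half-sine plus a size-coupled base level; at any step the wettest
`round(frac · area)` pixels (deepest first) are inundated, making wet
masks nested across any pair of steps, and a global `wetness` multiplier
produces dry/wet bookend landscapes that share identical wetland objects
with nested extents. NDVI is negative over open water, elevated in an
emergent ring (the outer 40% of each basin), and seasonal elsewhere;
temperature adds a north–south gradient and per-step noise to the regional
sinusoid; land cover is a thresholded smoothed random field.

## Annual integration and summaries

Steps tile the frost-free window in 14-day slots (the last slot partial);
winter before/after the window is charged at the first/last within-window
step's rate, covering the full 365-day year — a constant rate r therefore
integrates to exactly r · area · 8760 h, which the tests assert. Units:
mg m⁻² h⁻¹ → g pixel⁻¹ yr⁻¹ → Gg (1 Gg = 10¹² mg). The regional mean flux
rate is the pixel-hour-weighted mean over inundated pixel-steps within the
window; this weighting is declared explicitly because observed-table
conventions for such means vary and are rarely stated. Inundated area is
reported as the maximum per-step wet extent (mean also emitted). Size
classes are left-closed 1-ha bins to 10 ha plus an open top class;
per-wetland emissions come from exact label sums, so class totals conserve
the regional total to machine precision.

## Scenario engine

Futures use the delta method: each ensemble member carries additive
monthly temperature offsets (applied to the month containing each biweekly
step's midpoint) and a longer frost-free window. Window extension adds
⌈extra/14⌉ steps that replicate the boundary steps' water mask, NDVI and
temperature — consistent with the winter boundary-rate assumption rather
than attempting shoulder-season dynamics. Water and NDVI otherwise stay at
the bookend year's values (an NDVI-delta hook exists, default off, since
the mechanism by which futures would change NDVI is unresolved). The
synthetic ensemble draws 13 members around the pathway's regional warming
(moderate ~1.7 °C, severe ~2.7 °C; member sd 0.6 °C, month sd 0.4 °C) with
season extensions of ~57/71 days jittered by 7 days, never shorter than
historical. Fold changes divide ensemble-mean future totals (averaged over
the dry/wet bookends) by the mean of the two historical totals, with
per-bookend ratios always reported so extent effects are not masked.

## Problem sizes

Recovery replicates use campaigns of 192 wetlands × 1 chamber × 2 seasons
(~10k rows) — many distinct wetlands, rather than many chambers per
wetland, because the size smooth is identified only through between-wetland
contrasts, and the replicate campaign samples sizes around a 1-ha median
so the 3-ha generating peak has support on both sides. Forest evaluation
uses the full default campaign (~18.6k rows); landscapes run at 128²–256²
pixels with 120–400 wetlands. These sizes make every study condition
testable in minutes while preserving the dimensionality (13 smooth and
categorical terms, hundreds of random-effect levels, tens of thousands of
pixel-steps) that the methods must handle.

## Known limitations

- The forest cannot extrapolate temperature responses beyond the training
  range, so synthetic end-of-century fold changes (~1.1–1.3×) sit well
  below what a process response with Q10 ≈ 3 would give; the
  Arrhenius-oracle scenario test isolates the engine from this model
  limitation deliberately.
- The fitted forest also attenuates the size–flux gradient relative to the
  generating truth (surrogate predictors and correlated hydroperiod share
  the signal), flattening size-class emission shares compared to the
  truth-driven decomposition.
- Random intercepts for wetland and chamber are mutually confounded when
  each wetland carries one chamber, and the wetland intercept competes
  with the size smooth; neither harms prediction but individual variance
  components should not be over-interpreted.
- Raster persistence is plain TIFF with JSON georeferencing metadata in
  the ImageDescription tag; values and geotransform round-trip losslessly,
  but files are not GeoTIFF-tagged and GIS software will not read their
  projection.
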