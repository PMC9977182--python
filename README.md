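# prairie-ch4

Chamber-to-landscape modelling of wetland methane (CH₄) emissions from a
prairie-pothole wetlandscape: static-chamber flux calculation, a plot-scale
penalized additive flux model, random-forest upscaling on 30-m raster time
series, integration to cumulative annual emissions, and projection under
warming × wetland-extent scenarios. Every stage runs end-to-end on
synthetic data whose generating truth is known, so the whole pipeline is
testable by parameter and shape recovery.

## Who this is for

Ecosystem biogeochemists and greenhouse-gas modellers who want a tested,
reusable implementation of the standard chamber-to-region upscaling chain
for depressional wetland landscapes — and a synthetic wetlandscape world in
which each link of that chain can be validated against known truth.

## The models

**Chamber flux.** A static chamber of height *h* closed over the surface
accumulates CH₄; with a linear mixing-ratio change (slope *s* in ppm h⁻¹),
the areal flux is

    F = s · (M·P)/(R·T) · 10⁻⁶ · h        [g m⁻² h⁻¹]

with M the molar mass of CH₄, P pressure, T temperature (ideal gas law).
WFPS (water-filled pore space) is volumetric water content ÷ porosity.
Q10 — the multiplicative rate change per 10 °C — is estimated by binning
fluxes into 1 °C increments and regressing log bin-mean flux on bin
midpoint: Q10 = exp(10·slope).

**Plot-scale model.** Positive fluxes are log-normal; log flux is modelled
as an additive combination of penalized B-spline smooths
f(WFPS), f(soil T), f(NDVI), f(size), f(hydroperiod) and their first-order
biweekly lags, categorical land-cover and season-interval effects, and
ridge random intercepts for wetland and chamber-within-wetland. Smoothing
parameters are chosen by REML; a double penalty on each smooth's null
space lets the optimizer drop uninformative covariates entirely.

**Landscape model.** Remotely-sensed surrogates stand in for the chamber
covariates at 30 m: inundation → WFPS, per-pixel wet-step count →
hydroperiod, connected-component area of the any-step-wet mask → wetland
size. A random forest (log-flux response, ~2/3 bootstrap per tree, random
feature subsets, out-of-bag evaluation) transfers the chamber relationship
to every wetland pixel and biweekly step.

**Annual integration and scenarios.** Biweekly rates integrate over the
frost-free window; winter is charged at the boundary-step rates, so a
constant rate r yields exactly r·area·8760 h. Futures are built by the
delta method — per-member monthly temperature offsets and longer frost-free
seasons from a 13-member synthetic climate ensemble — crossed with dry/wet
historical extent bookends.

## Worked example

```bash
python analysis/01_simulate_chambers.py --seed 42
python analysis/03_fit_plot_model.py   --seed 42
```

prints (abridged):

```
simulated 18590 chamber observations from 143 wetlands
median flux 0.10 mg m-2 h-1; generating signal explains 58% of log-flux variance
fit on 4056 positive-flux rows: deviance explained 57.2%, adjusted r2 0.57
recovery over 20 replicate campaigns: all four generating shapes in 20/20;
pure-noise term removed in 20/20
```

The first two lines describe the synthetic campaign: ~18.6k biweekly
chamber deployments whose generating response explains ~60% of log-flux
variance (the rest is wetland, chamber and residual noise). The fit line
reports the additive model's log-scale deviance explained on a smaller
campaign; the recovery lines say that across 20 independent replicate
campaigns the fitted partial effects reproduced all four generating-curve
signatures (steep WFPS decline below 80%, monotone temperature response,
wetland-size peak near 3 ha, NDVI step at zero) and the term-selection
penalty removed a planted pure-noise covariate.

The remaining drivers (`analysis/04`–`07`) simulate the 30-m wetlandscape
bookends, fit and validate the forest, upscale to annual regional
emissions with size-class decompositions, and project the four warming ×
extent scenarios. `prairie-ch4 run --seed 1 --out-dir results/run` executes
the same chain as one pipeline with a reproducibility manifest.

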