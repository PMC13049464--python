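# Methods

This note documents the models implemented in `thermotraits`, the
numerical choices behind them, and what the synthetic experiment does and
does not establish.

## Thermal performance model

Microbial process rates across temperature are described by the
Dual-Kinetics (DK) extension of the Ratkowsky square-root model. On the
square-root scale,

```
growth:       sqrt(G(T)) = a (T - Tmin) (1 - exp(b (T - Tmax)))
respiration:  sqrt(R(T)) = a (T - Tmin) (1 + exp(b (T - Tmax)))
```

with `a` the square-root-scale slope ((µg C g⁻¹ h⁻¹)^½ °C⁻¹), `Tmin` the
low x-axis intercept, `Tmax` the high intercept (growth) or its
respiration equivalent, and `b` (°C⁻¹) the sharpness of the exponential
deviation. Growth rises roughly as a square law above `Tmin`, peaks at
`Topt`, and collapses to zero at `Tmax`; respiration instead accelerates
smoothly around a tipping point `Ttp`. Rates are defined as
`max(sqrt-model, 0)²`, so growth is exactly zero outside `[Tmin, Tmax]`
and no negative rate can enter the annual integration.

### Two-stage calibration

Stage 1 fits an ordinary least-squares line to `(T, sqrt(rate))` pairs on
the low temperature range (default 0–25 °C), where the exponential term
is negligible; `a` is the slope and `Tmin = -intercept/slope`. Stage 2
holds `(a, Tmin)` fixed and fits `(b, Tmax)` by bounded nonlinear least
squares (`scipy.optimize.least_squares`, trust-region reflective) over
the full screening range, still on the square-root scale. Technical
duplicates enter both stages as independent observations — the model is
fit to data, not to means — and the reported R² is computed on the
square-root scale over all observations.

Numerical choices:

* Stage-2 box: `b ∈ [1e-3, 2]` starting at 0.2; `Tmax ∈ (max observed T
  − 5, 80]` starting at max observed T + 5. When the data carry no
  measurable high-temperature signal the `(b, Tmax)` objective is a ridge
  (shrinking `b` is equivalent to raising `Tmax`); the fit detects a
  deviation term contributing < 1e-4 relative over the observed grid,
  reports `Tmax` pinned at the upper search bound, and raises a bound-hit
  diagnostic instead of returning an arbitrary ridge point.
* A fitted `Tmax` more than 20 °C below the hottest screening
  temperature is flagged as implausible in the diagnostics.
* Negative measured rates (instrument noise near zero) are truncated to
  zero at CSV ingestion and counted.

### Derived indices

`Topt` (growth) solves `d sqrt(G)/dT = 0`, i.e.
`exp(b(T − Tmax)) (1 + b(T − Tmin)) = 1`, by bracketed root search
(`brentq`) on `(Tmin, Tmax)` to 1e-8 °C. The respiration curve itself is
monotone for `b > 0` and has no such root; its tipping point `Ttp` is
computed by applying the same growth-form optimum condition to the fitted
respiration parameters. This is an explicit, overridable policy: the
reported `Ttp` values (inside the screened range, between `Tmin` and
`Tmax`) are consistent with this construction, but the package treats it
as a definition of convenience, not a property of the respiration model,
and `t_crit` may be supplied directly instead.

Temperature sensitivity is summarized by
`Q10 = ((20 − Tmin)/(10 − Tmin))²` over the default 10–20 °C interval —
the squared ratio of the square-root line, exact wherever the exponential
term is negligible below 20 °C.

## Field forcing

Field campaigns record soil temperature and moisture twice a week in the
early afternoon (2–4 pm). Annual integration needs hourly forcing, so:

* **Diurnal model.** Each day follows a symmetric sinusoid peaking at
  `peak_hour` (default 14:00) with range `max(0, α + β·mean)`; defaults
  `α = 8 °C`, `β = 0.2`. The range-vs-mean linearity mirrors empirical
  daily-range calibrations for seasonally dry subtropical sites; the
  specific coefficients are configuration values because no published
  values exist for the study plots, and the synthetic generator uses the
  same parameters so the inversion is exactly testable.
* **Inversion.** An afternoon reading at `measurement_hour` (default
  15:00) sits near the daily maximum; the daily mean is recovered by
  solving `mean + (range(mean)/2)·cos(2π(h−peak)/24) = observed` with a
  bracketed root search. Daily means are linearly interpolated across
  gaps between measurement days (held at the nearest value beyond the
  first/last measurement).
* **Moisture** is interpolated at daily resolution and held constant
  within a day — soil moisture varies far more slowly than temperature.
* **Seasons.** The modeled year runs 365 days from 2018-02-08 (ending
  just before soil sampling), partitioned into two dry windows
  (2018-02-08→2018-05-26, 2019-01-21→2019-02-10) and one wet window
  (2018-05-27→2019-01-20), endpoints inclusive; the windows are validated
  to cover the year without overlap.

### Moisture rate modifier

The DAYCENT decomposition moisture function

```
ω(s) = ((s − c2)/(c1 − c2))^(c4 (c2−c1)/(c1−c3)) · ((s − c3)/(c1 − c3))^c4
```

uses the fine-texture constants c1 = 0.6, c2 = 1.27, c3 = 0.0012,
c4 = 2.84, giving ω = 1 at s = 0.6 and ω → 0 in dry soil; output is
clamped to [0, 1]. Field moisture is recorded as % of pore-volume
saturation, so the default maps `s = W/100` directly. Because the
function is written in terms of volumetric water content over porosity,
a configuration switch (`input="volumetric"`) instead applies
`s = W/(100·φ)`; saturation is the default since that is the unit the
field series carries.

## Annual budgets and counterfactual scenarios

Instantaneous rates follow the rate-modifier form used in biogeochemical
models: `rate_p(t) = ref_p · τ_p(T_t) · ω(W_t)` for p ∈ {bacterial
growth, fungal growth, respiration}, where `τ_p(T) =
rate_p(T)/rate_p(Tcrit)` normalizes each fitted curve to 1 at its own
critical temperature. Growth τ is in [0, 1]; respiration τ exceeds 1
above `Ttp` because the curve is monotone. One shared ω serves all three
processes (only one moisture function is defined; per-process overrides
are possible through the parameters object).

Reference rates default to the fitted curve evaluated at `Tcrit` — the
assays are in absolute C units, so the curve itself carries the
magnitude — and can be overridden directly. Hourly rates (µg C g⁻¹ h⁻¹)
convert to per-area fluxes through bulk density × depth (defaults
1.1 g cm⁻³ and 0.10 m; the conversion factor is exactly
`bd·depth` g C m⁻² per µg C g⁻¹). Cumulative totals are left-endpoint
Riemann sums at the model's native 1 h step; CUE = growth/(growth +
respiration).

Treatment effects are decomposed by source swapping between a control
and a treatment plot (paired within block and land use): budgets are
computed for control, treatment, and three counterfactuals using the
treatment's temperature series only, moisture series only, or
temperature-rate relationships only, with everything else from control.
Reference rates are held at control values across all five scenarios so
the decomposition isolates forcing and trait effects.

## Synthetic experiment

The generator emulates the study design — two land uses × three
treatments (control, OTC warming, rain shelter) × three blocks — so the
whole chain is testable without any field download.

* **Assays**: rates at 0–45 °C in 5 °C steps, technical duplicates,
  multiplicative Gaussian noise on the square-root scale (CV 5 %),
  truncated at zero. Noise on the square-root scale keeps the stage-1
  OLS assumptions valid, and a 5 % CV reproduces fit quality of R² well
  above 0.9.
* **Trait priors**: `Tcrit` and `Tmax` uniform in the observed index
  ranges (bacterial Topt 33–38 °C, Tmax 47–49 °C; fungal 36–40 and
  47–50 °C; respiration Ttp 32–40 °C, with Tmax 48–55 °C as the
  respiration deviation is weaker and its high intercept less
  constrained). `b` is then solved from the optimum condition so the
  drawn `Tcrit` is exactly the curve's optimum, and `a` is scaled to a
  configured reference rate at `Tcrit` (crop 0.20/0.14/1.2 and forest
  0.25/0.18/1.8 µg C g⁻¹ h⁻¹ for bacterial growth / fungal growth /
  respiration — magnitudes that place annual totals in the
  10²-g C m⁻² y⁻¹ range typical of these soils).
* **Tmin** is either uniform in a land-use-dependent range or, in the
  full world generator, linked linearly to the plot's own modeled soil
  MAT with slope 0.25 °C/°C (SD 0.6 °C) for the growth processes and
  slope 0 for respiration, building the community-adaptation gradient
  into the world. The reference point is Tmin = −1.5 °C at MAT 22 °C
  (−5 °C for respiration).
* **Field series**: twice-weekly records (alternating 3/4-day gaps) with
  per-season means/SDs — cropland dry/wet 41.8 ± 5.2 / 26.7 ± 5.1 °C and
  6.1 ± 4.3 / 30.5 ± 12.7 % saturation; forest 29.8 ± 3.7 / 21.9 ± 3.4 °C
  and 10.5 ± 3.8 / 37.2 ± 14.0 % — with OTC adding +3.9 °C to the
  cropland dry season (+1.0 °C wet; +2.0/+0.8 °C in forest, where no
  published figure exists), shelter cooling the cropland dry season by
  1.2 °C, and shelter lowering wet-season moisture means (forest to
  30.4 %, cropland to 28 %). Deviations carry AR(1) correlation
  (ρ = 0.5) so interpolation is exercised on serially dependent data.
  Moisture is clamped to [0, 100] %.
* **Seeds** are explicit everywhere; per-plot streams mix the run seed
  with a CRC32 of the plot label, so one seed yields distinct but
  individually reproducible plots.

What the synthetic world does *not* emulate: spatial autocorrelation
between plots, sensor drift and missing measurement days, rate
measurement error correlated across temperatures within an assay run,
within-season trends (values are stationary around seasonal means), or
any coupling between moisture and the temperature screening. Passing
tests therefore demonstrate that the estimators and the budget machinery
are correct and stable under realistic noise — not that the specific
published flux totals are recovered, which requires the deposited field
dataset and the original study's unpublished constants (bulk density,
reference-rate anchoring, diurnal calibration).

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data:
the parameter-recovery experiment uses 100 assays (2,000 observations);
the pipeline runs on one 18-plot world (54 assays, ~105 field dates per
plot, 8,760 forcing hours per plot); the regression-slope calibration
check uses 200 replicate worlds fitting bacterial growth only. These
sizes give Monte-Carlo standard errors comfortably below the asserted
tolerances while keeping a full run in well under a minute.

## Known limitations

* The `Ttp` construction for respiration is a policy (see above); other
  definitions (e.g., curvature maxima) would give different values.
* The diurnal α/β defaults are plausible for seasonally dry subtropical
  soil at 5 cm but uncalibrated; soil MAT and maxT summaries inherit
  them. There is no depth damping — the surface sinusoid is applied
  directly at measurement depth.
* Reference rates tie absolute budget magnitudes to the fitted `a`
  parameter; with real assay data in C units this is well defined, but
  comparisons across studies need the same anchoring convention.
* The annual integration ignores autotrophic respiration, fluxes below
  10 cm, and any substrate limitation feedback; it is a rate-modifier
  upscaling, not a C-pool model.
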