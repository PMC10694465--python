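# Methods

`heatlabor` projects occupational heat-stress labor losses — work hours lost
(WHL) — from gridded daily meteorology. This note records the model, the
parameters that matter, the synthetic study domain, and the numerical and
design choices.

## Pipeline overview

1. **WBGT** (`wbgt`). Daily mean/max wet-bulb globe temperature per grid
   cell, indoor and outdoor.
2. **Hourly disaggregation**. Daily WBGT is spread over clock hours with the
   "4+4+4" scheme; a workday definition selects the 8 worked hours.
3. **Exposure-response** (`erf`). The fraction of a work hour lost at WBGT
   `w` and metabolic intensity `I` is the normal CDF
   `loss(w; I) = Φ((w − Prodmean_I) / Prodsd_I)`, with one `(Prodmean,
   Prodsd)` pair per intensity class (200/300/400 W).
4. **Exposed population** (`exposure`). A gridded total population is split
   into agriculture / construction / manufacturing / service workers from
   per-province urbanization and sector shares; indoor workers behind air
   conditioning are removed.
5. **WHL** (`whl`). Per-capita daily loss = Σ over worked hours of the loss
   fraction; totals multiply by exposed workers and aggregate to provinces,
   periods (baseline 1986–2005; early 2021–2040; middle 2051–2070; late
   2081–2100) and the pseudo-GCM ensemble.
6. **Attribution and benefits** (`attribution`). Factor separation splits
   WHL changes into climate, population and interaction effects; the
   1.5 °C benefit substitutes mid-century WBGT from a stabilized
   low-warming scenario and prices avoided hours with the human-capital
   method.

## WBGT estimators

**Indoor** uses the simplified WBGT regression
`sWBGT = 0.567·Ta + 0.393·e + 3.94` with vapor pressure
`e = (RH/100)·6.105·exp(17.27·Ta/(237.7+Ta))` (hPa, Magnus form). It needs
only temperature and humidity and is a deliberately protective (high-biased)
approximation in moderate conditions. The estimator is pluggable.

**Outdoor** composes `WBGT = 0.7·Tnwb + 0.2·Tg + 0.1·Ta`. The default
backend solves two elementwise energy balances by vectorized bisection
(48 iterations, bracketing guaranteed analytically):

- *Globe*: `h_g(u)·(Tg − Ta) + ε σ (Tg⁴ − Ta⁴) = f_g·S`, with emissivity
  ε = 0.95, absorbed-solar fraction f_g = 0.5 and convective coefficient
  `h_g = max(6.3·u^0.6, 2.5)` W m⁻² K⁻¹ (sphere; free-convection floor).
- *Natural wet bulb*: `h_w(u)·L·(e_s(Tnwb) − e_a) = h_w(u)·(Ta − Tnwb) +
  f_w·S`, with the Lewis-relation factor
  `L = 0.622·λ/(c_p·P) ≈ 1.485 hPa⁻¹`, wick solar fraction f_w = 0.15
  (albedo ≈ 0.4 plus cylindrical geometry) and
  `h_w = max(8.0·u^0.5, 3.0)`.

With no sun the globe equals air temperature and the wet bulb reduces to the
psychrometric limit; radiation raises both and wind pulls both back — the
estimator is non-decreasing in radiation and non-increasing in wind when the
sun is up. A cheap regression backend (`swbgt_radiation`: sWBGT plus a
wind-damped radiation term) is available for quick looks. Indoor
calculations that need a wind term assume a fixed 1 m/s.

Daily **max** WBGT pairs the daily-max temperature with radiation scaled by
a midday peak factor (default 2.0, the ratio of peak to diurnal-mean
insolation for a half-sinusoid day); humidity and wind are daily values.
Because both estimators are monotone in temperature and radiation, max ≥
mean holds by construction.

## "4+4+4" hourly disaggregation

A 12-hour daylight block (07:00–19:00) carries 4 h at the daily max
(11:00–15:00), 4 h at the max–mean midpoint (09:00–11:00, 15:00–17:00) and
4 h at the daily mean (07:00–09:00, 17:00–19:00); hours outside the block
carry the daily mean. The source method does not fix which clock hours
carry which level; this layout is symmetric around 13:00 and is
configuration, not a claim. The default workday is 08:00–12:00 and
13:00–17:00 (8 h), giving the level multiset {mean×1, mid×4, max×3}; delays
of +1/+2 h shift the whole window (the +2 h delay moves two worked hours
into the evening mean level, slightly lowering exposure). Because each day
has at most three distinct hourly values, per-capita daily WHL is computed
as the count-weighted sum of three CDF evaluations.

## ERF calibration

Work/rest tables give `work_fraction = work/(work+rest)` per (intensity,
WBGT); the observed loss is `1 − work_fraction`. Fitting is nonlinear least
squares (scipy `least_squares`) on the loss scale, initialized at the WBGT
closest to loss 0.5 (location) and half the span between losses nearest
0.16/0.84 (scale), with the scale bounded to (0.1, 20) °C. On noiseless
tables the generating parameters are recovered to ~1e−8.

Calibration transfers the standard fit's between-intensity offsets onto an
epidemiological 300 W anchor: the calibrated 300 W curve equals the anchor
exactly and 200/400 W add the fitted (mean, sd) differences. Whether sd
offsets should transfer as differences or the anchor sd should be reused is
ambiguous in the source; difference transfer is the default with
`sd_mode="anchor"` as the alternative. A transfer that would produce a
non-positive sd is an error, not a silent clamp. The real occupational
standard's work/rest values and the real anchor parameters are not shipped;
the package carries clearly labelled synthetic stand-ins
(`SYNTHETIC_STANDARD_TRUTH`, `SYNTHETIC_ANCHOR_300W = (33.0, 4.0)` °C) and
nothing in the machinery depends on their specific values.

Sector → intensity/setting mapping: agriculture and construction are 400 W
outdoor, manufacturing 300 W indoor, service 200 W indoor.

## Exposed population

Per cell and year: `agriculture = total·rural_rate·agriculture_rate`;
`non_agriculture = total·urban_rate·non_agriculture_rate`, split into
construction/manufacturing/service by a per-province table (synthetic
default 0.15/0.35/0.50). Agriculture and non-agriculture participation
rates are held constant over time; urbanization rises. Indoor sectors are
scaled by `(1 − ac_rate)` (default penetration 0.6, constant; future
scenarios ramp linearly to 0.7/0.8/0.9 by 2100). Provinces are axis-aligned
rectangles on the toy grid with cell-center containment; regridding is
block aggregation only (sum for population — exactly mass-conserving — and
mean for WBGT), since general resampling is out of scope.

## Synthetic study domain

The generator supplies every input with known truth. Defaults define the
study conditions and are not tuned per experiment:

- Grid 8×8 cells of 50 km; 365-day no-leap calendar; years 1986–2100
  (pipeline default samples every 5th year — each sampled year carries a
  full daily calendar — keeping toy runs small while spanning the century).
- Temperature: grid-mean annual mean 9 °C (a temperate, monsoon-like
  national domain whose populated south is much warmer), north–south
  contrast 8 °C, seasonal amplitude 10 °C, diurnal half-range 4 °C plus a
  small gamma-distributed excess (tasmax ≥ tas by construction), AR(1)
  daily noise (ρ = 0.7, sd 2 °C). This places baseline per-capita losses at
  a few tens of hours per year — the regime in which warming, not
  demography, dominates the century-scale WHL trend.
- Scenario trends, linear from 2006 in °C/decade: rcp85 0.5; rcp45 0.35;
  rcp26 0.2 flat after 2050; cool15 0.2 flat after 2035 (the 1.5 °C
  stand-in). Pseudo-GCMs share weather noise and perturb the trend by ±5%
  per member, so scenario differences are purely forced — convenient for
  exact trend tests, not a model of real ensemble spread.
- Humidity 70% baseline, −1 %/°C of warming anomaly; wind gamma with mean
  2 m/s; radiation 220 ± 80 W/m² seasonal cycle.
- Population: Gaussian-in-time national path peaking at 0.75 billion in
  2030 (≈ −45% by 2100), fixed lognormal spatial weights; fertility
  variants scale the path toward 0.9/1.1 by 2100. Urbanization: logistic
  rise from ~0.55 to ~0.8 per province.

What the generator does **not** emulate: real spatial covariance,
orography, coastlines, humidity–circulation coupling, migration, or any
real model's variance structure. Passing tests demonstrate the machinery —
formula correctness, conservation, ordering, attribution identities — not
fidelity to any real country's numbers.

## Numerical choices and edge cases

- Loss fractions are evaluated with `scipy.special.erf`; values saturate to
  exactly 0/1 beyond ≈ ±6 sd, so strict-monotonicity checks are meaningful
  within ±4.5 sd.
- Energy-balance bisection uses analytically guaranteed brackets
  (`[Ta − 0.5, Ta + q/h]` for the globe; `[Ta − 60, Ta + q/h]` for the
  wick); a failed bracket raises with the offending cell count rather than
  returning NaN silently.
- Factor separation is additive by construction; residuals are at the
  floating-point re-association level (~1 ulp of the largest term).
- Ensemble "95%" intervals default to the ensemble min–max, the honest
  choice for 2–3 members; a normal approximation is available for larger
  ensembles.
- The work year is 365 days (every day a potential workday), consistent
  with the 8 × 365 = 2920 h full-time-job conversion used for headline
  job-equivalent numbers.
- Negative avoided-WHL cells (where the comparison scenario is cooler) are
  kept and counted by default; zero-truncation is a switch.

## Known limitations

- The indoor estimator ignores radiant load from machinery; the outdoor
  estimator's coefficients are fixed, not fitted to station data.
- Per-capita national WHL uses the exposed working population as the
  denominator; other denominators (total workforce) would scale it.
- Delayed-workday analyses reuse the same daylight layout shifted, which is
  a configuration choice, not an observed schedule.
- Economic valuation is a pure unit-value product; no GDP-share or
  discounting machinery is included.
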