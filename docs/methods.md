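# Methods

## Scope and model chain

`ensorice` implements a two-phase assessment of ENSO impacts on Mekong
River Delta (MRD) rice production. Phase 1 is the crop-model side:
plot-level calibration of a yield simulator, provincial validation
against a 1976–2016 yield panel, and projection of 2020–2050 seasonal
yields under RCP4.5/RCP8.5 climate deltas. Phase 2 is the impact side:
estimation of historical ENSO yield-reduction ratios, classification
into province-specific severity levels, application of those levels to
future ENSO years from a calendar of high-probability episodes, and
risk-area-weighted production accounting.

Hazards are mapped season-wise: El Niño → salinity intrusion/drought →
winter-spring (WS) crop; La Niña → flood → autumn-winter (AW) crop; the
summer-autumn (SA) crop faces neither hazard and its reduction ratio is
identically zero. Sea-level rise, pest/disease dynamics (beyond
exclusion years), rice quality and price effects are out of scope.

## The crop surrogate (deliberately NOT ORYZA)

Full eco-physiological models such as ORYZA resolve phenology, leaf
area, nitrogen and soil water. Their internals are not reproduced
here; instead a deliberately small surrogate maps season weather to
yield through two multiplicative stress factors:

    f_T = clip(1 − s_T · max(0, T̄ − T_opt) / y*, 0, 1)
    f_W = clip(1 − s_W · max(0, (W − R) / W), 0, 1)
    YS  = y* · f_T · f_W

with `T̄` the mean temperature and `R` the rainfall total over the first
`season_length` days of the season. This form was chosen for analytic
testability: a stress-free season returns exactly the potential yield
`y*`; warming the reference season by ΔT above optimum lowers yield by
exactly `s_T·ΔT`; stress can never raise yield. The surrogate sits
behind the single function `simulate_yield(weather, params)`, so a
coupling to a full crop model can replace it without touching the rest
of the pipeline.

Default parameters (units; rationale): potential yield 7.0 ton/ha
(upper range of observed WS yields), optimum temperature 28 °C (near
the delta's hot-season mean, so ENSO/RCP warming is stressful at the
margin), heat sensitivity 0.6 ton/ha/°C, water requirement 400 mm per
season, water-deficit sensitivity 0.7, season length 100 days (local
varieties mature in 95–110 days). Season windows are fixed calendar
slices labelled by harvest year: WS Nov(y−1)–Feb(y), SA Apr–Jul(y),
AW Aug–Nov(y).

Calibration minimises plot-level yield RMSE with bounded least squares
(`scipy.optimize.least_squares`, trf), deterministic for a fixed
starting point; leaf-area matching is not part of the objective. Free
parameters default to the three that plot management contrasts
identify well (potential yield, heat and water sensitivities); every
free parameter requires finite bounds.

## Validation statistics

Nash–Sutcliffe model efficiency `Ef = 1 − Σ(YO−YS)²/Σ(YO−ȲO)²` (1 =
perfect, 0 = mean predictor, negative = worse than the mean; undefined
and an error for constant observations). R² is the squared Pearson
correlation — this, not regression through the origin, reproduces the
packaged plot table's printed seasonal values (WS 0.89, SA 0.96,
AW 0.78) from its printed yields. Per-cell Ef reports require at least
5 overlapping years (configurable); shorter cells are flagged
unavailable rather than raised. Note the packaged plot table's printed
YO−YS column disagrees with its own YO and YS by 0.01 in two cells
(source rounding); differences are always recomputed from YO and YS.

## Reduction ratios, CDFs and levels

The reduction ratio is defined as `D = (YS − YO)/YS × 100`, the percent
shortfall of the observed crop relative to its simulated (stress-free)
potential, clamped to [0, 100]. The sign convention makes D positive
exactly in damage years and consistent with its later use
`YF = YS(1 − D/100)`; negative raw shortfalls (good years) clamp to
zero because the levels describe losses only. Pest-outbreak seasons
(default 1992, 2002 and 2009 AW — brown plant hopper / grassy stunt
virus outbreaks unrelated to ENSO) are excluded from estimation so the
ENSO attribution is not contaminated; the exclusion list is
configurable.

Per province × hazard season, estimates across ENSO years form an
empirical CDF whose maximum is the severe-year reduction. Levels are
derived by an explicit, pluggable rule; the default splits the positive
estimates into empirical tertiles, with each band represented by its
maximum (conservative: the high level carries the worst observed
year). With fewer than three distinct positive estimates the output
degenerates to a single band repeated across levels. How the published
bands were originally derived from the CDFs is not documented; the
published band table is shipped as a fixture so users can bypass
estimation entirely.

## Scenario projection

RCP deltas are exogenous: ΔT is added uniformly to all temperatures
(RCP4.5: 1.4 °C; RCP8.5: stated as 1.8–1.9 °C, default midpoint 1.85),
and rainfall is scaled multiplicatively by a per-province Δrain %
(RCP4.5 ranges from 5.8 % in Ca Mau to 18.2 % in Ben Tre, regional mean
≈13 %; RCP8.5 from 10.8 % in Ca Mau to 18.3 % in Can Tho). Only the
range endpoints are published per scenario; the intermediate provincial
defaults in `scenario_deltas.csv` are package configuration chosen
inside the stated ranges and are user-replaceable. The baseline window
is 2005–2016 inclusive, the future window 2020–2050; future means are
taken over all years (ENSO years are not excluded). Future ENSO-year
yields inside the projection are trend-only; ENSO depressions are
applied downstream by the reduction module, mirroring the separation
of the projection and impact steps. Regional summary rows are
unweighted province means over provinces cropping the season — this
choice is verified arithmetically against the packaged change table
(the 12 provincial WS present yields average to 6.40 ton/ha and their
reduction ratios to 1.93 %) and encoded as a test. Ca Mau has no WS
crop; requesting a cell without calibrated parameters is an error.

## Production accounting

Seasonal production `PPs = Σₗ YF_l · S_l` sums over the four risk
strata (high/medium/low/none); each at-risk stratum's yield is reduced
by the level matching its risk class (identity mapping, configurable)
and the no-risk stratum is never reduced. Annual `PPa = Σₛ PPs` sums a
province's applicable seasons (absent seasons are absent, not
zero-filled); the regional total requires all 13 provinces and errors
on a missing one. Losses are `100·(present − condition)/present`,
computed from unrounded totals; printed-style tables round half-up at
2 decimals in 10⁶ tons. Absolute rice areas S (ha) per province ×
season are a required input that is not public alongside the packaged
tables; the demo derives a synthetic area per province — annual present
production divided by the sum of present seasonal yields, used for
every season — which reproduces the present production column exactly
and is labelled a demo convenience, not survey data. The packaged
provincial production columns do not all sum exactly to the packaged
regional totals row (source rounding of provincial entries, ≤0.02);
loss checks therefore use the totals row.

## Synthetic-data generator: what it emulates, what it does not

The generator defines the study conditions for all tests:

* **Weather** — stationary monthly climatology of a tropical monsoon
  regime (annual mean ≈27 °C with a weak cycle; dry sunny Dec–Apr; wet
  May–Nov totalling ≈1 650 mm/yr), daily temperature noise sd 0.8 °C,
  gamma-distributed daily rainfall (shape 0.4). Defaults live in the
  `Climatology` config object, not in code. El Niño years add +1 °C,
  +30 sunshine h/month and +25 mm/month evaporation, La Niña years
  +80 mm/month rainfall, inside the December–April window of the
  tagged calendar year (so a tagged year's WS season overlaps its
  Jan–Feb anomalous months). The daily-weather table includes an
  evaporation column so the evaporation anomaly is representable.
  Scenario deltas transform the same underlying draws, so scenarios
  are exactly paired and a null delta is bitwise-identical to
  baseline.
* **Yield panels** — linear trend plus additive noise; ENSO hazard
  seasons depressed by a known true D %; pest years depressed through
  an independent channel so tests can verify they are excluded from
  ENSO estimation; the truth table is returned for recovery tests.
* **Plot experiments** — surrogate output plus noise, with per-plot
  sowing-date temperature offsets and irrigation/rainfall multipliers
  providing the contrast that makes calibration identifiable. The
  experimental design is 8 WS / 7 SA / 4 AW plots; the packaged
  reference plot table prints 8 WS / 4 SA / 7 AW pairs, and the
  fixture mirrors the printed table cell-for-cell.
* **Risk tables** — Dirichlet fractions rounded to 0.1 and renormalised
  to sum to 100.

Not emulated: spatial correlation between provinces, serial weather
autocorrelation, wet/dry-day spell structure, typhoons and extreme
events, soil heterogeneity, and any trend in ENSO frequency. Passing
recovery tests therefore demonstrates the *estimators* are correct
under the stated noise model, not that real-delta reductions equal the
synthetic truth.

The historical ENSO calendar for 1976–2016 is not published with the
reference tables; the packaged `historical_enso_calendar.csv` is an
approximate ONI-based list (WS episodes labelled by harvest year) and
is plain replaceable configuration. The future calendar packages the
published high-probability episodes verbatim (nine El Niño WS seasons,
thirteen La Niña AW years, 2020–2050).

## Numerical choices and degenerate inputs

Seeded `numpy.random.Generator` streams derived per (seed, province,
purpose) via `SeedSequence`; no global state, no wall-clock seeds.
Printed-style rounding is decimal round-half-up (not banker's).
Degenerate inputs raise early with named cells: constant observed
series (Ef, R²), non-positive simulated yields (D), empty estimate
sets (CDF), unknown reduction levels, mismatched strata, missing
provinces, unbounded calibration spaces, seasons shorter than the crop
cycle. Equal estimates collapse classification to one band.
Problem sizes used by the test-suite simulations (300 replicate years
for anomaly convergence, 30 ENSO years for reduction recovery, 20
replicates for noisy calibration) are the package's chosen study
conditions and keep the whole suite in seconds.

## Known limitations

The surrogate has no phenology, nitrogen or soil water balance, so its
absolute yields are only as meaningful as its calibration; the
projection inherits every limitation of exogenous delta scaling (no
circulation change, no CO₂ fertilisation); reduction levels assume
future ENSO damage mirrors the historical ratios; and the demo's area
table is synthetic. The pipeline's value is the tested, deterministic
scaffolding — each scientific input (calendars, deltas, areas, level
rules) is replaceable configuration.
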