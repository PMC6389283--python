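# Methods

This note documents the models, the numerical choices, and the limits of
what the synthetic experiments can show.  Everything quantitative stated
here is computed by the test suite or the example scripts.

## Reflectance-to-LAI transfer

The transfer is piecewise in NDVI: `LAI = (NDVI − 0.28)/0.18` for
NDVI ≤ 0.7 and `LAI = 0.35·(SR − 1)` above.  Because NDVI and SR are both
monotone functions of the NIR/red ratio, the branch conditions coincide
(NDVI > 0.7 ⇔ SR > 17/3 ⇔ LAI > 2.33 on the SR branch), so exactly one
branch applies to any pixel and the map is invertible.  The two branches do
not meet exactly at the threshold — the NDVI branch reaches 2.33 while the
SR branch starts at 1.63 — and the step is left as is rather than smoothed;
with the generator's inverse the mismatch region is never emitted at zero
noise, and under noise it affects only composites that straddle the
threshold.  Output is clamped to [0, `lai_cap` = 8 m²/m²] because the SR
branch is unbounded for bright-NIR/dark-red pixels, and NDVI below the 0.28
soil intercept clamps to zero.

## LAD-logistic fitting

Composite LAI samples are accumulated by a rectangle rule whose interval is
the DOY gap to the previous sample (a missing composite widens the weight of
its successor; the first sample carries the nominal 8-day interval).  The
three-parameter logistic is fit by bounded trust-region least squares on the
cumulative curve.  Starting values follow the data (`b3₀ = 1.1·max LAD`,
`b2₀` at the steepest increase, `b1₀ = 4·max slope/b3₀`) with up to five
seeded, jittered restarts.  An increment-space (whitened) objective and a
1/LAI-weighted variant were evaluated and rejected: on trajectories that are
not exactly logistic the shape mismatch dominates at the low-signal tails,
and both alternatives measurably increased the variance of the fitted peak.
Fits whose inflection `b2` falls beyond the last composite used are returned
but flagged `low_confidence` — truncating the series before the LAI peak
(EOD 209) leaves the inflection poorly constrained.

## Planting-date model and its calibration

`D = b2 + τ + ρ/b1` with one (τ, ρ) pair per EOD.  The packaged default
pairs (−4.73/0.96, −10.74/0.06, −8.77/0.36 for EOD 209/257/321) are the
published calibration for the original MODIS/Illinois survey data.  Note
what those constants imply: with ρ/b1 of a few days, the predicted planting
falls within ~10 days of the peak-LAI date `b2`.  In any mechanistically
consistent world, maize plants 60–90 days before peak LAI, so the default
pairs cannot recover the planting date of a simulated season — they encode
a statistical relation specific to their source data.  The model *form* is
portable; the constants are not.  `calibrate_planting_params` therefore
refits (τ, ρ) by ordinary least squares of `D − b2` on `1/b1`, and all
synthetic recovery experiments use a calibration obtained from a
seed-disjoint batch of generator scenarios.  With that calibration the
20-scenario protocol at EOD 321 recovers planting with a median absolute
error of ~3.5 days (RMSE ~5 days), comparable to the ~7-day survey-scale
validation the model family reports.

## The daily growth simulator

The simulator keeps the CERES-Maize state variables and printed equations —
leaf expansion `PLAG = 3.0·XN²·TI·min(TURFAC, 1−SATFAC, PSTRES2, KSTRES)`,
leaf weight `GROLF = 0.00116·PLAG·PLA^0.25`, the stage-3 area
reconstruction `PLA = LFWT^0.8·267.0` (read as the exact inverse of the
leaf-weight allometry), senescence `PLAS = (PLA−SENLA)·(1−SLFW)` with
`SLFW = 0.95 + 0.05·SWFAC` (FSLFW = 0.05), stress factors
`TURFAC = min(1, r/RWUEP1)`, `SWFAC = min(1, r)` with `r = TRWUP/EP1` and
RWUEP1 = 1.5, grain growth
`GROGRN = RGFILL·GPP·G3·0.001·(0.45 + 0.55·SWFAC)` and
`YIELD = GRNWT·10·EARS` — with every non-water stress factor (nitrogen,
phosphorus, potassium, water-logging, light, temperature senescence)
identically 1.0.  Water supply is the only stress.  Fertilizer events are
accepted and logged but have no physiological effect, consistent with that
assumption; photoperiod sensitivity P2 is carried in the coefficient type
but unused (constant-daylength assumption).

Around those equations sit simplified components, chosen once and
config-overridable:

- **Thermal time**: `max(0, min(Tmean, 34) − 8)` °C·day (base 8 °C, mean
  capped at 34 °C).
- **Phenology**: emergence 5 days after planting; juvenile phase ends at P1;
  tassel initiation after a further 2 phyllochrons; leaf growth ends when
  the leaf count XN (advancing by dtt/PHINT) reaches the total leaf number
  `TLNO = 12 + P1/21` (19.6–24.4 leaves across the five classes — the range
  real hybrids carry); effective grain fill starts 170 °C·day after end of
  leaf growth; physiological maturity (terminal stage 6) at P5 °C·day after
  silking.
- **Top-leaf plateau**: the XN² term of PLAG saturates at `xn_area_cap` = 12
  (~430 cm² per phyllochron), reflecting that upper-canopy leaf area stops
  growing leaf by leaf; without it the quadratic accumulates to a peak LAI
  near 16, far outside the maize range.  With it, unstressed peak LAI runs
  3.7 (PC0001) to 5.2 (PC0005) at 7.41 plants/m².
- **Soil water**: a tipping-bucket balance — infiltration cascades top-down,
  each layer holding at most its drained upper limit; transpiration demand
  EP1 is a Priestley–Taylor-style radiation/temperature estimate scaled by
  `min(1, LAI)`; potential uptake TRWUP is 0.3/day of each layer's
  plant-available water weighted by its root factor; actual extraction is
  `min(EP1, TRWUP)` removed proportionally.  The uptake rate is set so that
  a profile at the 0.5 auto-irrigation trigger still meets 1.5× demand,
  which makes the auto-irrigation mode genuinely unstressed (TURFAC = SWFAC
  = 1 all season) — a property the orderings below rely on.
- **Auto-irrigation**: refill to the drained upper limit whenever the
  plant-available fraction drops below 0.5; events are logged.
- **Grain**: `GPP = G2` (potential kernels, no kernel-number stress),
  `EARS = PLTPOP` (one ear per plant), RGFILL a trapezoid in daily mean
  temperature (0 at ≤6 °C, 1 between 16 and 32 °C, 0 at ≥44 °C).

Because kernel number and assimilate supply never limit the sink, simulated
yields are *water-limited potential* yields — tens of t/ha under full
irrigation, roughly double typical reported farm yields.  Every comparison
the package makes (configuration orderings, recovery experiments, closure)
is internal to the same model, so this offset cancels; absolute yield levels
should not be read against survey statistics.

## Stress back-estimation

For each day *d* of the stress window (5 days after planting to 5 days
before simulated physiological maturity), the season is re-simulated from
planting with all previously estimated daily LAI and stress factors forced
on days < *d* — the literal day-by-day loop, quadratic in season length
(~120 prefix simulations for a 150-day season, well under a second); a
`single_pass` flag estimates every day from one unforced run instead.
Stage rules:

- Stages 1–2: `TURFAC_est = (ΔLAI_obs/ΔLAI_sim)·TURFAC_sim`,
  `SWFAC_est = 1.5·TURFAC_est`.
- Stage 3: the same ratio on leaf-weight increments (LFWT_RS from the
  allometry).
- Stages 4–6: `SWFAC_est = 1 − (−ΔLAI_obs,pp/PLAS)·(1 − SWFAC_sim)`,
  `TURFAC_est = SWFAC_est/1.5`, with ΔLAI converted to per-plant cm²
  before dividing by PLAS (the units force this conversion).

All factors clamp to [0, 1].  Degenerate days: when the simulated leaf
increment is below 1e-6 in stages 1–3 the ratio is undefined and the
previous day's estimate is carried forward.  In stages 4–6 the simulated
PLAS vanishes exactly when SWFAC_sim = 1, and the senescence model gives the
update a well-defined analytic limit,
`SWFAC_est = 1 − (−ΔLAI_obs,pp)/(FSLFW·(PLA−SENLA))`, which is used
directly.  This limit matters twice over: a flat observation yields 1
(keeping the closure property exact), and a declining observation registers
stress even against an irrigated simulation that never senesces — without
it, the `stress_auto` configuration would be unable to see drought at all
after flowering.

**Closure.**  Factors extracted from a simulator-generated truth trajectory
and forced back in reproduce the truth yield to well within 1% (measured:
exact to machine rounding), because on each day the forced prefix places the
model in the truth state and the ratio collapses to 1.  The estimate for
day *d* depends only on observations up to *d* (verified by truncation).

One systematic artifact: at the stage-2→3 transition the area bookkeeping
jumps onto the `LFWT^0.8` curve, so the first stage-3 day's increment ratio
deviates from 1 even on truth observations (~10% for one day); it is
harmless because LAI forcing resets the state the next day.

## Maturity-group selection

The selector compares the fit-derived maximum daily LAI
(`LAD(b2) − LAD(b2−1)`) against each candidate class's simulated season
maximum and takes the smallest absolute difference (one comparison, so the
RMSE of the matching rule reduces to |difference|; ties go to the
lowest-numbered class).  Two estimator refinements are applied by default
and were decisive in testing:

1. **Matched observation operator.**  The candidate's maximum is not read
   off the raw trajectory but passed through the same estimator as the
   observations: a linear 30-day post-maturity dry-down (the optical sensor
   keeps seeing drying leaves after physiological maturity), sampling on the
   observed composite DOYs, LAD accumulation, and the same logistic fit.
   The raw comparison is biased low by ~15–20% because a logistic derivative
   cannot hold a plateau, and the bias moves the selection one to two
   classes early.
2. **Noise matching.**  Composite noise inflates the LAD tails and widens
   the fitted logistic, depressing the observed maximum by ~3% on average.
   Candidates are therefore evaluated as the mean fitted maximum over five
   seeded realizations of the nominal composite noise (cv 0.05), making the
   two sides of the comparison identically distributed.

With both refinements the comparison is unbiased, and at zero observation
noise it recovers the truth class deterministically.  Under the nominal
noise (cv 0.05 per band, 10% missing composites) the recovery rate over
seeded scenarios is ~70–77%, with every miss an adjacent GDD class.  The
limit is informational, not implementational: adjacent classes differ by
~8% in the maximum-LAI statistic (the five classes differ mainly in P1),
while the statistic's noise-induced standard deviation is ~4%, so ~2σ
separates neighbours.  A ≥90% exact-class requirement is not reachable from
a single season's max-LAI statistic at this noise level; the corresponding
acceptance test is left failing rather than weakened, and the measured rate
is the honest headline.  Full-curve RMSE selection was evaluated as an
alternative statistic and rejected: the shape mismatch between the logistic
derivative and the plateaued trajectory biases it systematically toward
early classes (11/30 recovery).

## Synthetic data

Generators are pure functions of (seed, parameters).  Weather: sinusoidal
annual temperature cycle (mean 11 °C, amplitude 14 °C, peak DOY 196) with
Gaussian noise, radiation from a clear-sky seasonal envelope times a cloud
factor, and rain as a wet-day process (45% wet days, gamma amounts, mean
6 mm) targeting the 800–1200 mm annual band; a drought specification
multiplies rain in a window by a suppression factor and brightens/warms
those days.  Soils: 4–6 layers with LL < DUL < SAT drawn from silt-loam
ranges, exponentially decaying root factors, organic carbon derived from
organic matter by the 0.4724 linear conversion.  Reflectance: the exact
inverse of the LAI transfer (NIR on a 0.35→0.50 seasonal baseline, red
solved from the target NDVI or SR), sampled every 8 days over DOY 89–329,
independent multiplicative noise per band (default cv 0.05), composites
dropped at 10%.  Scenario truths are rain-fed simulator runs (plus optional
drought and irrigation events) with a linear 30-day post-maturity dry-down
appended for the sensor's benefit; scenario planting dates respect
agronomic feasibility caps per maturity class (longer-season hybrids plant
earlier, DOY 112–148 overall).

What the generator does *not* emulate — and therefore what passing tests do
not show about real data: atmospheric and BRDF residuals with non-Gaussian,
band-correlated structure; mixed pixels and non-corn land cover; real
cultivar diversity within a GDD class; nutrient and pest stress; and any
discrepancy between the simulator's own growth equations and real canopies.
The recovery experiments demonstrate that the estimation machinery inverts
its forward model under realistic observation noise, not that the forward
model matches fields.

## Evaluation

R² is the squared Pearson correlation (the regression-scatter convention),
RMSE the root mean squared difference, NRMSE = RMSE·100/mean(observed) with
quality bands excellent (<10%), good (<20%), fair (<30%), poor (above);
band boundaries fall to the better class since the strict inequalities leave
them undefined.  Aggregation to regions is the unweighted mean, with
optional per-grid area weights.

## Problem sizes

The default protocols use one 365-day season per scenario, 20 scenarios for
the recovery and drought experiments, 20–30 seed-disjoint scenarios for the
phenology calibration, and 5 noise draws per maturity candidate; the full
day-by-day stress loop re-simulates ~120 prefixes per season.  These sizes
keep any single experiment under a minute on one core while leaving the
statistics stable to reseeding.
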