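# maizeassim

Forcing-based assimilation of satellite-derived leaf area index (LAI) into a
simplified CERES-Maize daily growth model, for regional corn yield
prediction from minimum inputs.

## The problem

Crop growth models need inputs that are rarely known at regional scale —
planting date, cultivar maturity, and above all the day-by-day water status
of fields that may or may not be irrigated.  Optical satellites see the
canopy every few days but say nothing about causes.  This package implements
a simple assimilation strategy that connects the two: everything the model
is missing is estimated from the seasonal trajectory of satellite LAI and
*forced* into the model, with no ensemble filtering and no per-site
calibration loop.

The pipeline, per 1-km grid cell:

1. **Reflectance → LAI.**  8-day red/NIR composites (DOY 89–329) become LAI
   through a piecewise transfer: `LAI = (NDVI − 0.28)/0.18` for NDVI ≤ 0.7,
   and `LAI = 0.35·(SR − 1)` above it, where `NDVI = (NIR−red)/(NIR+red)`
   and `SR = NIR/red`.
2. **LAD-logistic fit.**  Cumulative leaf area duration is fit with
   `LAD(t) = b3 / (1 + exp(−b1·(t − b2)))` — `b1` the LAI growth rate
   (day⁻¹), `b2` the DOY of maximum daily LAI, `b3` the cumulative LAI at
   physiological maturity.  The derivative of the fit is the daily LAI
   curve `LAI_RS(d)`, and `LFWT_RS = (LAI_RS/PLTPOP/0.0001/267)^1.25` gives
   per-plant leaf weight.
3. **Planting date.**  `D = b2 + τ + ρ/b1`, with a (τ, ρ) pair per EOD (the
   last DOY of data used: 209, 257 or 321).
4. **Maturity group.**  Each of five generic hybrid classes (P1, P2, P5,
   G2, G3, PHINT) is simulated; the class whose season-maximum LAI best
   matches the fit-derived maximum `LAD(b2) − LAD(b2−1)` is selected.
5. **Water-stress back-estimation.**  For every day *d* of the season the
   model is re-run from planting with all previously estimated daily LAI and
   stress factors forced; the ratio of observed to simulated leaf growth on
   day *d* rescales the simulated stress factor
   (`TURFAC_est = ΔLAI_obs/ΔLAI_sim · TURFAC_sim` during leaf growth,
   `SWFAC_est = 1.5·TURFAC_est`; an analogous senescence-based update after
   flowering), clamped to [0, 1].
6. **Forced yield run and evaluation.**  Four configurations —
   `default_rain`, `default_auto`, `stress_rain`, `stress_auto` — cross the
   two water modes with and without stress/LAI forcing; yields aggregate to
   region means and are scored with R², RMSE and NRMSE.

The daily simulator implements the CERES-Maize leaf growth
(`PLAG = 3·XN²·TI·TURFAC`, `GROLF = 0.00116·PLAG·PLA^0.25`), senescence
(`SLFW = 0.95 + 0.05·SWFAC`), water stress (`TURFAC = min(1, r/1.5)`,
`SWFAC = min(1, r)` for supply/demand ratio `r = TRWUP/EP1`), and grain
equations (`GROGRN = RGFILL·GPP·G3·0.001·(0.45 + 0.55·SWFAC)`,
`YIELD = GRNWT·10·EARS`), with every non-water stress factor fixed at 1 and
documented simplified components for thermal time, phenology phases, and a
tipping-bucket soil water balance (see `docs/methods.md`).

A first-class synthetic-data module generates seeded weather, soils and
reflectance from known-truth simulated seasons, so the whole pipeline is
testable without any external data.

## Worked example

```python
import maizeassim as ma

spec = ma.ScenarioSpec(planting_doy=125, maturity_group="PC0003",
                       drought=ma.DroughtSpec(start_doy=185, end_doy=225, factor=0.1))
bundle = ma.gen_scenario(seed=11, spec=spec)
truth = bundle.truth_result
observed = dict(zip(truth.trace["doy"].astype(int), truth.trace["lai"]))

series = ma.estimate_stress_series(observed, 125, truth.coefficients,
                                   bundle.weather, bundle.soil,
                                   bundle.management, water_mode="rain_fed")
forced = ma.run_assimilated_yield(series, bundle.weather, bundle.soil,
                                  bundle.management, truth.coefficients,
                                  water_mode="rain_fed")
print(truth.yield_kg_ha, forced.yield_kg_ha)
```

Running `python examples/estimate_water_stress.py` (this scenario) prints:

```
stress window DOY 130-251 (122 days re-simulated)
estimated SWFAC: min 0.19, days below 0.9: 40
truth yield (rain-fed, drought):    18116 kg/ha
stress-forced run:                  18116 kg/ha (closure error 0.00%)
irrigated run, no assimilation:     23175 kg/ha
```

The drought drove the photosynthesis stress factor SWFAC as low as 0.19;
forcing the back-estimated factors and daily LAI into the model reproduces
the truth yield exactly (the estimation loop inverts the forward model),
while the irrigated run that ignores the observations overestimates yield by
~28%.  The other scripts in `examples/` walk through season simulation, the
LAD fit, the recovery experiments and the evaluation statistics, one
capability each.

A thin CLI mirrors the library (`maizeassim synth | fit | plant-date |
maturity | stress | simulate | evaluate | run-all`); every stage writes the
CSV/JSON its successor reads, and `run-all --seed N` is byte-reproducible.

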