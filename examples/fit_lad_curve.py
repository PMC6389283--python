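"""Fit the LAD-logistic to a satellite reflectance series.

Builds a known-truth scenario (the simulator's season encoded as noisy 8-day
red/NIR composites), converts reflectance to LAI, accumulates leaf area
duration, fits LAD(t) = b3 / (1 + exp(-b1 (t - b2))), and reads the derived
quantities off the fit: peak daily LAI and the estimated planting date.
"""

import maizeassim as ma
from maizeassim.experiments import calibrate_synthetic_phenology

spec = ma.ScenarioSpec(planting_doy=128, maturity_group="PC0003")
bundle = ma.gen_scenario(seed=4, spec=spec)

lai = bundle.reflectance.to_lai()
doy, lad = ma.cumulative_lad(lai)
fit = ma.fit_lad_logistic(doy, lad, eod=321, seed=4)

print(f"composites used: {fit.n_points} (noise cv 5%, 10% missing)")
print(f"b1 = {fit.b1:.4f} /day   (LAI growth rate)")
print(f"b2 = {fit.b2:.1f} DOY    (date of maximum daily LAI)")
print(f"b3 = {fit.b3:.1f} m2/m2*day (cumulative LAI at maturity)")
print(f"fit-derived peak LAI LAD(b2)-LAD(b2-1) = {ma.max_lai_from_fit(fit):.2f}"
      f"  (truth trajectory peak {bundle.truth_result.max_lai():.2f})")

# The planting-date model D = b2 + tau + rho/b1 needs a (tau, rho) pair
# calibrated for the world the observations come from; here that world is
# the synthetic generator, so calibrate on a disjoint batch of its scenarios.
params = calibrate_synthetic_phenology(eod=321, n=20, seed0=900)
est = ma.estimate_planting_date(fit, params)
print(f"estimated planting DOY {est.doy} (truth {spec.planting_doy})")
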