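"""Run the daily maize growth simulator for one season.

Generates a year of corn-belt weather and a layered soil profile, plants a
mid-maturity hybrid in mid-May, and simulates the season under both water
modes.  The yield gap between the two runs is what water supply cost the
rain-fed crop.
"""

import maizeassim as ma

weather = ma.gen_weather(seed=1)
soil = ma.gen_soil(seed=101)
mgmt = ma.Management(planting_doy=135)          # ~May 15
coeffs = ma.get_genetic_coefficients("PC0003")  # 2650-2700 GDD class

for mode in ("rain_fed", "auto_irrigation"):
    res = ma.simulate_season(weather, soil, mgmt, coeffs, water_mode=mode)
    t = res.trace
    print(f"{mode:16s} maturity DOY {res.maturity_doy}  "
          f"yield {res.yield_kg_ha:8.0f} kg/ha  "
          f"peak LAI {t['lai'].max():.2f}  "
          f"min SWFAC {t['swfac'].min():.2f}")

# Yield is grain weight per plant * 10 * ears per m2 at physiological
# maturity; it is a water-limited potential (no nutrient or kernel-number
# stress), so the irrigated number is an upper bound, and the rain-fed
# shortfall measures the season's water stress.
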