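{
  "description": "Crop phenology prediction model parameters for planting date, D = b2 + tau + rho/b1, by EOD (last DOY of satellite data used in the LAD-logistic fit). tau: offset (days) from the peak-LAI date b2 to the stage; rho: effect of the LAI growth rate (dimensionless).",
  "planting": {
    "209": {"tau": -4.73, "rho": 0.96},
    "257": {"tau": -10.74, "rho": 0.06},
    "321": {"tau": -8.77, "rho": 0.36}
  }
}
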