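{
  "description": "DSSAT 4.6 generic corn hybrid coefficients by maturity group (GDD class). P1: thermal time emergence to end of juvenile phase (degree day, Tbase 8C). P2: photoperiod sensitivity (days hr^-1; carried but unused, constant-daylength assumption). P5: thermal time silking to physiological maturity (degree day). G2: potential kernel number (kernels plant^-1). G3: potential kernel filling rate (mg kernel^-1 day^-1). PHINT: phyllochron interval (degree day per leaf tip).",
  "groups": [
    {"var_id": "PC0001", "name": "2500-2600 GDD", "p1": 160.0, "p2": 0.75, "p5": 780.0, "g2": 750.0, "g3": 8.5, "phint": 49.0},
    {"var_id": "PC0002", "name": "2600-2650 GDD", "p1": 185.0, "p2": 0.75, "p5": 850.0, "g2": 800.0, "g3": 8.5, "phint": 49.0},
    {"var_id": "PC0003", "name": "2650-2700 GDD", "p1": 212.0, "p2": 0.75, "p5": 850.0, "g2": 800.0, "g3": 8.5, "phint": 49.0},
    {"var_id": "PC0004", "name": "2700-2750 GDD", "p1": 240.0, "p2": 0.75, "p5": 850.0, "g2": 800.0, "g3": 8.5, "phint": 49.0},
    {"var_id": "PC0005", "name": "2750-2800 GDD", "p1": 260.0, "p2": 0.75, "p5": 850.0, "g2": 800.0, "g3": 8.5, "phint": 49.0}
  ]
}
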