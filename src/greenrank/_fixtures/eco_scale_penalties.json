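{
  "_comment": "Default Eco-Scale penalty-point table, adapted from the cited Eco-Scale reference (Galuszka et al., analytical Eco-Scale), NOT from the survey this package accompanies. Edit freely; penalties are plain inputs to eco_scale().",
  "reagent_amount": {
    "lt_10": 1,
    "10_to_100": 2,
    "gt_100": 3
  },
  "reagent_hazard_per_pictogram": {
    "warning": 1,
    "danger": 2
  },
  "instrument_energy_kwh_per_sample": {
    "le_0.1": 0,
    "le_1.5": 1,
    "gt_1.5": 2
  },
  "occupational_hazard": {
    "hermetic": 0,
    "vapour_emission": 3
  },
  "waste_amount": {
    "none": 0,
    "lt_1_g": 1,
    "1_to_10_g": 3,
    "gt_10_g": 5
  },
  "waste_treatment": {
    "recycling": 0,
    "degradation": 1,
    "passivation": 2,
    "none": 3
  }
}
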