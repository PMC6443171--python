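{
  "label": "hau_cohort60",
  "description": "H. austinensis, interbreeding cohort of 60 on bloodworm diet. Three rounds of 60, 54 and 31 clutches; 145 clutches, 6055 embryos in total.",
  "n_individuals": 60,
  "s_counts": [60, 54, 31],
  "zd_c1": {"mean": 109.7, "sd": 19.3, "min": 70, "max": 143},
  "inter_clutch": [
    {"mean": 80, "sd": 28.3, "min": 1},
    {"mean": 83, "sd": 57.2, "min": 1}
  ],
  "clutch_size": [
    {"mean": 43.8, "sd": 20.8, "min": 6, "max": 117},
    {"mean": 41.5, "sd": 22.4, "min": 7, "max": 93},
    {"mean": 38.9, "sd": 25.2, "min": 6, "max": 97}
  ],
  "cum_intervals": [
    {"mean": 109.7, "sd": 19.3, "min": 70, "max": 143},
    {"mean": 189.8, "sd": 28.3, "min": 144, "max": 234},
    {"mean": 273.1, "sd": 57.2, "min": 237, "max": 346}
  ],
  "interval_s_counts": [60, 54, 31],
  "post_last_survival": {"mean": 100, "sd": 40, "min": 0},
  "lifespan": {"mean": 380, "sd": 60, "min": 0},
  "notes": {
    "post_last_survival": "25 animals were still alive through the final 105 reproduction-free days of the experiment; mean/SD chosen, not reported",
    "lifespan": "chosen; the experiment ran 452 days. Used only for never-laying animals"
  }
}
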