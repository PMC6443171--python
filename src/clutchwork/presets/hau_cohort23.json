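{
  "label": "hau_cohort23",
  "description": "H. austinensis, interbreeding cohort of 23 on bloodworm diet. Two full rounds (23 and 16 clutches) plus a single third-round clutch; 40 clutches, 3591 embryos in total.",
  "n_individuals": 23,
  "s_counts": [23, 16, 1],
  "zd_c1": {"mean": 109.3, "sd": 20.4, "min": 80, "max": 148},
  "inter_clutch": [
    {"mean": 79, "sd": 36.6, "min": 1},
    {"mean": 55, "sd": 0, "min": 1}
  ],
  "clutch_size": [
    {"mean": 94.2, "sd": 41.0, "min": 45, "max": 179},
    {"mean": 87.4, "sd": 36.2, "min": 22, "max": 160},
    {"mean": 26, "sd": 0, "min": 26, "max": 26}
  ],
  "cum_intervals": [
    {"mean": 109.3, "sd": 20.4, "min": 80, "max": 148},
    {"mean": 188.4, "sd": 36.6, "min": 148, "max": 240},
    {"mean": 243, "sd": 0, "min": 243, "max": 243}
  ],
  "interval_s_counts": [23, 16, 1],
  "post_last_survival": {"mean": 100, "sd": 40, "min": 0},
  "lifespan": {"mean": 350, "sd": 60, "min": 0},
  "notes": {
    "post_last_survival": "the last animals survived well over 100 d after the final clutch; mean/SD chosen, not reported",
    "lifespan": "chosen; used only for never-laying animals"
  }
}
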