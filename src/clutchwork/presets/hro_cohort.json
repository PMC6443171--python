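{
  "label": "hro_cohort",
  "description": "H. robusta, interbreeding cohort of 48 on snail diet. Per-round clutch sizes and timings inferred by the round-counting rule; five rounds of 48, 34, 28, 26, 13 clutches.",
  "n_individuals": 48,
  "s_counts": [48, 34, 28, 26, 13],
  "zd_c1": {"mean": 107.4, "sd": 10.7, "min": 94, "max": 134},
  "inter_clutch": [
    {"mean": 40, "sd": 11.1, "min": 1},
    {"mean": 48, "sd": 11.0, "min": 1},
    {"mean": 36, "sd": 13.2, "min": 1},
    {"mean": 32, "sd": 9.2, "min": 1}
  ],
  "clutch_size": [
    {"mean": 24.0, "sd": 10.0, "min": 11, "max": 65},
    {"mean": 44.6, "sd": 16.8, "min": 15, "max": 85},
    {"mean": 68.4, "sd": 18.4, "min": 21, "max": 102},
    {"mean": 75.3, "sd": 18.5, "min": 29, "max": 114},
    {"mean": 48.1, "sd": 22.3, "min": 17, "max": 85}
  ],
  "cum_intervals": [
    {"mean": 107.4, "sd": 10.7, "min": 94, "max": 134},
    {"mean": 146.8, "sd": 11.1, "min": 135, "max": 170},
    {"mean": 184.9, "sd": 11.0, "min": 171, "max": 204},
    {"mean": 221.1, "sd": 13.2, "min": 204, "max": 241},
    {"mean": 252.8, "sd": 9.2, "min": 241, "max": 276}
  ],
  "interval_s_counts": [48, 34, 28, 26, 13],
  "post_last_survival": {"mean": 20, "sd": 10, "min": 0, "max": 34},
  "lifespan": {"mean": 270, "sd": 30, "min": 0},
  "notes": {
    "post_last_survival": "the cohort collapsed quickly after its fifth bout; the last survivor died 34 d after the final clutch, taken as the upper bound. Mean/SD chosen, not reported",
    "lifespan": "chosen as final-round day (~253) plus post-last survival; used only for never-laying animals"
  }
}
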