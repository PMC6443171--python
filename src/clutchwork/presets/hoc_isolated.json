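{
  "label": "hoc_isolated",
  "description": "H. octatestisaca, self-fertilizing individuals reared in isolation, bloodworm diet (N=5). At most three clutches; long generation time (140 d).",
  "n_individuals": 5,
  "s_counts": [5, 5, 3],
  "zd_c1": {"mean": 140.0, "sd": 25.8, "min": 120, "max": 180},
  "inter_clutch": [
    {"mean": 21, "sd": 37.7, "min": 1},
    {"mean": 60, "sd": 43.2, "min": 1}
  ],
  "clutch_size": [
    {"mean": 26.4, "sd": 7.5, "min": 17, "max": 37},
    {"mean": 50.2, "sd": 12.7, "min": 33, "max": 66},
    {"mean": 70.3, "sd": 4.7, "min": 65, "max": 74}
  ],
  "cum_intervals": [
    {"mean": 140.0, "sd": 25.8, "min": 120, "max": 180},
    {"mean": 160.8, "sd": 37.7, "min": 137, "max": 227},
    {"mean": 220.8, "sd": 43.2, "min": 191, "max": 270}
  ],
  "interval_s_counts": [5, 4, 3],
  "post_last_survival": {"mean": 49, "sd": 25, "min": 0},
  "lifespan": {"mean": 246, "sd": 40, "min": 0},
  "notes": {
    "post_last_survival": "mean chosen as reported mean lifespan (246 d) minus the expected last-clutch day under this preset (~197 d); several animals survived long after their last clutch. SD chosen, not reported",
    "lifespan": "reported mean 246 d; SD chosen, not reported"
  }
}
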