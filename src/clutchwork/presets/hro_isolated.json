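{
  "label": "hro_isolated",
  "description": "H. robusta, self-fertilizing individuals reared in isolation, snail diet (N=16). Clutch-size rows C1..C8 and interval rows from the published summary tables; inter-clutch step SDs are not printed, so the later clutch's cumulative-day SD stands in as the spread proxy.",
  "n_individuals": 16,
  "s_counts": [10, 14, 14, 11, 11, 9, 6, 1],
  "zd_c1": {"mean": 56.3, "sd": 8.7, "min": 37, "max": 68},
  "inter_clutch": [
    {"mean": 28, "sd": 7.7, "min": 1},
    {"mean": 23, "sd": 10.5, "min": 1},
    {"mean": 30, "sd": 9.9, "min": 1},
    {"mean": 33, "sd": 16.0, "min": 1},
    {"mean": 29, "sd": 17.2, "min": 1},
    {"mean": 44, "sd": 29.6, "min": 1},
    {"mean": 21, "sd": 0, "min": 1}
  ],
  "clutch_size": [
    {"mean": 20.3, "sd": 4.1, "min": 15, "max": 25},
    {"mean": 51.1, "sd": 16.3, "min": 3, "max": 70},
    {"mean": 71.1, "sd": 19.5, "min": 34, "max": 99},
    {"mean": 77.6, "sd": 19.9, "min": 55, "max": 104},
    {"mean": 69.1, "sd": 23.5, "min": 30, "max": 105},
    {"mean": 51.0, "sd": 30.7, "min": 7, "max": 95},
    {"mean": 44.2, "sd": 27.3, "min": 12, "max": 81},
    {"mean": 13, "sd": 0, "min": 13, "max": 13}
  ],
  "cum_intervals": [
    {"mean": 56.3, "sd": 8.7, "min": 37, "max": 68},
    {"mean": 83.5, "sd": 7.7, "min": 72, "max": 93},
    {"mean": 107.4, "sd": 10.5, "min": 92, "max": 121},
    {"mean": 136.8, "sd": 9.9, "min": 117, "max": 150},
    {"mean": 170.4, "sd": 16.0, "min": 142, "max": 193},
    {"mean": 199.4, "sd": 17.2, "min": 169, "max": 222},
    {"mean": 243.3, "sd": 29.6, "min": 217, "max": 295},
    {"mean": 264, "sd": 0, "min": 264, "max": 264}
  ],
  "interval_s_counts": [15, 15, 14, 12, 10, 8, 5, 1],
  "post_last_survival": {"mean": 33, "sd": 20, "min": 0},
  "lifespan": {"mean": 229, "sd": 40, "min": 0},
  "notes": {
    "post_last_survival": "mean chosen as reported mean lifespan (229 d) minus the expected last-clutch day under this preset (~196 d); SD chosen, not reported",
    "lifespan": "reported mean 229 d; SD chosen, not reported"
  }
}
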