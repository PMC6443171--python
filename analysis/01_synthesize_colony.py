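"""Generate the synthetic colony: one ground-truth dataset per parameter
preset, written under results/data/<preset>/.

The raw per-animal records behind the published tables were never
deposited, so every downstream analysis here runs on synthetic records
drawn from the printed moments, with true clutch labels carried alongside.
"""

from pathlib import Path

from clutchwork.synthetic_data import PRESETS, generate_dataset, make_params

SEED = 20190401
OUT = Path(__file__).resolve().parent.parent / "results" / "data"

# cohort sizes matched to the corresponding experiments
N_BY_PRESET = {
    "hro_isolated": 16,
    "hro_cohort": 48,
    "hoc_isolated": 5,
    "hau_cohort23": 23,
    "hau_cohort60": 60,
}


def main():
    for preset in PRESETS:
        n = N_BY_PRESET[preset]
        ds = generate_dataset(make_params(preset), n=n, seed=SEED,
                              outdir=OUT / preset)
        print(
            f"{preset:13s} n={n:3d}: {len(ds.cohort.clutches):4d} clutches, "
            f"{ds.cohort.total_embryos:6d} embryos -> results/data/{preset}/"
        )


if __name__ == "__main__":
    main()
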