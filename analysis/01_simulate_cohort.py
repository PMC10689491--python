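"""Simulate a small synthetic cohort of recorded neurons.

Generates 4 wild-type-like and 4 knockout-like cells (spontaneous epoch,
40-trial stimulation block, current-step protocol for one cell per group)
with paired seeds, stores the HDF5 bundles under scratch/cohort/, and writes
the startle-response table to results/startle_table.csv.
"""

import sys
from pathlib import Path

from vmvar import io as vio
from vmvar import pipeline, synth

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

N_PER_GROUP = 4
FS = 10000.0
DURATION_SPONT = 60.0
BASE_SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 7


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)
    for group, preset in (("wt", "wt_like"), ("ko", "ko_like")):
        for i in range(N_PER_GROUP):
            params = synth.genotype_presets(
                preset, fs=FS, duration_spont=DURATION_SPONT, seed=BASE_SEED + i
            )
            bundle = pipeline.simulate_cell(
                params, f"{group}_{i:02d}", group, with_protocol=(i == 0)
            )
            stem = SCRATCH / f"{group}_{i:02d}"
            vio.write_bundle(bundle.spont, stem.with_suffix(".spont.h5"))
            vio.write_bundle(bundle.trials, stem.with_suffix(".trials.h5"))
            if bundle.protocol is not None:
                vio.write_bundle(bundle.protocol, stem.with_suffix(".protocol.h5"))
            print(f"wrote {stem.name}: {DURATION_SPONT:.0f}-s spontaneous epoch, "
                  f"{bundle.trials.n_trials} trials")

    startle = synth.generate_startle_table(
        n_animals=10,
        group_params={
            "wt": dict(mean=100.0, slope_per_db=5.0, animal_sd=8.0, trial_sd=8.0),
            "ko": dict(mean=100.0, slope_per_db=5.0, animal_sd=16.0, trial_sd=16.0),
        },
        seed=BASE_SEED,
    )
    out = RESULTS / "startle_table.csv"
    startle.to_csv(out, index=False)
    print(f"wrote {out.relative_to(ROOT)}: {startle['animal_id'].nunique()} animals, "
          f"{len(startle)} trials")


if __name__ == "__main__":
    main()
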