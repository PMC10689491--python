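"""Run the per-cell pipeline over the simulated cohort.

Reads the HDF5 bundles written by 01_simulate_cohort.py, extracts every
state/spectral/EPSP/AP/intrinsic parameter per neuron, and writes the
neurons-by-parameters table to results/cohort_table.csv.
"""

from pathlib import Path

import pandas as pd

from vmvar import io as vio
from vmvar import pipeline

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

CONFIG = pipeline.AnalysisConfig(seg_epoch=60.0, spont_window=60.0)


def load_bundles() -> list[pipeline.CellBundle]:
    bundles = []
    for spont_path in sorted(SCRATCH.glob("*.spont.h5")):
        stem = spont_path.name.replace(".spont.h5", "")
        group = stem.split("_")[0]
        trials_path = SCRATCH / f"{stem}.trials.h5"
        protocol_path = SCRATCH / f"{stem}.protocol.h5"
        bundles.append(
            pipeline.CellBundle(
                cell_id=stem,
                group=group,
                spont=vio.read_bundle(spont_path),
                trials=vio.read_bundle(trials_path) if trials_path.exists() else None,
                protocol=vio.read_bundle(protocol_path) if protocol_path.exists() else None,
            )
        )
    return bundles


def main() -> None:
    bundles = load_bundles()
    if not bundles:
        raise SystemExit("no bundles found; run analysis/01_simulate_cohort.py first")
    rows = []
    for bundle in bundles:
        summary = pipeline.run_cell(bundle, CONFIG)
        rows.append(summary.to_row())
        n_absent = len(summary.absent)
        print(f"{bundle.cell_id}: {len(summary.params)} parameters"
              + (f" ({n_absent} absent)" if n_absent else ""))
    table = pd.DataFrame(rows)
    out = RESULTS / "cohort_table.csv"
    table.to_csv(out, index=False)
    print(f"wrote {out.relative_to(ROOT)} with {len(table)} neurons x "
          f"{len(table.columns) - 2} parameters")
    for col in ("baseline_sd", "tbt_sd_amplitude", "up_freq", "micro_count"):
        if col in table:
            by_group = table.groupby("group")[col].mean()
            print(f"  mean {col}: " + ", ".join(
                f"{g}={v:.3g}" for g, v in by_group.items()))


if __name__ == "__main__":
    main()
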