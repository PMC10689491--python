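"""Trial-by-trial and inter-individual variability of startle responses.

Reads results/startle_table.csv (animal x intensity x trial responses),
computes the per-animal trial SD at each sound intensity, compares groups with
the mixed (repeated-measures) ANOVA over intensities, and tests
inter-individual variance per intensity with the Bartlett test. Writes
results/startle_report.json.
"""

import json
from pathlib import Path

import pandas as pd

from vmvar import stats

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    table = pd.read_csv(RESULTS / "startle_table.csv")
    out = stats.startle_variability(table)

    report: dict = {"warnings": out["warnings"]}
    tbt = out["tbt_group_test"]
    if tbt is not None:
        report["trial_by_trial"] = {"test": tbt.test, "F": tbt.statistic, "p": tbt.p}
        print(f"trial-by-trial variability ({tbt.test}): "
              f"F={tbt.statistic:.2f}, p={tbt.p:.3g}")
    report["inter_individual"] = {}
    for db, rep in out["inter_individual"].items():
        report["inter_individual"][str(db)] = {
            "test": rep.test, "statistic": rep.statistic, "p": rep.p,
            "variances": rep.details["variances"],
        }
        print(f"inter-individual variance at {db:.0f} dB (Bartlett): "
              f"p={rep.p:.3g}  variances=" + ", ".join(
                  f"{g}={v:.1f}" for g, v in rep.details["variances"].items()))

    mean_sd = out["trial_sd_table"].groupby("group")["trial_sd"].mean()
    report["mean_trial_sd"] = {g: float(v) for g, v in mean_sd.items()}
    print("mean trial SD per group: " + ", ".join(
        f"{g}={v:.2f}" for g, v in mean_sd.items()))

    (RESULTS / "startle_report.json").write_text(json.dumps(report, indent=1))
    print("wrote results/startle_report.json")


if __name__ == "__main__":
    main()
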