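"""Group-level statistics and correlation graphs over the cohort table.

Applies the statistical layer to results/cohort_table.csv: per-parameter
Grubbs screen, normality-dispatched group comparisons (permutation test for
spontaneous firing, which pools silent and active cells), variance-homogeneity
tests, and the per-group significance-filtered Pearson correlation graphs.
Writes results/group_stats.json and results/graph_<group>.json.
"""

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from vmvar import io as vio
from vmvar import stats

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

PERMUTATION_PARAMS = {"spont_rate"}


def main() -> None:
    table = pd.read_csv(RESULTS / "cohort_table.csv")
    param_cols = [c for c in table.columns if c not in ("cell_id", "group")]
    report: dict = {"comparisons": {}, "variance_tests": {}, "skipped": {}}

    sizes = table["group"].value_counts()
    if len(sizes) < 2 or (sizes < 3).any():
        raise SystemExit("need >= 2 groups with >= 3 cells each")

    for col in param_cols:
        vals, labs = [], []
        for g, sub in table.groupby("group"):
            x = sub[col].dropna().to_numpy(dtype=float)
            kept, _, _ = stats.grubbs_filter(x)
            vals.append(kept)
            labs.append(np.repeat(g, kept.size))
        values, labels = np.concatenate(vals), np.concatenate(labs)
        counts = pd.Series(labels).value_counts()
        if len(counts) < 2 or (counts < 3).any():
            report["skipped"][col] = "group too small after missing-value removal"
            continue
        try:
            if col in PERMUTATION_PARAMS:
                cmp = stats.permutation_test(values, labels, seed=0)
            else:
                cmp = stats.compare_groups(values, labels)
            var = stats.variance_test(values, labels)
        except Exception as err:
            report["skipped"][col] = str(err)
            continue
        report["comparisons"][col] = {
            "test": cmp.test, "statistic": cmp.statistic, "p": cmp.p,
        }
        report["variance_tests"][col] = {
            "test": var.test, "statistic": var.statistic, "p": var.p,
            "variance_ratio": var.details.get("variance_ratio"),
        }
        flag = "*" if (cmp.p is not None and cmp.p < 0.05) else " "
        print(f"{flag} {col:24s} {cmp.test:22s} p={cmp.p:.3g}   "
              f"var: {var.test} p={var.p:.3g}")

    for g, sub in table.groupby("group"):
        usable = [c for c in param_cols
                  if sub[c].notna().sum() >= 3 and sub[c].std() > 0]
        if len(usable) < 2:
            continue
        r, p = stats.correlation_matrix(sub[usable])
        graph = stats.node_graph(r, p)
        out = RESULTS / f"graph_{g}.json"
        vio.write_graph_json(graph, out)
        print(f"{g}: correlation graph with {graph.number_of_edges()} significant "
              f"edges over {graph.number_of_nodes()} parameters -> {out.name}")

    (RESULTS / "group_stats.json").write_text(json.dumps(report, indent=1))
    print(f"wrote results/group_stats.json "
          f"({len(report['comparisons'])} parameters compared)")


if __name__ == "__main__":
    main()
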