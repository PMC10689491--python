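"""Statistical layer: Grubbs, dispatch, variance tests, permutation, graphs."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from vmvar import stats, synth
from vmvar.trace import ValidationError


# ---------------------------------------------------------------------------
# Grubbs


def test_grubbs_removes_gross_outlier():
    kept, removed, _ = stats.grubbs_filter(np.array([1.0, 1.1, 0.9, 1.05, 25.0]))
    assert removed == [4]
    assert 25.0 not in kept


def test_grubbs_keeps_small_samples_intact():
    kept, removed, _ = stats.grubbs_filter(np.array([1.0, 2.0, 3.0]))
    assert removed == []
    kept, removed, warn = stats.grubbs_filter(np.array([1.0, 2.0]))
    assert removed == [] and warn
    kept, removed, warn = stats.grubbs_filter(np.array([3.0, 3.0, 3.0, 3.0]))
    assert removed == [] and warn


def test_grubbs_decisions_match_critical_formula():
    """Across n = 3..30, removal happens iff max |z| exceeds the studentized
    extreme-deviate critical value."""
    rng = np.random.default_rng(0)
    for n in range(3, 31):
        x = rng.normal(0, 1, n)
        if n % 3 == 0:
            x[0] += rng.uniform(2, 6)  # sometimes plant an outlier
        z = np.abs(x - x.mean()) / np.std(x, ddof=1)
        t = sps.t.isf(0.05 / (2 * n), n - 2)
        crit = (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))
        _, removed, _ = stats.grubbs_filter(x)
        assert bool(removed) == bool(z.max() > crit), n


# ---------------------------------------------------------------------------
# group comparison dispatch


def test_compare_identical_groups():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0] * 2)
    g = np.array(["a"] * 5 + ["b"] * 5)
    report = stats.compare_groups(x, g)
    assert report.p == pytest.approx(1.0)


def test_compare_groups_selects_t_and_rejects_shifted_normals():
    rng = np.random.default_rng(1)
    tests, rejections = [], 0
    n_sims = 150
    for _ in range(n_sims):
        a = rng.normal(0, 1, 20)
        b = rng.normal(1, 1, 20)
        report = stats.compare_groups(
            np.concatenate([a, b]), np.repeat(["a", "b"], 20)
        )
        tests.append(report.test)
        rejections += report.p < 0.05
    assert tests.count("t test") / n_sims >= 0.8
    assert rejections / n_sims >= 0.85


def test_compare_groups_dispatches_heavy_tails_to_ranks():
    rng = np.random.default_rng(2)
    picked = []
    for _ in range(100):
        a = rng.standard_cauchy(20)
        b = rng.standard_cauchy(20)
        report = stats.compare_groups(
            np.concatenate([a, b]), np.repeat(["a", "b"], 20)
        )
        picked.append(report.test)
    assert picked.count("Mann-Whitney U") / len(picked) >= 0.95


def test_compare_three_groups_posthoc():
    rng = np.random.default_rng(3)
    x = np.concatenate([rng.normal(0, 1, 10), rng.normal(0, 1, 10), rng.normal(3, 1, 10)])
    g = np.repeat(["wt", "ko", "ko_bms"], 10)
    report = stats.compare_groups(x, g)
    assert report.test in ("one-way ANOVA", "Kruskal-Wallis")
    assert report.p < 0.01
    assert len(report.details["pairwise_p"]) == 3


def test_compare_groups_small_group_errors():
    with pytest.raises(ValidationError, match="n < 3"):
        stats.compare_groups(np.arange(5.0), np.array(["a", "a", "a", "b", "b"]))


# ---------------------------------------------------------------------------
# variance tests


def test_variance_identical_groups_levene_zero():
    x = np.array([1.0, 2.0, 3.0, 4.0] * 2)
    g = np.repeat(["a", "b"], 4)
    report = stats.variance_test(x, g)
    assert report.statistic == pytest.approx(report.statistic)  # finite
    assert report.details["variance_ratio"] == pytest.approx(1.0)
    assert report.p > 0.9


def test_variance_test_detects_sd_ratio_2():
    rng = np.random.default_rng(4)
    rejections = 0
    n_sims = 150
    for _ in range(n_sims):
        a = rng.normal(0, 1, 16)
        b = rng.normal(0, 2, 17)
        report = stats.variance_test(
            np.concatenate([a, b]), np.repeat(["a", "b"], [16, 17])
        )
        rejections += report.p < 0.05
    assert rejections / n_sims >= 0.6


def test_variance_zero_spread_goes_to_levene():
    x = np.concatenate([np.full(5, 2.0), np.array([1.0, 2.0, 3.0, 4.0, 5.0])])
    g = np.repeat(["a", "b"], 5)
    report = stats.variance_test(x, g)
    assert "Levene" in report.test
    assert report.warnings


# ---------------------------------------------------------------------------
# permutation test


def brute_force_perm_p(a, b):
    """Oracle: enumerate every assignment of the pooled values to group A."""
    pooled = np.concatenate([a, b])
    obs = abs(a.mean() - b.mean())
    count = total = 0
    for idx in itertools.combinations(range(pooled.size), a.size):
        mask = np.zeros(pooled.size, bool)
        mask[list(idx)] = True
        stat = abs(pooled[mask].mean() - pooled[~mask].mean())
        count += stat >= obs - 1e-12
        total += 1
    return count / total


def test_permutation_exact_example():
    report = stats.permutation_test(
        np.array([1.0, 2, 3, 4, 5, 6]), np.repeat(["a", "b"], 3)
    )
    assert report.test == "permutation (exact)"
    assert report.p == pytest.approx(2 / 20)


def test_permutation_identical_groups_p_one():
    report = stats.permutation_test(
        np.array([5.0] * 8), np.repeat(["a", "b"], 4)
    )
    assert report.p == pytest.approx(1.0)


@pytest.mark.parametrize("n1,n2", [(3, 3), (4, 5), (6, 6)])
def test_permutation_exact_equals_brute_force(n1, n2):
    rng = np.random.default_rng(10 + n1 + n2)
    a, b = rng.normal(0, 1, n1), rng.normal(1, 1, n2)
    report = stats.permutation_test(
        np.concatenate([a, b]), np.repeat(["a", "b"], [n1, n2])
    )
    assert report.p == pytest.approx(brute_force_perm_p(a, b), abs=1e-12)


def test_permutation_monte_carlo_close_to_exact():
    rng = np.random.default_rng(11)
    a, b = rng.normal(0, 1, 5), rng.normal(0.5, 1, 5)
    exact = brute_force_perm_p(a, b)
    values = np.concatenate([a, b])
    groups = np.repeat(["a", "b"], 5)
    # force the Monte-Carlo path by lowering the exact-enumeration limit
    old = stats.EXACT_PERM_LIMIT
    try:
        stats.EXACT_PERM_LIMIT = 1
        mc = stats.permutation_test(values, groups, n_perm=10_000, seed=1)
    finally:
        stats.EXACT_PERM_LIMIT = old
    assert mc.test == "permutation (monte-carlo)"
    assert abs(mc.p - exact) <= 0.01


# ---------------------------------------------------------------------------
# correlations and node graph


def test_correlation_matrix_basic():
    df = pd.DataFrame({
        "x": [1.0, 2.0, 3.0, 4.0],
        "y": [2.0, 4.0, 6.0, 8.0],
        "z": [1.0, -1.0, 1.0, -1.0],
    })
    r, p = stats.correlation_matrix(df)
    assert r.loc["x", "x"] == 1.0
    assert r.loc["x", "y"] == pytest.approx(1.0)
    assert p.loc["x", "y"] < 0.01


def test_correlation_constant_column_flagged_nan():
    df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "c": [5.0] * 4})
    r, p = stats.correlation_matrix(df)
    assert np.isnan(r.loc["x", "c"])


def test_correlation_orthogonal_vectors_near_zero():
    rng = np.random.default_rng(5)
    x = rng.normal(0, 1, 50)
    y = rng.normal(0, 1, 50)
    x -= x.mean()
    y -= y.mean()
    y -= (x @ y) / (x @ x) * x  # orthogonalize
    r, _ = stats.correlation_matrix(pd.DataFrame({"x": x, "y": y}))
    assert abs(r.loc["x", "y"]) < 0.01


def test_node_graph_degrees():
    cols = ["a", "b", "c"]
    r = pd.DataFrame(np.eye(3), index=cols, columns=cols)
    p = pd.DataFrame(np.ones((3, 3)), index=cols, columns=cols)
    r.loc["a", "b"] = r.loc["b", "a"] = 0.9
    p.loc["a", "b"] = p.loc["b", "a"] = 0.01
    g = stats.node_graph(r, p)
    assert g.nodes["a"]["degree"] == 1
    assert g.nodes["b"]["degree"] == 1
    assert g.nodes["c"]["degree"] == 0
    assert g.edges["a", "b"]["sign"] == 1


def test_node_graph_fully_correlated_block():
    rng = np.random.default_rng(6)
    base = rng.normal(0, 1, 60)
    df = pd.DataFrame({f"p{i}": base + rng.normal(0, 0.05, 60) for i in range(4)})
    r, p = stats.correlation_matrix(df)
    g = stats.node_graph(r, p)
    assert all(g.nodes[n]["degree"] == 3 for n in g.nodes)  # complete K4
    # structural invariant: degree attribute equals incident edges
    for n in g.nodes:
        assert g.nodes[n]["degree"] == g.degree[n]


def test_node_graph_empty_when_nothing_significant():
    cols = ["a", "b"]
    r = pd.DataFrame(np.eye(2), index=cols, columns=cols)
    p = pd.DataFrame(np.ones((2, 2)), index=cols, columns=cols)
    g = stats.node_graph(r, p)
    assert g.number_of_edges() == 0


# ---------------------------------------------------------------------------
# startle variability


def test_startle_trial_sd_values():
    rows = []
    for trial, resp in enumerate([1.0, 2.0, 3.0, 4.0]):
        rows.append(dict(animal_id="a1", group="wt", intensity_db=71.0,
                         trial=trial, response=resp))
        rows.append(dict(animal_id="a2", group="wt", intensity_db=71.0,
                         trial=trial, response=2.0))
    out = stats.startle_variability(pd.DataFrame(rows))
    tbt = out["trial_sd_table"].set_index("animal_id")["trial_sd"]
    assert tbt["a1"] == pytest.approx(1.2910, abs=1e-3)
    assert tbt["a2"] == 0.0


def test_startle_group_difference_detected():
    """Trial-SD ratio 2 between groups, 10 animals each: the group test on
    per-animal trial SDs detects the difference in >= 80% of simulations."""
    detections = 0
    n_sims = 60
    for seed in range(n_sims):
        gp = {
            "wt": dict(mean=100.0, slope_per_db=3.0, animal_sd=5.0, trial_sd=8.0),
            "ko": dict(mean=100.0, slope_per_db=3.0, animal_sd=5.0, trial_sd=16.0),
        }
        table = synth.generate_startle_table(10, gp, seed=seed)
        out = stats.startle_variability(table)
        detections += out["tbt_group_test"].p < 0.05
    assert detections / n_sims >= 0.8


def test_startle_inter_individual_bartlett():
    """A 4x animal-level SD gap shows up in the per-intensity Bartlett tests."""
    gp = {
        "wt": dict(mean=100.0, slope_per_db=3.0, animal_sd=4.0, trial_sd=8.0),
        "ko": dict(mean=100.0, slope_per_db=3.0, animal_sd=16.0, trial_sd=8.0),
    }
    table = synth.generate_startle_table(12, gp, seed=3)
    out = stats.startle_variability(table)
    ps = [rep.p for rep in out["inter_individual"].values()]
    assert len(ps) == 4
    assert min(ps) < 0.05


def test_startle_missing_columns():
    with pytest.raises(ValidationError, match="missing startle columns"):
        stats.startle_variability(pd.DataFrame({"animal_id": [], "group": []}))
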