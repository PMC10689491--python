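"""Cohort-level statistics: outlier removal, normality-dispatched group
comparisons, variance-homogeneity tests, permutation test, Pearson correlation
matrices with significance-filtered node graphs, and the acoustic-startle
variability analysis.

Dispatch mirrors common electrophysiology practice: values are screened once
with a two-sided single-outlier Grubbs test (alpha = 0.05); Shapiro-Wilk per
group selects the parametric path (t test / ANOVA, F or Bartlett for
variances) versus the rank path (Mann-Whitney U / Kruskal-Wallis with Dunn
post hoc, Levene centered on the mean). Parameters pooling silent and active
cells use a two-sided permutation test on the difference of group means.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats as sps

from .trace import ValidationError

__all__ = [
    "TestReport",
    "grubbs_filter",
    "grubbs_critical",
    "compare_groups",
    "variance_test",
    "permutation_test",
    "correlation_matrix",
    "node_graph",
    "startle_variability",
]

ALPHA = 0.05
EXACT_PERM_LIMIT = 20_000


@dataclass
class TestReport:
    test: str
    statistic: float | None
    p: float | None
    n: dict[str, int]
    details: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Grubbs outlier screen


def grubbs_critical(n: int, alpha: float = ALPHA) -> float:
    """Two-sided Grubbs critical value for a single outlier at level alpha."""
    t = sps.t.isf(alpha / (2 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t**2 / (n - 2 + t**2))


def grubbs_filter(
    values: np.ndarray, alpha: float = ALPHA
) -> tuple[np.ndarray, list[int], list[str]]:
    """Two-sided single-outlier Grubbs test, applied once.

    Returns ``(kept_values, removed_indices, warnings)``; at most one value is
    removed per call. Samples of fewer than three values, or with zero spread,
    are returned unchanged with a warning record.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        return x, [], ["grubbs: n < 3, no outlier test applied"]
    sd = np.std(x, ddof=1)
    if sd == 0:
        return x, [], ["grubbs: zero spread, no outlier test applied"]
    z = np.abs(x - np.mean(x)) / sd
    i = int(np.argmax(z))
    if z[i] > grubbs_critical(n, alpha):
        return np.delete(x, i), [i], []
    return x, [], []


# ---------------------------------------------------------------------------
# group comparisons


def _split(values: np.ndarray, groups: np.ndarray) -> dict[str, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    return {g: values[groups == g] for g in pd.unique(groups)}


def _all_normal(samples: dict[str, np.ndarray], alpha: float = ALPHA) -> bool:
    for x in samples.values():
        if np.std(x, ddof=1) == 0:
            return False
        if sps.shapiro(x).pvalue < alpha:
            return False
    return True


def _dunn_posthoc(samples: dict[str, np.ndarray]) -> dict[tuple[str, str], float]:
    """Dunn's rank-based pairwise test with tie correction, Bonferroni-adjusted."""
    labels = list(samples)
    pooled = np.concatenate([samples[g] for g in labels])
    n = pooled.size
    ranks = sps.rankdata(pooled)
    # tie correction term
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n - 1))
    mean_ranks, sizes = {}, {}
    start = 0
    for g in labels:
        k = samples[g].size
        mean_ranks[g] = np.mean(ranks[start : start + k])
        sizes[g] = k
        start += k
    m = len(labels) * (len(labels) - 1) // 2
    out = {}
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1 / sizes[a] + 1 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = min(2 * sps.norm.sf(abs(z)) * m, 1.0)
        out[(a, b)] = float(p)
    return out


def compare_groups(
    values: np.ndarray,
    groups: np.ndarray,
    alpha: float = ALPHA,
    posthoc: str = "dunn",
) -> TestReport:
    """Normality-dispatched comparison of group locations.

    Two groups: unpaired t test when every group passes Shapiro-Wilk at
    ``alpha``, otherwise Mann-Whitney U. Three or more: one-way ANOVA with
    Bonferroni-corrected pairwise t tests, or Kruskal-Wallis with Dunn
    (``posthoc`` selects "dunn" or "bonferroni" for the rank path).
    """
    samples = _split(values, groups)
    if len(samples) < 2:
        raise ValidationError("compare_groups needs at least 2 groups")
    for g, x in samples.items():
        if x.size < 3:
            raise ValidationError(f"group {g!r} has n < 3")
    ns = {g: int(x.size) for g, x in samples.items()}
    normal = _all_normal(samples, alpha)
    data = list(samples.values())
    if len(samples) == 2:
        if normal:
            res = sps.ttest_ind(*data)
            return TestReport("t test", float(res.statistic), float(res.pvalue), ns)
        res = sps.mannwhitneyu(*data, alternative="two-sided")
        return TestReport("Mann-Whitney U", float(res.statistic), float(res.pvalue), ns)
    if normal:
        res = sps.f_oneway(*data)
        pairs = {}
        m = comb(len(samples), 2)
        for a, b in itertools.combinations(samples, 2):
            p = sps.ttest_ind(samples[a], samples[b]).pvalue
            pairs[(a, b)] = min(float(p) * m, 1.0)
        return TestReport(
            "one-way ANOVA", float(res.statistic), float(res.pvalue), ns,
            details={"posthoc": "bonferroni t", "pairwise_p": pairs},
        )
    res = sps.kruskal(*data)
    if posthoc == "dunn":
        pairs = _dunn_posthoc(samples)
        label = "dunn"
    else:
        m = comb(len(samples), 2)
        pairs = {
            (a, b): min(
                float(sps.mannwhitneyu(samples[a], samples[b],
                                       alternative="two-sided").pvalue) * m, 1.0)
            for a, b in itertools.combinations(samples, 2)
        }
        label = "bonferroni mann-whitney"
    return TestReport(
        "Kruskal-Wallis", float(res.statistic), float(res.pvalue), ns,
        details={"posthoc": label, "pairwise_p": pairs},
    )


def variance_test(values: np.ndarray, groups: np.ndarray, alpha: float = ALPHA) -> TestReport:
    """Variance-homogeneity test with normality dispatch.

    Normally distributed groups: two-sided F test for two groups, Bartlett for
    more. Otherwise (or when a group has zero spread): Levene centered on the
    mean. The report carries the ratio of the largest to smallest group
    variance.
    """
    samples = _split(values, groups)
    if len(samples) < 2:
        raise ValidationError("variance_test needs at least 2 groups")
    for g, x in samples.items():
        if x.size < 3:
            raise ValidationError(f"group {g!r} has n < 3")
    ns = {g: int(x.size) for g, x in samples.items()}
    data = list(samples.values())
    variances = {g: float(np.var(x, ddof=1)) for g, x in samples.items()}
    warnings = []
    zero_var = any(v == 0 for v in variances.values())
    if zero_var:
        warnings.append("zero variance in a group; using Levene")
    ratio = (
        max(variances.values()) / min(variances.values())
        if min(variances.values()) > 0 else np.inf
    )
    details = {"variances": variances, "variance_ratio": float(ratio)}
    if not zero_var and _all_normal(samples, alpha):
        if len(samples) == 2:
            f = variances[list(samples)[0]] / variances[list(samples)[1]]
            dfn, dfd = data[0].size - 1, data[1].size - 1
            p = 2 * min(sps.f.cdf(f, dfn, dfd), sps.f.sf(f, dfn, dfd))
            return TestReport("F test", float(f), float(min(p, 1.0)), ns, details)
        res = sps.bartlett(*data)
        return TestReport("Bartlett", float(res.statistic), float(res.pvalue), ns, details)
    res = sps.levene(*data, center="mean")
    return TestReport(
        "Levene (mean-centered)", float(res.statistic), float(res.pvalue), ns,
        details, warnings,
    )


def permutation_test(
    values: np.ndarray,
    groups: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> TestReport:
    """Two-sided permutation test on the absolute difference of group means.

    Label assignments are enumerated exactly when the number of combinations
    is at most 20,000; otherwise a seeded Monte-Carlo sample of ``n_perm``
    permutations is drawn and the p value uses the +1 correction.
    """
    samples = _split(values, groups)
    if len(samples) != 2:
        raise ValidationError("permutation_test needs exactly 2 groups")
    a, b = samples.values()
    if a.size == 0 or b.size == 0:
        raise ValidationError("empty group")
    pooled = np.concatenate([a, b])
    n, n1 = pooled.size, a.size
    observed = abs(np.mean(a) - np.mean(b))
    total = pooled.sum()
    ns = {g: int(x.size) for g, x in samples.items()}
    eps = 1e-12
    if comb(n, n1) <= EXACT_PERM_LIMIT:
        count = 0
        n_combos = 0
        for idx in itertools.combinations(range(n), n1):
            m1 = pooled[list(idx)].sum() / n1
            m2 = (total - m1 * n1) / (n - n1)
            if abs(m1 - m2) >= observed - eps:
                count += 1
            n_combos += 1
        p = count / n_combos
        return TestReport(
            "permutation (exact)", float(observed), float(p), ns,
            details={"n_permutations": n_combos},
        )
    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
    m1 = perm[:, :n1].mean(axis=1)
    m2 = perm[:, n1:].mean(axis=1)
    count = int(np.sum(np.abs(m1 - m2) >= observed - eps))
    p = (count + 1) / (n_perm + 1)
    return TestReport(
        "permutation (monte-carlo)", float(observed), float(p), ns,
        details={"n_permutations": n_perm, "seed": seed},
    )


# ---------------------------------------------------------------------------
# correlation matrix and node graph


def correlation_matrix(
    table: pd.DataFrame, min_pairs: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided p per parameter pair, pairwise-complete.

    Constant columns yield NaN (flagged undefined) rather than 0. The diagonal
    r is 1 with p = 0.
    """
    cols = list(table.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        r[i, i], p[i, i] = 1.0, 0.0
        for j in range(i + 1, k):
            x = table[cols[i]].to_numpy(dtype=float)
            y = table[cols[j]].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < min_pairs:
                continue
            if np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                continue  # undefined for constant columns
            res = sps.pearsonr(x[ok], y[ok])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def node_graph(
    r: pd.DataFrame,
    p: pd.DataFrame,
    categories: dict[str, str] | None = None,
    alpha: float = ALPHA,
) -> nx.Graph:
    """Significance-filtered correlation graph.

    Nodes are parameters (with a ``category`` attribute and ``degree``
    recomputed from retained edges); edges keep pairs with p < ``alpha`` (no
    multiplicity correction), weighted by |r| with the sign as an attribute.
    """
    if r.shape != p.shape or list(r.columns) != list(p.columns):
        raise ValidationError("r and p matrices must be conformant")
    g = nx.Graph()
    categories = categories or {}
    for name in r.columns:
        g.add_node(name, category=categories.get(name, "uncategorized"))
    cols = list(r.columns)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            pv, rv = p.iloc[i, j], r.iloc[i, j]
            if np.isfinite(pv) and pv < alpha:
                g.add_edge(a, b, r=float(rv), p=float(pv),
                           weight=abs(float(rv)), sign=int(np.sign(rv)))
    for name in g.nodes:
        g.nodes[name]["degree"] = g.degree[name]
    return g


# ---------------------------------------------------------------------------
# startle-response variability


def startle_variability(table: pd.DataFrame) -> dict:
    """Trial-by-trial and inter-individual variability of startle responses.

    Expects long-format columns ``animal_id, group, intensity_db, trial,
    response``. Trial-by-trial variability is the per-animal SD of responses
    at each intensity, compared across groups with a mixed (repeated-measures)
    two-way ANOVA over intensities. Inter-individual variability is the
    variance of per-animal mean responses per group at each intensity,
    compared with the Bartlett test.
    """
    required = {"animal_id", "group", "intensity_db", "trial", "response"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"missing startle columns: {sorted(missing)}")
    counts = table.groupby(["animal_id", "intensity_db"])["response"].count()
    warnings = []
    bad = counts[counts < 2]
    if len(bad):
        warnings.append(f"excluded {len(bad)} single-trial animal/intensity cells")
        keep = counts[counts >= 2].index
        table = table.set_index(["animal_id", "intensity_db"]).loc[keep].reset_index()

    tbt = (
        table.groupby(["group", "animal_id", "intensity_db"])["response"]
        .std(ddof=1)
        .rename("trial_sd")
        .reset_index()
    )
    try:
        import pingouin as pg

        aov = pg.mixed_anova(
            data=tbt, dv="trial_sd", within="intensity_db",
            subject="animal_id", between="group",
        )
        group_row = aov[aov["Source"] == "group"].iloc[0]
        p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
        tbt_test = TestReport(
            "mixed ANOVA (group)", float(group_row["F"]),
            float(group_row[p_col]),
            {g: int(n) for g, n in tbt.groupby("group")["animal_id"].nunique().items()},
            details={"anova": aov.to_dict(orient="records")},
        )
    except Exception as err:  # pragma: no cover - degenerate designs
        warnings.append(f"mixed ANOVA failed: {err}")
        tbt_test = None

    animal_means = (
        table.groupby(["group", "animal_id", "intensity_db"])["response"]
        .mean()
        .reset_index()
    )
    inter = {}
    for db, sub in animal_means.groupby("intensity_db"):
        samples = [g["response"].to_numpy() for _, g in sub.groupby("group")]
        variances = {
            name: float(np.var(g["response"], ddof=1))
            for name, g in sub.groupby("group")
        }
        if len(samples) >= 2 and all(len(s) >= 2 for s in samples):
            res = sps.bartlett(*samples)
            inter[float(db)] = TestReport(
                "Bartlett", float(res.statistic), float(res.pvalue),
                {str(i): len(s) for i, s in enumerate(samples)},
                details={"variances": variances},
            )
    return {
        "trial_sd_table": tbt,
        "tbt_group_test": tbt_test,
        "inter_individual": inter,
        "warnings": warnings,
    }
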