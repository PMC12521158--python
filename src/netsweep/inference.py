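"""Permutation-based group comparison of AUC metrics and distribution tests.

Group differences in every AUC-integrated topological metric are assessed
with a nonparametric permutation test: pooled values are randomly
re-partitioned into groups of the original sizes, the between-group mean
difference recomputed each time, and the 95th percentile of the absolute
null differences taken as the critical value of a two-tailed test at
alpha = 0.05. Nodal p-values are corrected for multiple comparisons with
the Benjamini–Hochberg false discovery rate within each nodal-metric
family. Degree and link-weight distributions are compared with two-sample
Kolmogorov–Smirnov and Mann–Whitney U tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from netsweep.metrics import GLOBAL_METRIC_NAMES, MetricCurveSet

__all__ = [
    "PermutationResult",
    "DistributionComparison",
    "permutation_test",
    "fdr_adjust",
    "compare_group_metrics",
    "compare_distributions",
    "cohort_auc_table",
]


@dataclass
class PermutationResult:
    """Outcome of a two-tailed permutation test on a group mean difference."""

    metric_name: str
    observed_diff: float  # group A mean - group B mean
    null_diffs: np.ndarray
    p_two_tailed: float
    critical_value: float  # 95th percentile of |null|
    significant: bool


def permutation_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    metric_name: str = "",
    alpha: float = 0.05,
) -> PermutationResult:
    """Two-tailed permutation test on the difference of group means.

    The null distribution re-partitions the pooled values into groups of
    the original sizes ``n_perm`` times. The p-value uses add-one
    smoothing, p = (1 + #{|null| >= |observed|}) / (n_perm + 1), and the
    decision rule flags significance when |observed| reaches the
    empirical (1 - alpha) quantile of |null|. Deterministic given seed.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    observed = float(a.mean() - b.mean())
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        null = np.zeros(n_perm)
        return PermutationResult(metric_name, observed, null, 1.0, 0.0,
                                 False)
    rng = np.random.default_rng(seed)
    perms = rng.permuted(
        np.broadcast_to(pooled, (n_perm, pooled.size)), axis=1)
    null = perms[:, :a.size].mean(axis=1) - perms[:, a.size:].mean(axis=1)
    abs_null = np.abs(null)
    p = (1.0 + np.count_nonzero(abs_null >= abs(observed))) / (n_perm + 1.0)
    critical = float(np.quantile(abs_null, 1.0 - alpha))
    return PermutationResult(metric_name, observed, null, float(p), critical,
                             bool(abs(observed) >= critical))


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cohort_auc_table(curve_sets: list[MetricCurveSet]) -> pd.DataFrame:
    """Stack per-subject AUC summaries into one tidy cohort table."""
    return pd.concat([cs.auc_rows() for cs in curve_sets],
                     ignore_index=True)


def compare_group_metrics(
    auc_table: pd.DataFrame,
    grouping: pd.Series,
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Permutation comparison of every AUC metric between two groups.

    ``auc_table`` is the tidy table from :func:`cohort_auc_table`
    (columns subject_id, metric, scope, node_label, auc); ``grouping``
    maps subject_id to one of exactly two group labels (index =
    subject_id). Group A is the label that sorts first. Returns one row
    per global metric and per (nodal metric, node) with group means ± SD,
    the observed difference, a t-like statistic (difference / pooled SE,
    for reporting), raw permutation p, and — for nodal rows — the
    BH-adjusted p within each nodal-metric family.
    """
    groups = np.sort(grouping.unique())
    if groups.size != 2:
        raise ValueError(f"need exactly 2 groups, got {list(groups)}")
    subjects = auc_table["subject_id"].unique()
    missing = [s for s in subjects if s not in grouping.index]
    if missing:
        raise ValueError(f"subjects missing from grouping: {missing}")
    wide = auc_table.pivot_table(
        index="subject_id", columns=["scope", "metric", "node_label"],
        values="auc", sort=False)
    incomplete = wide.index[wide.isna().any(axis=1)].tolist()
    if incomplete:
        raise ValueError(f"incomplete metric sets for subjects: {incomplete}")
    in_a = grouping.loc[wide.index] == groups[0]
    # one derived seed per column, in column order: deterministic and
    # independently rerunnable per metric
    col_seeds = np.random.SeedSequence(seed).spawn(wide.shape[1])
    rows = []
    for (scope, metric, node), child in zip(wide.columns, col_seeds):
        col = wide[(scope, metric, node)]
        a = col[in_a].to_numpy()
        b = col[~in_a].to_numpy()
        test_seed = int(child.generate_state(1)[0] % (2**31))
        res = permutation_test(a, b, n_perm=n_perm, seed=test_seed,
                               metric_name=metric, alpha=alpha)
        n_a, n_b = a.size, b.size
        pooled_var = (((n_a - 1) * a.var(ddof=1) + (n_b - 1) * b.var(ddof=1))
                      / (n_a + n_b - 2))
        se = np.sqrt(pooled_var * (1 / n_a + 1 / n_b))
        rows.append({
            "scope": scope, "metric": metric, "node_label": node,
            f"mean_{groups[0]}": a.mean(), f"sd_{groups[0]}": a.std(ddof=1),
            f"mean_{groups[1]}": b.mean(), f"sd_{groups[1]}": b.std(ddof=1),
            "observed_diff": res.observed_diff,
            "t_like": res.observed_diff / se if se > 0 else np.nan,
            "p_raw": res.p_two_tailed,
            "critical_value": res.critical_value,
            "significant": res.significant,
        })
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    for metric in out.loc[out["scope"] == "node", "metric"].unique():
        mask = (out["scope"] == "node") & (out["metric"] == metric)
        out.loc[mask, "p_fdr"] = fdr_adjust(out.loc[mask, "p_raw"].to_numpy())
    return out


@dataclass
class DistributionComparison:
    """K-S and Mann–Whitney comparison of two empirical distributions."""

    ks_statistic: float
    ks_p: float
    mwu_statistic: float
    mwu_p: float


def compare_distributions(
    sample_a: np.ndarray, sample_b: np.ndarray
) -> DistributionComparison:
    """Two-sample Kolmogorov–Smirnov and Mann–Whitney U tests.

    K-S uses the asymptotic sup-|ECDF difference| test; Mann–Whitney
    uses exact enumeration when both samples have at most 20 tie-free
    observations and the normal approximation with continuity and tie
    correction otherwise. Both two-tailed.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both samples need at least 2 observations")
    ks = stats.ks_2samp(a, b, method="asymp")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (max(a.size, b.size) <= 20 and no_ties) \
        else "asymptotic"
    mwu = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return DistributionComparison(
        float(ks.statistic), float(ks.pvalue),
        float(mwu.statistic), float(mwu.pvalue))
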