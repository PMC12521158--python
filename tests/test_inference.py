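import itertools

import numpy as np
import pandas as pd
import pytest

from netsweep import (
    compare_distributions,
    compare_group_metrics,
    fdr_adjust,
    permutation_test,
)


class TestPermutationTest:
    def test_identical_constant_groups(self):
        res = permutation_test(np.full(5, 2.0), np.full(4, 2.0), n_perm=200,
                               seed=0)
        assert res.observed_diff == 0.0
        assert res.p_two_tailed == 1.0
        assert not res.significant

    def test_matches_exhaustive_enumeration_on_small_pool(self):
        a = np.array([10.0, 10.0, 10.0])
        b = np.array([0.0, 0.0, 0.0])
        pooled = np.concatenate([a, b])
        observed = a.mean() - b.mean()
        null = []
        for idx in itertools.combinations(range(6), 3):
            mask = np.zeros(6, dtype=bool)
            mask[list(idx)] = True
            null.append(pooled[mask].mean() - pooled[~mask].mean())
        exact_p = np.mean(np.abs(null) >= abs(observed))  # = 2/20
        res = permutation_test(a, b, n_perm=20_000, seed=7)
        assert exact_p == pytest.approx(0.1)
        assert res.p_two_tailed == pytest.approx(exact_p, abs=0.01)

    def test_same_seed_reproduces_null(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=10), rng.normal(size=8)
        r1 = permutation_test(a, b, n_perm=500, seed=11)
        r2 = permutation_test(a, b, n_perm=500, seed=11)
        np.testing.assert_array_equal(r1.null_diffs, r2.null_diffs)

    def test_significant_flag_tracks_critical_value(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = rng.normal(size=12)
            b = rng.normal(loc=rng.uniform(0, 1.5), size=9)
            res = permutation_test(a, b, n_perm=1000, seed=2)
            assert res.significant == \
                (abs(res.observed_diff) >= res.critical_value)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            permutation_test(np.array([]), np.ones(3), n_perm=100, seed=0)


class TestFdrAdjust:
    def test_benjamini_hochberg_by_hand(self):
        adj = fdr_adjust(np.array([0.01, 0.02, 0.03, 0.5]))
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.5])

    def test_single_p_unchanged(self):
        assert fdr_adjust(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_all_ones_stay_ones(self):
        np.testing.assert_array_equal(fdr_adjust(np.ones(6)), np.ones(6))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust(np.array([0.5, 1.2]))


def _auc_table(values_by_subject):
    rows = []
    for sid, metrics in values_by_subject.items():
        for (metric, scope, node), v in metrics.items():
            rows.append((sid, metric, scope, node, v))
    return pd.DataFrame(rows, columns=["subject_id", "metric", "scope",
                                       "node_label", "auc"])


class TestCompareGroupMetrics:
    def _cohort_table(self, rng, shift=0.0, n_a=12, n_b=10):
        table = {}
        grouping = {}
        for i in range(n_a + n_b):
            sid = f"s{i:02d}"
            in_a = i < n_a
            grouping[sid] = "a" if in_a else "b"
            mu = shift if in_a else 0.0
            table[sid] = {
                ("m1", "global", ""): rng.normal(mu),
                ("m2", "global", ""): rng.normal(),
                ("nm", "node", "ROI1"): rng.normal(mu),
                ("nm", "node", "ROI2"): rng.normal(),
            }
        return _auc_table(table), pd.Series(grouping)

    def test_planted_global_shift_detected_with_fdr_columns(self, rng):
        table, grouping = self._cohort_table(rng, shift=3.0)
        out = compare_group_metrics(table, grouping, n_perm=2000, seed=1)
        m1 = out[(out["metric"] == "m1") & (out["scope"] == "global")]
        assert m1["significant"].item()
        assert m1["observed_diff"].item() > 0
        assert np.isnan(m1["p_fdr"].item())  # globals not FDR-corrected
        nodal = out[out["scope"] == "node"]
        assert nodal["p_fdr"].notna().all()

    def test_group_means_match_direct_computation(self, rng):
        table, grouping = self._cohort_table(rng, shift=1.0)
        out = compare_group_metrics(table, grouping, n_perm=200, seed=1)
        m1 = out[(out["metric"] == "m1") & (out["scope"] == "global")]
        vals = table[(table["metric"] == "m1")].set_index("subject_id")[
            "auc"]
        expected = vals[[s for s in vals.index
                         if grouping[s] == "a"]].mean()
        assert m1["mean_a"].item() == pytest.approx(expected)

    def test_incomplete_subject_listed_in_error(self, rng):
        table, grouping = self._cohort_table(rng)
        table = table.drop(table.index[-1])  # s21 loses one metric
        with pytest.raises(ValueError, match="s21"):
            compare_group_metrics(table, grouping, n_perm=200, seed=0)

    def test_requires_exactly_two_groups(self, rng):
        table, grouping = self._cohort_table(rng)
        grouping.iloc[0] = "c"
        with pytest.raises(ValueError, match="2 groups"):
            compare_group_metrics(table, grouping, n_perm=200, seed=0)


class TestCompareDistributions:
    def test_identical_samples_have_zero_ks_distance(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = compare_distributions(a, a.copy())
        assert res.ks_statistic == 0.0

    def test_disjoint_supports_have_unit_ks_distance(self):
        res = compare_distributions(np.array([1.0, 2.0, 3.0]),
                                    np.array([11.0, 12.0, 13.0]))
        assert res.ks_statistic == 1.0

    def test_mann_whitney_u_matches_pair_counting(self):
        a = np.array([1.0, 2.0])
        b = np.array([1.5, 2.5])
        res = compare_distributions(a, b)
        # brute force: #(a_i > b_j) pairs = 1 (2 > 1.5)
        assert res.mwu_statistic == pytest.approx(1.0)

    def test_large_samples_use_tie_corrected_normal_approximation(self, rng):
        a = rng.integers(0, 5, size=60).astype(float)
        b = rng.integers(1, 6, size=50).astype(float)
        res = compare_distributions(a, b)
        assert 0 < res.mwu_p <= 1
        assert 0 < res.ks_p <= 1

    def test_tiny_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_distributions(np.array([1.0]), np.array([1.0, 2.0]))
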