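"""Two-group tests, BH correction, volcano calls, clustering — vs oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcmlnc.diffexpr import test_two_groups as two_group_p
from dcmlnc import (
    DEGSets,
    bh_adjust,
    differential_expression,
    hierarchical_order,
    overlap_sets,
)


def bh_bruteforce(p):
    """Independent step-up oracle: q_i = min over j>=rank(i) of p_(j) m/j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running_min = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, p[idx] * m / rank)
        q[idx] = running_min
    return q


def mann_whitney_exact_enumeration(a, b):
    """Two-sided p by enumerating all C(n+m, n) rank assignments."""
    pooled = sorted(a + b)
    n = len(a)
    u_obs = sum(1 for x in a for y in b if x > y) + 0.5 * sum(
        1 for x in a for y in b if x == y
    )
    mean_u = n * len(b) / 2
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), n):
        grp_a = [pooled[i] for i in comb]
        grp_b = [pooled[i] for i in range(len(pooled)) if i not in comb]
        u = sum(1 for x in grp_a for y in grp_b if x > y) + 0.5 * sum(
            1 for x in grp_a for y in grp_b if x == y
        )
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


class TestTwoGroups:
    def test_identical_groups_welch(self):
        assert two_group_p([1, 2, 3, 4], [1, 2, 3, 4], "welch_t") == pytest.approx(1.0)

    def test_mann_whitney_fully_separated(self):
        p = two_group_p([1, 2, 3, 4], [5, 6, 7, 8], "mann_whitney")
        assert p == pytest.approx(2 / 70)

    def test_mann_whitney_matches_enumeration(self, rng):
        for _ in range(5):
            a = list(np.round(rng.normal(size=4), 3))
            b = list(np.round(rng.normal(0.5, 1, size=4), 3))
            p_impl = two_group_p(a, b, "mann_whitney")
            p_oracle = mann_whitney_exact_enumeration(a, b)
            assert p_impl == pytest.approx(p_oracle, abs=1e-12)

    def test_welch_agrees_with_permutation_oracle(self, rng):
        a = rng.normal(0, 1, size=6)
        b = rng.normal(0.8, 1, size=6)
        p_welch = two_group_p(a, b, "welch_t")
        pooled = np.concatenate([a, b])
        obs = abs(a.mean() - b.mean())
        hits = 0
        n_perm = 10_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            if abs(perm[:6].mean() - perm[6:].mean()) >= obs - 1e-12:
                hits += 1
        p_perm = hits / n_perm
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p_welch - p_perm) < max(5 * se, 0.02)

    def test_zero_variance_equal_means(self):
        assert two_group_p([2, 2, 2], [2, 2, 2], "welch_t") == 1.0

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            two_group_p([1], [2, 3], "welch_t")


class TestBH:
    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50)
    )
    def test_oracle_equivalence(self, p):
        np.testing.assert_allclose(bh_adjust(p), bh_bruteforce(p), atol=1e-12)

    def test_monotone_in_sorted_order(self, rng):
        p = rng.uniform(size=40)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestDifferentialExpression:
    def test_threshold_arithmetic(self, tiny_norm):
        norm, meta = tiny_norm
        table = differential_expression(norm, meta, ("control", "dbdb", 6)).set_index("probe_id")
        assert table.loc["P1", "fc_linear"] == pytest.approx(4.0)
        assert table.loc["P1", "direction"] == "up"
        assert table.loc["P3", "fc_linear"] == pytest.approx(8.0)
        assert table.loc["P3", "direction"] == "down"
        assert table.loc["P2", "direction"] == "none"
        assert table.loc["P4", "p"] == 1.0 and table.loc["P4", "direction"] == "none"

    def test_subthreshold_fold_change_never_significant(self, tiny_norm):
        norm, meta = tiny_norm
        # shrink P1's offset to log2fc ~ 0.585 (fc 1.5) but keep tiny variance
        norm.values.loc["P1"] = [5.0, 5.01, 4.99, 5.0, 5.585, 5.595, 5.575, 5.585]
        table = differential_expression(norm, meta, ("control", "dbdb", 6)).set_index("probe_id")
        assert table.loc["P1", "p"] < 1e-6
        assert not table.loc["P1", "significant"]

    def test_volcano_partition_and_symmetry(self, small_norm):
        norm, filtered = small_norm
        fwd = differential_expression(norm, filtered.metadata, ("control", "dbdb", 20))
        rev = differential_expression(norm, filtered.metadata, ("dbdb", "control", 20))
        assert set(fwd["direction"]) <= {"up", "down", "none"}
        merged = fwd.set_index("probe_id").join(rev.set_index("probe_id"), rsuffix="_rev")
        np.testing.assert_allclose(merged["log2fc"], -merged["log2fc_rev"], atol=1e-12)
        np.testing.assert_allclose(merged["p"], merged["p_rev"], atol=1e-12)
        assert (merged.loc[merged["direction"] == "up", "direction_rev"] == "down").all()

    def test_planted_de_recovery(self):
        """Sensitivity >= 0.9, FPR <= 0.01 over 10 seeds at strong effects."""
        from dcmlnc import SimulationConfig, run_preprocessing, simulate_study

        sens, fpr = [], []
        for seed in range(10):
            cfg = SimulationConfig(
                seed=seed, frac_de=0.1, fc_range=(4, 8), sigma_noise=0.25, n_hubs=0,
                n_chromosomes=3, chrom_length=2_000_000, n_coding=150, n_lnc_per_class=30,
            )
            study, truth, _ = simulate_study(cfg)
            norm, filtered = run_preprocessing(study)
            de = differential_expression(norm, filtered.metadata, ("control", "dbdb", 20))
            called = set(de.loc[de["significant"], "probe_id"])
            retained = set(norm.probe_ids)
            true = set(truth.de_sets[20]) & retained
            sens.append(len(called & true) / len(true))
            fpr.append(len(called - true) / len(retained - true))
        assert np.mean(sens) >= 0.9
        assert np.mean(fpr) <= 0.01

    def test_type_one_calibration(self):
        """Welch p < 0.05 fraction near nominal on null data."""
        from dcmlnc import SimulationConfig, run_preprocessing, simulate_study

        fracs = []
        for seed in range(20):
            cfg = SimulationConfig(
                seed=seed, frac_de=0.0, n_hubs=0,
                n_chromosomes=3, chrom_length=2_000_000, n_coding=150, n_lnc_per_class=30,
            )
            study, _, _ = simulate_study(cfg)
            norm, filtered = run_preprocessing(study)
            de = differential_expression(norm, filtered.metadata, ("control", "dbdb", 6))
            fracs.append((de["p"] < 0.05).mean())
        assert 0.03 <= np.mean(fracs) <= 0.07

    def test_small_group_rejected(self, tiny_norm):
        norm, meta = tiny_norm
        meta_bad = meta.copy()
        meta_bad.loc[meta_bad.index[0], "genotype"] = "other"
        meta_bad = meta_bad[meta_bad["genotype"].isin(["other", "dbdb"])]
        with pytest.raises(ValueError):
            differential_expression(norm, meta_bad, ("other", "dbdb", 6))


class TestOverlap:
    def test_set_arithmetic(self):
        a = DEGSets(up={"a", "b"}, down={"c"})
        b = DEGSets(up={"b"}, down={"c", "d"})
        rep = overlap_sets(a, b)
        assert rep["intersection"] == 2
        assert rep["multiplicity_total"] == 6
        assert rep["union"] == 4

    def test_disjoint(self):
        rep = overlap_sets(DEGSets({"a"}, set()), DEGSets({"b"}, set()))
        assert rep["intersection"] == 0

    def test_up_down_disjoint_enforced(self):
        with pytest.raises(ValueError):
            DEGSets(up={"a"}, down={"a"})


def brute_force_average_linkage(points, ids):
    """Exhaustive agglomeration oracle for small n (average linkage)."""
    clusters = {i: [i] for i in range(len(ids))}
    dist = {
        (i, j): float(np.linalg.norm(points[i] - points[j]))
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
    }

    def cdist(a, b):
        return float(
            np.mean(
                [dist[tuple(sorted((i, j)))] for i in clusters[a] for j in clusters[b]]
            )
        )

    merges = []
    alive = sorted(clusters)
    while len(alive) > 1:
        best = min(
            ((a, b) for i, a in enumerate(alive) for b in alive[i + 1 :]),
            key=lambda ab: (cdist(*ab), ab),
        )
        a, b = best
        merges.append((sorted(clusters[a]), sorted(clusters[b]), cdist(a, b)))
        new = max(clusters) + 1
        clusters[new] = clusters.pop(a) + clusters.pop(b)
        alive = sorted(clusters)
    return merges


class TestHierarchical:
    def _norm(self, values, ids):
        from dcmlnc import NormalizedMatrix

        cols = [f"s{j}" for j in range(values.shape[1])]
        return NormalizedMatrix(
            pd.DataFrame(values, index=pd.Index(ids, name="probe_id"), columns=cols)
        )

    def test_identical_profiles_merge_first(self):
        x = np.array([[1.0, 2, 3], [9, 9, 9], [1.0, 2, 3], [5, 0, 5]])
        norm = self._norm(x, ["a", "b", "c", "d"])
        leaves, z = hierarchical_order(norm, {"a", "b", "c", "d"})
        assert z[0, 2] == pytest.approx(0.0)
        first = {int(z[0, 0]), int(z[0, 1])}
        assert first == {0, 2}  # sorted ids: a, b, c, d -> a and c identical

    def test_matches_brute_force_on_four_leaves(self, rng):
        x = rng.normal(size=(4, 5))
        ids = ["a", "b", "c", "d"]
        norm = self._norm(x, ids)
        _, z = hierarchical_order(norm, set(ids), metric="euclidean", linkage="average")
        oracle = brute_force_average_linkage(x, ids)
        heights = sorted(m[2] for m in oracle)
        np.testing.assert_allclose(sorted(z[:, 2]), heights, rtol=1e-9)

    def test_leaf_order_invariant_to_row_permutation(self, rng):
        x = rng.normal(size=(6, 4))
        ids = [f"p{i}" for i in range(6)]
        norm1 = self._norm(x, ids)
        perm = rng.permutation(6)
        norm2 = self._norm(x[perm], [ids[i] for i in perm])
        l1, _ = hierarchical_order(norm1, set(ids))
        l2, _ = hierarchical_order(norm2, set(ids))
        assert l1 == l2

    def test_zero_variance_row_correlation_metric(self):
        x = np.array([[1.0, 2, 3, 4], [4, 4, 4, 4], [2, 4, 6, 8]])
        norm = self._norm(x, ["a", "b", "c"])
        leaves, z = hierarchical_order(norm, {"a", "b", "c"}, metric="correlation")
        assert len(leaves) == 3  # constant row handled, not NaN
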