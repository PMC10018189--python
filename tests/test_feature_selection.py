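import itertools

import numpy as np
import pytest
from scipy.stats import f_oneway

import cgpromoter as cg
from conftest import random_labeled_matrix


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def naive_agglomerative_pairs(columns: np.ndarray, method: str):
    """Brute-force agglomerative clustering of feature columns.

    Maintains explicit inter-cluster distances via the Lance-Williams
    update and records every merge; returns the leaf-leaf merges (pairs)
    and the remaining singletons. Deliberately independent of scipy's
    linkage implementation.
    """
    d = columns.shape[0]
    active = {i: [i] for i in range(d)}
    sizes = {i: 1 for i in range(d)}
    dist = {}
    for i, j in itertools.combinations(range(d), 2):
        dist[(i, j)] = float(np.linalg.norm(columns[i] - columns[j]))
    pairs, next_id = [], d
    while len(active) > 1:
        (i, j), dij = min(dist.items(), key=lambda kv: kv[1])
        if i < d and j < d:
            pairs.append((i, j))
        new = next_id
        next_id += 1
        ni, nj = sizes[i], sizes[j]
        for k in list(active):
            if k in (i, j):
                continue
            dik = dist[tuple(sorted((i, k)))]
            djk = dist[tuple(sorted((j, k)))]
            nk = sizes[k]
            if method == "single":
                dnew = min(dik, djk)
            elif method == "complete":
                dnew = max(dik, djk)
            elif method == "ward":
                dnew = np.sqrt(
                    ((ni + nk) * dik**2 + (nj + nk) * djk**2 - nk * dij**2)
                    / (ni + nj + nk)
                )
            else:
                raise ValueError(method)
            dist[tuple(sorted((new, k)))] = float(dnew)
        for k in (i, j):
            for key in [key for key in dist if k in key]:
                del dist[key]
        active[new] = active.pop(i) + active.pop(j)
        sizes[new] = ni + nj
    paired = {x for p in pairs for x in p}
    singletons = [x for x in range(d) if x not in paired]
    return pairs, singletons


def textbook_two_group_f(x0: np.ndarray, x1: np.ndarray) -> float:
    """One-way ANOVA F written out from sums of squares."""
    n0, n1 = len(x0), len(x1)
    grand = (x0.sum() + x1.sum()) / (n0 + n1)
    ssb = n0 * (x0.mean() - grand) ** 2 + n1 * (x1.mean() - grand) ** 2
    ssw = ((x0 - x0.mean()) ** 2).sum() + ((x1 - x1.mean()) ** 2).sum()
    return (ssb / 1.0) / (ssw / (n0 + n1 - 2))


# ---------------------------------------------------------------------------
# ANOVA F
# ---------------------------------------------------------------------------

class TestAnovaF:
    def test_hand_case(self):
        # group0 = [1, 2], group1 = [3, 4]: SSB = 4, SSW = 1 on 2 df -> F = 8
        fm = cg.FeatureMatrix(np.array([[1.0], [2.0], [3.0], [4.0]]),
                              ["f0"], labels=[0, 0, 1, 1])
        F = cg.anova_f(fm)
        assert F.F[0] == pytest.approx(8.0)

    def test_matches_oracles_on_random_matrix(self, rng):
        fm = random_labeled_matrix(rng, n=20, d=10)
        F = cg.anova_f(fm)
        x0, x1 = fm.values[fm.labels == 0], fm.values[fm.labels == 1]
        for j in range(10):
            assert F.F[j] == pytest.approx(
                textbook_two_group_f(x0[:, j], x1[:, j]), rel=1e-10)
        scipy_F, _ = f_oneway(x0, x1)
        np.testing.assert_allclose(F.F, scipy_F, rtol=1e-10)

    def test_constant_feature_is_zero_with_warning(self, rng, caplog):
        fm = random_labeled_matrix(rng, n=10, d=3)
        fm.values[:, 1] = 4.2
        with caplog.at_level("WARNING", logger="cgpromoter"):
            F = cg.anova_f(fm)
        assert F.F[1] == 0.0
        assert any("F = 0" in r.message for r in caplog.records)

    def test_perfect_separator_is_inf_sentinel(self, rng):
        fm = random_labeled_matrix(rng, n=10, d=2)
        fm.values[:, 0] = fm.labels  # zero within-class variance, classes differ
        F = cg.anova_f(fm)
        assert np.isinf(F.F[0]) and np.isfinite(F.F[1])

    def test_invariance_to_order_and_relabeling(self, rng):
        fm = random_labeled_matrix(rng, n=16, d=6)
        F = cg.anova_f(fm)
        perm = rng.permutation(16)
        F_perm = cg.anova_f(cg.FeatureMatrix(
            fm.values[perm], fm.feature_ids, labels=fm.labels[perm]))
        F_swap = cg.anova_f(cg.FeatureMatrix(
            fm.values, fm.feature_ids, labels=1 - fm.labels))
        np.testing.assert_allclose(F_perm.F, F.F, rtol=1e-10)
        np.testing.assert_allclose(F_swap.F, F.F, rtol=1e-10)

    def test_single_class_rejected(self, rng):
        fm = cg.FeatureMatrix(rng.normal(size=(6, 2)), ["a", "b"],
                              labels=[1] * 6)
        with pytest.raises(ValueError):
            cg.anova_f(fm)


# ---------------------------------------------------------------------------
# First-level pairing
# ---------------------------------------------------------------------------

class TestFirstLevelPairs:
    def _toy(self):
        """Three features where columns 1 and 2 (0-based) are near-duplicates."""
        rng = np.random.default_rng(0)
        f2 = rng.normal(size=30)
        f3 = f2 + rng.normal(scale=0.01, size=30)
        f1 = rng.normal(loc=10, size=30)
        return cg.FeatureMatrix(np.column_stack([f1, f2, f3]),
                                ["f1", "f2", "f3"],
                                labels=[0] * 15 + [1] * 15)

    def test_three_feature_toy(self):
        pairing = cg.first_level_pairs(self._toy(), cg.LinkageConfig(scale=False))
        assert pairing.pairs == [(1, 2)]
        assert pairing.singletons == [0]

    def test_two_features_forced_pair(self, rng):
        fm = cg.FeatureMatrix(rng.normal(size=(10, 2)), ["a", "b"])
        pairing = cg.first_level_pairs(fm)
        assert pairing.pairs == [(0, 1)] and pairing.singletons == []

    def test_exact_duplicate_always_pairs(self, rng):
        X = rng.normal(size=(15, 6))
        X[:, 4] = X[:, 2]  # distance 0 to its copy
        fm = cg.FeatureMatrix(X, [f"f{j}" for j in range(6)])
        pairing = cg.first_level_pairs(fm, cg.LinkageConfig(scale=False))
        assert (2, 4) in pairing.pairs

    @pytest.mark.parametrize("method", ["ward", "complete", "single"])
    def test_matches_naive_agglomerative_oracle(self, method, rng):
        for _ in range(5):
            n, d = int(rng.integers(8, 30)), int(rng.integers(3, 12))
            fm = cg.FeatureMatrix(rng.normal(size=(n, d)),
                                  [f"f{j}" for j in range(d)])
            pairing = cg.first_level_pairs(
                fm, cg.LinkageConfig(method=method, scale=False))
            exp_pairs, exp_singletons = naive_agglomerative_pairs(
                fm.values.T, method)
            assert sorted(pairing.pairs) == sorted(
                tuple(sorted(p)) for p in exp_pairs)
            assert sorted(pairing.singletons) == sorted(exp_singletons)

    def test_partition_invariant(self, rng):
        for d in (2, 3, 7, 12):
            fm = cg.FeatureMatrix(rng.normal(size=(20, d)),
                                  [f"f{j}" for j in range(d)])
            pairing = cg.first_level_pairs(fm)
            flat = sorted(j for p in pairing.pairs for j in p) + pairing.singletons
            assert sorted(flat) == list(range(d))
            assert 2 * len(pairing.pairs) + len(pairing.singletons) == d

    def test_ward_requires_euclidean(self):
        with pytest.raises(ValueError, match="Euclidean"):
            cg.LinkageConfig(method="ward", metric="correlation")


# ---------------------------------------------------------------------------
# Retention
# ---------------------------------------------------------------------------

class TestSelectFeatures:
    def test_larger_f_wins_and_singletons_kept(self):
        F = cg.FValueVector(np.array([1.0, 9.0, 3.0]),
                            np.zeros(3), np.ones(3))
        pairing = cg.PairingResult([(1, 2)], [0], cg.LinkageConfig(), 3)
        sel = cg.select_features(F, pairing, seed=0)
        assert sel.retained == [0, 1] and sel.removed == [2]
        assert not sel.decisions[0].tie_broken

    def test_all_singletons_keeps_everything(self):
        F = cg.FValueVector(np.ones(4), np.ones(4), np.ones(4))
        pairing = cg.PairingResult([], [0, 1, 2, 3], cg.LinkageConfig(), 4)
        assert cg.select_features(F, pairing).retained == [0, 1, 2, 3]

    def test_tie_break_is_seeded_and_near_uniform(self):
        F = cg.FValueVector(np.array([2.0, 2.0]), np.ones(2), np.ones(2))
        pairing = cg.PairingResult([(0, 1)], [], cg.LinkageConfig(), 2)
        winners = [cg.select_features(F, pairing, seed=s).retained[0]
                   for s in range(1000)]
        freq0 = winners.count(0) / 1000
        assert 0.45 <= freq0 <= 0.55
        assert cg.select_features(F, pairing, seed=17).retained == \
            cg.select_features(F, pairing, seed=17).retained

    def test_inf_sentinel_outranks_finite(self):
        F = cg.FValueVector(np.array([np.inf, 1e9]), np.ones(2), np.ones(2))
        pairing = cg.PairingResult([(0, 1)], [], cg.LinkageConfig(), 2)
        assert cg.select_features(F, pairing).retained == [0]

    def test_dimension_mismatch_rejected(self):
        F = cg.FValueVector(np.ones(3), np.ones(3), np.ones(3))
        pairing = cg.PairingResult([(0, 1)], [], cg.LinkageConfig(), 2)
        with pytest.raises(ValueError, match="features"):
            cg.select_features(F, pairing)


class TestApplySelection:
    def test_subsets_columns(self, rng):
        fm = random_labeled_matrix(rng, n=10, d=5)
        _, sel, _, pairing = cg.select_pipeline(fm, seed=0)
        reduced = cg.apply_selection(fm, sel)
        assert reduced.n_features == 5 - len(pairing.pairs)
        assert reduced.feature_ids == [fm.feature_ids[j] for j in sel.retained]
        np.testing.assert_array_equal(reduced.labels, fm.labels)

    def test_identity_selection(self, rng):
        fm = random_labeled_matrix(rng, n=10, d=3)
        sel = cg.SelectionResult([0, 1, 2], [], [], 0, cg.LinkageConfig())
        np.testing.assert_array_equal(
            cg.apply_selection(fm, sel).values, fm.values)

    def test_shuffled_columns_with_matching_ids_rejected(self, rng):
        fm = random_labeled_matrix(rng, n=10, d=4)
        _, sel, _, _ = cg.select_pipeline(fm, seed=0)
        perm = [2, 0, 3, 1]
        shuffled = cg.FeatureMatrix(fm.values[:, perm],
                                    [fm.feature_ids[j] for j in perm],
                                    labels=fm.labels)
        with pytest.raises(ValueError, match="feature_ids"):
            cg.apply_selection(shuffled, sel)


class TestPipelineProperties:
    def test_retained_count_identity(self, rng):
        for _ in range(5):
            fm = random_labeled_matrix(
                rng, n=int(rng.integers(8, 30)), d=int(rng.integers(2, 12)))
            _, sel, _, pairing = cg.select_pipeline(fm, seed=0)
            assert len(sel.retained) == pairing.d - len(pairing.pairs)

    def test_closest_pair_loses_a_member(self, rng):
        # the globally closest column pair merges first, so it is always a
        # first-level pair and selection removes one of the two; the minimum
        # pairwise distance among retained features can only grow
        from scipy.spatial.distance import pdist, squareform

        for _ in range(5):
            fm = random_labeled_matrix(rng, n=20, d=8)
            _, sel, _, _ = cg.select_pipeline(
                fm, cg.LinkageConfig(scale=False), seed=0)
            D = squareform(pdist(fm.values.T))
            np.fill_diagonal(D, np.inf)
            before = D.min()
            after = D[np.ix_(sel.retained, sel.retained)].min()
            assert after >= before - 1e-12

    def test_report_bookkeeping(self, rng, tmp_path):
        fm = random_labeled_matrix(rng, n=24, d=10)
        _, sel, F, pairing = cg.select_pipeline(fm, seed=1)
        path = tmp_path / "report.json"
        cg.feature_selection.write_selection_report(sel, F, path)
        import json

        report = json.loads(path.read_text())
        assert report["n_retained"] == report["n_features"] - report["n_pairs"]
        assert report["n_pairs"] * 2 + report["n_singletons"] == report["n_features"]
        assert len(report["retained_feature_ids"]) == report["n_retained"]
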