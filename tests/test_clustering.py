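"""Weighted Manhattan distances, average-linkage agglomeration, dendrogram cuts."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from coachcohort import (
    DataError,
    agglomerate_average,
    cluster_profiles,
    cut,
    pairwise_distances,
    weighted_manhattan,
)
from coachcohort.clustering import DistanceMatrix
from coachcohort.errors import ConfigError


def bruteforce_average_linkage(D):
    """Exhaustive UPGMA oracle: recompute every inter-cluster average from the
    original distance matrix at each step; ties broken by the smallest
    (node-id, node-id) pair.  Averages use math.fsum (correctly rounded, so
    independent of summation order).  Independent of the package
    implementation."""
    import math

    n = D.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    merges = []
    next_id = n
    while len(clusters) > 1:
        best_pair, best_avg = None, np.inf
        for a, b in itertools.combinations(sorted(clusters), 2):
            pairs = [(i, j) for i in clusters[a] for j in clusters[b]]
            avg = math.fsum(D[i, j] for i, j in pairs) / len(pairs)
            if avg < best_avg:
                best_pair, best_avg = (a, b), avg
        a, b = best_pair
        merges.append((a, b, best_avg, len(clusters[a] | clusters[b])))
        clusters[next_id] = clusters.pop(a) | clusters.pop(b)
        next_id += 1
    return merges


def matrix_from(D, ids=None):
    D = np.asarray(D, dtype=float)
    ids = ids or [f"p{i}" for i in range(D.shape[0])]
    return DistanceMatrix(ids, D)


def line_matrix(points):
    pts = np.asarray(points, dtype=float)
    return matrix_from(np.abs(pts[:, None] - pts[None, :]))


class TestWeightedManhattan:
    def test_identical_participants_at_zero(self):
        assert weighted_manhattan([1.0, 2.0], [1.0, 2.0], [1.0, 1.0]) == 0.0

    def test_hand_example(self):
        assert weighted_manhattan([1, 0], [0, 2], [1, 0.5]) == 1 * 1 + 0.5 * 2 == 2.0

    def test_all_zero_weights(self):
        assert weighted_manhattan([1, 2, 3], [9, 9, 9], [0, 0, 0]) == 0.0

    def test_no_shared_variables_rejected(self):
        with pytest.raises(DataError, match="share no"):
            weighted_manhattan([np.nan, 1.0], [2.0, np.nan], [1.0, 1.0])

    def test_missing_values_rescaled_by_shared_weight(self):
        # One of two unit-weight variables missing: the other is scaled x2.
        d = weighted_manhattan([1.0, np.nan], [3.0, 5.0], [1.0, 1.0])
        assert d == pytest.approx(2.0 * 2.0)

    @settings(max_examples=100, deadline=None)
    @given(
        u=st.lists(st.floats(-10, 10), min_size=1, max_size=6),
        data=st.data(),
    )
    def test_metric_properties(self, u, data):
        n = len(u)
        v = data.draw(st.lists(st.floats(-10, 10), min_size=n, max_size=n))
        t = data.draw(st.lists(st.floats(-10, 10), min_size=n, max_size=n))
        w = data.draw(st.lists(st.floats(0, 2), min_size=n, max_size=n))
        c = data.draw(st.floats(0.01, 100))
        duv = weighted_manhattan(u, v, w)
        assert duv >= 0
        assert duv == weighted_manhattan(v, u, w)  # symmetry
        assert weighted_manhattan(u, u, w) == 0.0
        # triangle inequality
        assert duv <= (
            weighted_manhattan(u, t, w) + weighted_manhattan(t, v, w) + 1e-9
        )
        # weight-scaling equivariance
        assert weighted_manhattan(u, v, [c * x for x in w]) == pytest.approx(
            c * duv, rel=1e-9, abs=1e-12
        )


class TestPairwiseDistances:
    def test_identical_pair_zero_matrix(self):
        z = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"], columns=["x", "y"])
        D = pairwise_distances(z, {"x": 1.0, "y": 1.0})
        assert np.all(D.values == 0)

    def test_colinear_points_unit_weight(self):
        z = pd.DataFrame({"x": [0.0, 1.0, 10.0]}, index=list("abc"))
        D = pairwise_distances(z, {"x": 1.0})
        expected = np.abs(np.subtract.outer([0, 1, 10], [0, 1, 10]))
        assert np.allclose(D.values, expected)

    def test_single_participant_rejected(self):
        z = pd.DataFrame({"x": [0.0]}, index=["a"])
        with pytest.raises(DataError):
            pairwise_distances(z, {"x": 1.0})

    def test_triangle_inequality_on_random_frame(self):
        rng = np.random.default_rng(5)
        z = pd.DataFrame(rng.normal(size=(8, 4)), columns=list("wxyz"))
        D = pairwise_distances(z, {c: 1.0 for c in "wxyz"}).values
        for i, j, k in itertools.permutations(range(8), 3):
            assert D[i, j] <= D[i, k] + D[k, j] + 1e-9


class TestAgglomerateAverage:
    def test_three_point_hand_example(self):
        tree = agglomerate_average(line_matrix([0, 1, 10]))
        assert [(m.left, m.right) for m in tree.merges] == [(0, 1), (2, 3)]
        assert [m.height for m in tree.merges] == [1.0, 9.5]

    def test_two_points_single_merge(self):
        tree = agglomerate_average(matrix_from([[0, 3], [3, 0]]))
        assert len(tree.merges) == 1 and tree.merges[0].height == 3.0

    def test_random_instances_match_bruteforce(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(3, 8))
            pts = rng.normal(size=(n, 3))
            D = np.sum(np.abs(pts[:, None] - pts[None]), axis=2)
            tree = agglomerate_average(matrix_from(D))
            oracle = bruteforce_average_linkage(D)
            assert [(m.left, m.right, m.size) for m in tree.merges] == [
                (a, b, s) for a, b, _, s in oracle
            ]
            np.testing.assert_allclose(
                [m.height for m in tree.merges], [h for *_, h, _ in oracle]
            )

    def test_integer_tie_breaking_matches_bruteforce(self):
        # All pairs at distance 1: merge order is decided purely by node ids.
        D = np.ones((5, 5)) - np.eye(5)
        tree = agglomerate_average(matrix_from(D))
        oracle = bruteforce_average_linkage(D)
        assert [(m.left, m.right) for m in tree.merges] == [
            (a, b) for a, b, *_ in oracle
        ]

    def test_heights_match_scipy_average_linkage(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(size=(20, 5))
        D = np.sum(np.abs(pts[:, None] - pts[None]), axis=2)
        tree = agglomerate_average(matrix_from(D))
        Z = hierarchy.linkage(squareform(D, checks=False), method="average")
        np.testing.assert_allclose(
            sorted(m.height for m in tree.merges), sorted(Z[:, 2]), rtol=1e-10
        )

    def test_heights_monotone_and_sizes_conserved(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(12, 3))
        D = np.sum(np.abs(pts[:, None] - pts[None]), axis=2)
        tree = agglomerate_average(matrix_from(D))
        heights = [m.height for m in tree.merges]
        assert heights == sorted(heights)
        assert tree.merges[-1].size == 12

    def test_nonfinite_rejected(self):
        D = np.zeros((3, 3))
        D[0, 1] = D[1, 0] = np.inf
        with pytest.raises(DataError):
            matrix_from(D)


class TestCut:
    tree = agglomerate_average(line_matrix([0, 1, 10]))

    def test_above_max_height_single_cluster(self):
        flat = cut(self.tree, 1.0, mode="fraction")
        assert flat.n_clusters == 1 and flat.sizes[0] == 3

    def test_below_min_height_all_singletons(self):
        flat = cut(self.tree, 0.5, mode="absolute")
        assert flat.n_clusters == 3

    def test_between_heights_splits_as_expected(self):
        flat = cut(self.tree, 5.0, mode="absolute", min_cluster_size=2)
        groups = {}
        for pid, cid in flat.labels.items():
            groups.setdefault(cid, set()).add(pid)
        assert set(map(frozenset, groups.values())) == {
            frozenset({"p0", "p1"}), frozenset({"p2"})
        }
        assert flat.outlier_flags == {0: False, 1: True}

    def test_cluster_ids_ordered_by_decreasing_size(self):
        flat = cut(self.tree, 5.0, mode="absolute")
        assert flat.sizes[0] >= flat.sizes[1]

    def test_proportions_sum_to_one(self):
        flat = cut(self.tree, 5.0, mode="absolute")
        assert sum(flat.proportions.values()) == pytest.approx(1.0)

    def test_cluster_count_monotone_in_threshold(self):
        rng = np.random.default_rng(17)
        pts = rng.normal(size=(15, 2))
        D = np.sum(np.abs(pts[:, None] - pts[None]), axis=2)
        tree = agglomerate_average(matrix_from(D))
        counts = [
            cut(tree, t, mode="fraction").n_clusters
            for t in np.linspace(0.01, 1.0, 25)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_weight_scaling_leaves_flat_clustering_unchanged(self):
        rng = np.random.default_rng(23)
        z = pd.DataFrame(rng.normal(size=(10, 4)), columns=list("wxyz"))
        w1 = {c: 1.0 for c in "wxyz"}
        w2 = {c: 2.0 for c in "wxyz"}
        t1 = agglomerate_average(pairwise_distances(z, w1))
        t2 = agglomerate_average(pairwise_distances(z, w2))
        np.testing.assert_allclose(
            [2 * m.height for m in t1.merges], [m.height for m in t2.merges]
        )
        assert cut(t1, 0.4).labels == cut(t2, 0.4).labels

    def test_invalid_mode_and_threshold_rejected(self):
        with pytest.raises(ConfigError):
            cut(self.tree, 0.5, mode="sideways")
        with pytest.raises(ConfigError):
            cut(self.tree, 1.5, mode="fraction")
        with pytest.raises(ConfigError):
            cut(self.tree, -1.0, mode="absolute")


class TestClusterProfiles:
    def _zframe(self):
        rng = np.random.default_rng(2)
        z = pd.DataFrame(
            rng.normal(size=(6, 2)),
            index=[f"p{i}" for i in range(6)],
            columns=["moca", "mna_mini"],
        )
        return z

    def test_singleton_cluster_is_own_vector(self, variable_specs):
        z = self._zframe()
        D = pairwise_distances(z, {"moca": 1.0, "mna_mini": 1.0})
        tree = agglomerate_average(D)
        flat = cut(tree, 1e-9, mode="absolute")  # all singletons
        prof = cluster_profiles(flat, z, ["cognitive", "nutritional"], variable_specs)
        for pid, cid in flat.labels.items():
            assert prof.loc[cid, "moca"] == pytest.approx(z.loc[pid, "moca"])

    def test_planted_shift_separates_profiles(self, variable_specs):
        rng = np.random.default_rng(4)
        z = pd.DataFrame(
            np.concatenate([rng.normal(-2, 0.3, (5, 1)), rng.normal(2, 0.3, (5, 1))]),
            index=[f"p{i}" for i in range(10)],
            columns=["mna_mini"],
        )
        D = pairwise_distances(z, {"mna_mini": 1.0})
        flat = cut(agglomerate_average(D), 0.3, mode="fraction")
        prof = cluster_profiles(flat, z, ["nutritional"], variable_specs)
        assert abs(prof["mna_mini"].iloc[0] - prof["mna_mini"].iloc[1]) > 3

    def test_whole_cohort_profile_near_zero_without_outliers(self, variable_specs):
        from coachcohort import fit_standardization

        rng = np.random.default_rng(8)
        raw = rng.normal(25, 3, 30)
        model = fit_standardization({"moca": raw.tolist()})
        kept = [x for x in raw if model.variables["moca"].fences[0] <= x <= model.variables["moca"].fences[1]]
        z = pd.DataFrame(
            {"moca": [model.standardize("moca", x) for x in kept]},
            index=[f"p{i}" for i in range(len(kept))],
        )
        D = pairwise_distances(z, {"moca": 1.0})
        flat = cut(agglomerate_average(D), 1.0, mode="fraction")
        prof = cluster_profiles(flat, z, ["cognitive"], variable_specs)
        assert prof.loc[0, "moca"] == pytest.approx(0.0, abs=1e-9)

    def test_empty_selection_rejected(self, variable_specs):
        z = self._zframe()
        flat = cut(agglomerate_average(pairwise_distances(z, {"moca": 1.0, "mna_mini": 1.0})), 1.0)
        with pytest.raises(DataError):
            cluster_profiles(flat, z, [], variable_specs)
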