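"""Distances, agglomeration against a brute-force oracle, dendrogram
slicing, and rank orders."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clustermat import (
    DistanceSpec,
    LabeledMatrix,
    LinkageSpec,
    LinkageTree,
    leaf_ordering,
    linkage,
    pairwise_distance,
    rank_orders,
    similarity_matrix,
    slice_groups,
)
from conftest import brute_force_agglomerate, random_labeled_matrix


def _mat(values):
    values = np.asarray(values, dtype=float)
    return LabeledMatrix(
        values,
        [f"r{i}" for i in range(values.shape[0])],
        [f"c{j}" for j in range(values.shape[1])],
    )


def _random_distance(seed, n):
    rng = np.random.default_rng(seed)
    a = rng.random((n, n))
    d = (a + a.T) / 2
    np.fill_diagonal(d, 0.0)
    return d


def _random_tree(seed, n):
    return linkage(_random_distance(seed, n))


class TestPairwiseDistance:
    def test_identical_vectors_distance_zero(self):
        d = pairwise_distance(_mat([[1, 2, 3], [1, 2, 3]]))
        assert d[0, 1] == pytest.approx(0, abs=1e-12)

    def test_orthogonal_cosine_distance_one(self):
        d = pairwise_distance(_mat([[1, 0], [0, 1]]))
        assert d[0, 1] == pytest.approx(1.0)

    def test_cosine_closed_form(self):
        d = pairwise_distance(_mat([[1, 0], [1, 1]]))
        assert d[0, 1] == pytest.approx(1 - 1 / math.sqrt(2), abs=1e-12)

    def test_symmetric_zero_diagonal(self):
        m = random_labeled_matrix(2, 8, 5, with_categories=False)
        d = pairwise_distance(m)
        assert np.array_equal(d, d.T)
        assert np.all(np.diag(d) == 0)

    def test_cosine_range_nonnegative_data(self):
        rng = np.random.default_rng(5)
        m = _mat(np.abs(rng.normal(size=(10, 6))))
        d = pairwise_distance(m)
        assert np.all(d >= 0) and np.all(d <= 1 + 1e-12)

    def test_cosine_range_signed_data(self):
        m = random_labeled_matrix(6, 10, 6, with_categories=False)
        d = pairwise_distance(m)
        assert np.all(d >= 0) and np.all(d <= 2 + 1e-12)

    def test_zero_vector_policy(self):
        d = pairwise_distance(_mat([[0, 0], [1, 2], [0, 0]]))
        assert d[0, 1] == 1.0
        assert d[0, 2] == 0.0

    def test_missing_entries_imputed_to_vector_mean(self):
        m = _mat([[1.0, np.nan, 3.0], [1.0, 2.0, 3.0]])
        d = pairwise_distance(m)
        full = _mat([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert d[0, 1] == pytest.approx(pairwise_distance(full)[0, 1])

    def test_single_vector_rejected(self):
        with pytest.raises(ValueError):
            pairwise_distance(_mat([[1, 2]]))

    def test_euclidean_metric(self):
        d = pairwise_distance(_mat([[0, 0], [3, 4]]), spec=DistanceSpec("euclidean"))
        assert d[0, 1] == pytest.approx(5.0)


class TestLinkage:
    def test_three_point_hand_oracle(self):
        d = np.array([[0, 1, 4], [1, 0, 5], [4, 5, 0]], dtype=float)
        t = linkage(d)
        assert t.merges[0] == (0, 1, 1.0, 2)
        a, b, h, size = t.merges[1]
        assert (a, b, size) == (3, 2, 3)
        assert h == pytest.approx(4.5)

    def test_single_leaf_empty_merges(self):
        t = linkage(np.zeros((1, 1)))
        assert t.merges == []
        assert t.leaf_order == [0]

    @pytest.mark.parametrize("method", ["average", "single", "complete"])
    def test_matches_brute_force_oracle(self, method):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(2, 9))
            d = _random_distance(seed + 1000, n)
            got = linkage(d, LinkageSpec(method)).merges
            want = brute_force_agglomerate(d, method)
            assert len(got) == len(want)
            for g, w in zip(got, want):
                assert g[0] == w[0] and g[1] == w[1] and g[3] == w[3]
                assert g[2] == pytest.approx(w[2], abs=1e-9)

    def test_matches_scipy_on_tie_free_instance(self):
        # independent cross-check on a metric instance without ties
        from scipy.cluster.hierarchy import linkage as scipy_linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(42)
        X = rng.normal(size=(12, 5))
        m = _mat(X)
        d = pairwise_distance(m, spec=DistanceSpec("euclidean"))
        ours = linkage(d)
        theirs = scipy_linkage(squareform(d, checks=False), method="average")
        np.testing.assert_allclose(
            sorted(h for *_, h, _ in ours.merges), sorted(theirs[:, 2]), atol=1e-9
        )

    def test_heights_non_decreasing(self):
        for seed in range(20):
            t = _random_tree(seed, 10)
            heights = [h for _, _, h, _ in t.merges]
            assert heights == sorted(heights)

    def test_asymmetric_rejected(self):
        d = np.array([[0, 1], [2, 0]], dtype=float)
        with pytest.raises(ValueError):
            linkage(d)

    def test_negative_rejected(self):
        d = np.array([[0, -1], [-1, 0]], dtype=float)
        with pytest.raises(ValueError):
            linkage(d)


class TestLeafOrdering:
    def test_three_point_order(self):
        d = np.array([[0, 1, 4], [1, 0, 5], [4, 5, 0]], dtype=float)
        assert linkage(d).leaf_order == [0, 1, 2]

    def test_singleton(self):
        assert leaf_ordering(LinkageTree(1, [])) == [0]

    def test_smallest_index_subtree_first(self):
        # leaf 0 merges late: its subtree must still be placed first
        d = np.array(
            [
                [0.0, 9.0, 9.0, 1.0],
                [9.0, 0.0, 0.5, 9.0],
                [9.0, 0.5, 0.0, 9.0],
                [1.0, 9.0, 9.0, 0.0],
            ]
        )
        t = linkage(d)
        order = t.leaf_order
        assert order.index(0) < order.index(1)
        assert order.index(0) < order.index(2)

    def test_is_permutation(self):
        for seed in range(10):
            t = _random_tree(seed, 12)
            assert sorted(t.leaf_order) == list(range(12))


class TestSliceGroups:
    def _tree3(self):
        d = np.array([[0, 1, 4], [1, 0, 5], [4, 5, 0]], dtype=float)
        return linkage(d)

    def test_tiny_fraction_all_singletons(self):
        g = slice_groups(self._tree3(), [1e-9])
        assert g.n_groups(0) == 3

    def test_fraction_one_single_group(self):
        g = slice_groups(self._tree3(), [1.0])
        assert g.assignments[0] == [0, 0, 0]

    def test_mid_fraction_hand_cut(self):
        # cut at 0.5 * 4.5 = 2.25: {A,B} merged at 1, C separate
        g = slice_groups(self._tree3(), [0.5])
        assert g.assignments[0] == [0, 0, 1]

    def test_group_ids_follow_leaf_order(self):
        for seed in range(10):
            t = _random_tree(seed, 9)
            g = slice_groups(t, [0.4])
            seen = []
            for leaf in t.leaf_order:
                gid = g.assignments[0][leaf]
                if gid not in seen:
                    seen.append(gid)
            assert seen == list(range(len(seen)))

    @settings(max_examples=200, deadline=None)
    @given(
        seed=st.integers(0, 100_000),
        f1=st.floats(0.01, 0.98),
        gap=st.floats(0.01, 0.5),
    )
    def test_refinement_monotonicity(self, seed, f1, gap):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        t = _random_tree(seed, n)
        f2 = min(f1 + gap, 1.0)
        if f2 <= f1:
            return
        g = slice_groups(t, [f1, f2])
        fine, coarse = g.assignments
        mapping = {}
        for f, c in zip(fine, coarse):
            assert mapping.setdefault(f, c) == c

    def test_group_count_between_merge_heights(self):
        t = self._tree3()
        # cut strictly between the two merge heights (1 and 4.5)
        frac = 2.0 / 4.5
        g = slice_groups(t, [frac])
        # leaves - merges below cut = 3 - 1 = 2 groups
        assert g.n_groups(0) == 2

    def test_bad_fraction_rejected(self):
        with pytest.raises(ValueError):
            slice_groups(self._tree3(), [0.0])
        with pytest.raises(ValueError):
            slice_groups(self._tree3(), [0.5, 0.5])


class TestRankOrders:
    def test_sum_descending(self):
        m = _mat([[1, 2], [4, 6], [3, 4]])  # sums 3, 10, 7
        r = rank_orders(m)
        assert r["rows"].orders["sum"] == [1, 2, 0]

    def test_alphabetical_case_insensitive(self):
        m = LabeledMatrix(np.zeros((2, 1)), ["b", "A"], ["x"])
        r = rank_orders(m)
        assert r["rows"].orders["alphabetical"] == [1, 0]

    def test_equal_sums_stable(self):
        m = _mat(np.ones((4, 3)))
        r = rank_orders(m)
        assert r["rows"].orders["sum"] == [0, 1, 2, 3]

    def test_cluster_order_is_leaf_order(self):
        m = random_labeled_matrix(3, 7, 5, with_categories=False)
        t = linkage(pairwise_distance(m))
        r = rank_orders(m, t_rows=t)
        assert r["rows"].orders["cluster"] == t.leaf_order


class TestSimilarityMatrix:
    def test_diagonal_exactly_one(self):
        m = random_labeled_matrix(4, 6, 5, with_categories=False)
        s = similarity_matrix(m, "rows")
        assert np.all(np.diag(s.values) == 1.0)

    def test_closed_form_off_diagonal(self):
        s = similarity_matrix(_mat([[1, 0], [1, 1]]), "rows")
        assert s.values[0, 1] == pytest.approx(1 / math.sqrt(2), abs=1e-12)

    def test_equals_one_minus_distance(self):
        m = random_labeled_matrix(5, 10, 6, with_categories=False)
        s = similarity_matrix(m, "rows")
        d = pairwise_distance(m, "rows")
        off = ~np.eye(10, dtype=bool)
        np.testing.assert_allclose(s.values[off], (1 - d)[off], atol=1e-12)

    def test_labels_and_categories_copied(self):
        m = random_labeled_matrix(6, 5, 4)
        s = similarity_matrix(m, "columns")
        assert s.row_labels == m.col_labels == s.col_labels
        assert [t.name for t in s.row_categories] == [t.name for t in m.col_categories]
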