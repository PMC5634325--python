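"""Normalization and filtering contracts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from clustermat import (
    FilterSpec,
    LabeledMatrix,
    NormalizationSpec,
    filter_missing,
    filter_top,
    quantile_normalize,
    ratio_to_reference,
    zscore,
)
from conftest import random_labeled_matrix


def _mat(values, row_prefix="r", col_prefix="c"):
    values = np.asarray(values, dtype=float)
    return LabeledMatrix(
        values,
        [f"{row_prefix}{i}" for i in range(values.shape[0])],
        [f"{col_prefix}{j}" for j in range(values.shape[1])],
    )


class TestZscore:
    def test_simple_row(self):
        z = zscore(_mat([[1, 2, 3]]), NormalizationSpec(axis="rows", ddof=1))
        np.testing.assert_allclose(z.values, [[-1, 0, 1]])

    def test_constant_row_maps_to_zeros(self):
        z = zscore(_mat([[5, 5, 5]]))
        np.testing.assert_array_equal(z.values, [[0, 0, 0]])

    def test_rows_have_mean_zero_sd_one(self):
        m = random_labeled_matrix(3, 20, 10, with_categories=False)
        z = zscore(m, NormalizationSpec(axis="rows", ddof=1))
        np.testing.assert_allclose(z.values.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(z.values.std(axis=1, ddof=1), 1, atol=1e-9)

    def test_idempotent(self):
        m = random_labeled_matrix(7, 10, 8, with_categories=False)
        z1 = zscore(m)
        z2 = zscore(z1)
        np.testing.assert_allclose(z1.values, z2.values, atol=1e-9)

    def test_missingness_preserved(self):
        m = _mat([[1, np.nan, 3, 5]])
        z = zscore(m)
        assert np.isnan(z.values[0, 1])
        obs = z.values[0, [0, 2, 3]]
        np.testing.assert_allclose(obs.mean(), 0, atol=1e-12)

    def test_column_axis(self):
        z = zscore(_mat([[1], [2], [3]]), NormalizationSpec(axis="columns"))
        np.testing.assert_allclose(z.values.ravel(), [-1, 0, 1])

    def test_ddof_exceeding_axis_rejected(self):
        with pytest.raises(ValueError):
            zscore(_mat([[1, 2]]), NormalizationSpec(axis="rows", ddof=2))


class TestQuantileNormalize:
    def test_two_column_hand_oracle(self):
        # sorted columns [1,3,5] and [2,4,8]; per-rank means 1.5, 3.5, 6.5
        m = _mat(np.array([[1, 2], [3, 4], [5, 8]]))
        q = quantile_normalize(m, NormalizationSpec(method="quantile", axis="columns"))
        np.testing.assert_allclose(q.values, [[1.5, 1.5], [3.5, 3.5], [6.5, 6.5]])

    def test_rank_order_respected(self):
        m = _mat(np.array([[5, 2], [1, 4], [3, 8]]))
        q = quantile_normalize(m, NormalizationSpec(method="quantile", axis="columns"))
        for j in range(2):
            assert np.array_equal(
                np.argsort(q.values[:, j]), np.argsort(m.values[:, j])
            )

    def test_identical_columns_unchanged(self):
        col = np.array([2.0, 7.0, 5.0])
        m = _mat(np.column_stack([col, col]))
        q = quantile_normalize(m, NormalizationSpec(method="quantile", axis="columns"))
        np.testing.assert_allclose(q.values, m.values)

    def test_sorted_columns_identical_after(self):
        m = random_labeled_matrix(11, 15, 6, with_categories=False)
        q = quantile_normalize(m, NormalizationSpec(method="quantile", axis="columns"))
        cols = np.sort(q.values, axis=0)
        for j in range(1, cols.shape[1]):
            np.testing.assert_allclose(cols[:, j], cols[:, 0])

    def test_ties_receive_mean_of_tied_references(self):
        m = _mat(np.array([[1, 10], [1, 20], [5, 30]]))
        q = quantile_normalize(m, NormalizationSpec(method="quantile", axis="columns"))
        assert q.values[0, 0] == q.values[1, 0]

    def test_missing_rejected_by_default(self):
        m = _mat([[1, np.nan], [2, 3]])
        with pytest.raises(ValueError, match="missing"):
            quantile_normalize(m, NormalizationSpec(method="quantile", axis="columns"))

    def test_interpolating_variant_handles_missing(self):
        m = _mat([[1, 2], [np.nan, 4], [5, 8], [7, 9]])
        q = quantile_normalize(
            m, NormalizationSpec(method="quantile", axis="columns"),
            missing="interpolate",
        )
        assert np.isnan(q.values[1, 0])
        # non-missing entries keep their within-column rank order
        col0 = q.values[[0, 2, 3], 0]
        assert np.all(np.diff(col0) > 0)


class TestFilterTop:
    def test_variance_top_250_of_1000(self):
        m = random_labeled_matrix(5, 1000, 10, with_categories=False)
        out = filter_top(m, FilterSpec("variance", 250, "rows"))
        assert out.shape == (250, 10)

    def test_clamped_to_axis_length(self):
        m = random_labeled_matrix(6, 5, 3, with_categories=False)
        out = filter_top(m, FilterSpec("sum", 99, "rows"))
        assert out.row_labels == m.row_labels

    def test_equal_metric_stable_selection(self):
        m = _mat(np.tile([1.0, 2.0, 3.0], (6, 1)))
        out = filter_top(m, FilterSpec("variance", 3, "rows"))
        assert out.row_labels == ["r0", "r1", "r2"]

    def test_kept_metrics_dominate_dropped(self):
        m = random_labeled_matrix(17, 30, 8, with_categories=False)
        out = filter_top(m, FilterSpec("sum", 10, "rows"))
        kept = set(out.row_labels)
        sums = {lab: s for lab, s in zip(m.row_labels, m.values.sum(axis=1))}
        worst_kept = min(sums[lab] for lab in kept)
        best_dropped = max(
            (sums[lab] for lab in m.row_labels if lab not in kept), default=-np.inf
        )
        assert worst_kept >= best_dropped

    def test_fraction_keeps_ceil(self):
        m = random_labeled_matrix(8, 10, 4, with_categories=False)
        out = filter_top(m, FilterSpec("sum", 0.25, "rows"))
        assert out.shape[0] == 3  # ceil(0.25 * 10)

    def test_categories_subset_along(self):
        m = random_labeled_matrix(9, 12, 5)
        out = filter_top(m, FilterSpec("variance", 4, "rows"))
        lab_to_entry = dict(zip(m.row_labels, m.row_categories[0].entries))
        for lab, entry in zip(out.row_labels, out.row_categories[0].entries):
            assert lab_to_entry[lab] == entry

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            filter_top(
                LabeledMatrix(np.zeros((0, 0)), [], []),
                FilterSpec("sum", 1, "rows"),
            )


class TestFilterMissing:
    def test_threshold_seven(self):
        # rows with 0..10 missing entries out of 11 columns
        vals = np.ones((11, 11))
        for i in range(11):
            vals[i, :i] = np.nan
        m = _mat(vals)
        out = filter_missing(m, 7, "rows")
        assert out.shape[0] == 8
        assert int(np.isnan(out.values).sum(axis=1).max()) == 7

    def test_large_threshold_is_identity(self):
        m = random_labeled_matrix(4, 6, 5, missing_rate=0.4, with_categories=False)
        out = filter_missing(m, 5, "rows")
        assert out.row_labels == m.row_labels

    def test_all_missing_row_removed_at_zero(self):
        vals = np.array([[1.0, 2.0], [np.nan, np.nan]])
        out = filter_missing(_mat(vals), 0, "rows")
        assert out.row_labels == ["r0"]

    @settings(max_examples=30, deadline=None)
    @given(seed=st.integers(0, 5000), max_missing=st.integers(0, 6))
    def test_never_removes_compliant_vector(self, seed, max_missing):
        m = random_labeled_matrix(seed, 10, 6, missing_rate=0.35, with_categories=False)
        out = filter_missing(m, max_missing, "rows")
        kept = set(out.row_labels)
        for i, lab in enumerate(m.row_labels):
            n_missing = int(np.isnan(m.values[i]).sum())
            assert (lab in kept) == (n_missing <= max_missing)


class TestRatioToReference:
    def test_elementwise_division(self):
        m = _mat(np.array([[2.0, 1.0], [4.0, 2.0]]))
        out = ratio_to_reference(m, "c1")
        assert out.col_labels == ["c0"]
        np.testing.assert_allclose(out.values.ravel(), [2.0, 2.0])

    def test_zero_reference_yields_missing(self):
        m = _mat(np.array([[2.0, 0.0]]))
        out = ratio_to_reference(m, "c1")
        assert np.isnan(out.values[0, 0])

    def test_per_run_mapping(self):
        # 3 runs x 2 samples, each run has its own reference column
        rng = np.random.default_rng(0)
        vals = np.abs(rng.normal(size=(4, 9))) + 1.0
        labels = [f"s{r}{k}" for r in range(3) for k in range(2)] + [
            f"ref{r}" for r in range(3)
        ]
        m = LabeledMatrix(vals, [f"p{i}" for i in range(4)], labels)
        mapping = {f"s{r}{k}": f"ref{r}" for r in range(3) for k in range(2)}
        out = ratio_to_reference(m, mapping)
        assert out.col_labels == [f"s{r}{k}" for r in range(3) for k in range(2)]
        for j, lab in enumerate(out.col_labels):
            ref = vals[:, labels.index(mapping[lab])]
            np.testing.assert_allclose(out.values[:, j], vals[:, labels.index(lab)] / ref)

    def test_unmapped_sample_rejected(self):
        m = _mat(np.ones((2, 3)))
        with pytest.raises(KeyError, match="c2"):
            ratio_to_reference(m, {"c0": "c1"})
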