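"""Normalization and filtering primitives.

These operate on :class:`~clustermat.matrix_io.LabeledMatrix` and never
mutate their input. Missing entries (NaN) are handled explicitly per
operation: Z-scores and filter metrics are computed over the non-missing
entries of each vector; quantile normalization requires complete vectors
by default (an interpolating variant supports incomplete ones, for
pipelines that quantile-normalize before missing-value filtering).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Union

import numpy as np

from .matrix_io import LabeledMatrix, _check_axis

log = logging.getLogger(__name__)

__all__ = [
    "NormalizationSpec",
    "FilterSpec",
    "zscore",
    "quantile_normalize",
    "filter_top",
    "filter_missing",
    "ratio_to_reference",
    "impute_vector_mean",
]


@dataclass
class NormalizationSpec:
    """Which normalization to apply, along which axis.

    ``ddof`` (Z-score only) is the delta degrees of freedom of the standard
    deviation; the default 1 gives the sample s.d. ``reference`` (quantile
    only) picks the per-rank summary of the sorted vectors: mean or median.
    """

    method: str = "zscore"
    axis: str = "rows"
    ddof: int = 1
    reference: str = "mean"

    def __post_init__(self) -> None:
        if self.method not in ("zscore", "quantile"):
            raise ValueError(f"unknown normalization method {self.method!r}")
        _check_axis(self.axis)
        if self.ddof < 0:
            raise ValueError("ddof must be >= 0")
        if self.reference not in ("mean", "median"):
            raise ValueError(f"quantile reference must be mean or median, got {self.reference!r}")


@dataclass
class FilterSpec:
    """Keep the top vectors along an axis by a simple metric.

    ``keep`` is either an integer N >= 1 (top-N) or a fraction in (0, 1]
    (top ceil(f * axis length)). ``metric`` is one of sum, variance,
    absolute-sum; metrics are computed over non-missing entries.
    """

    metric: str = "variance"
    keep: Union[int, float] = 1.0
    axis: str = "rows"

    def __post_init__(self) -> None:
        if self.metric not in ("sum", "variance", "absolute-sum"):
            raise ValueError(f"unknown filter metric {self.metric!r}")
        _check_axis(self.axis)
        if isinstance(self.keep, bool) or (
            isinstance(self.keep, int) and self.keep < 1
        ):
            raise ValueError("top-N keep must be an integer >= 1")
        if isinstance(self.keep, float) and not (0 < self.keep <= 1):
            raise ValueError("fractional keep must lie in (0, 1]")

    def n_keep(self, axis_len: int) -> int:
        if isinstance(self.keep, float):
            n = math.ceil(self.keep * axis_len)
        else:
            n = self.keep
        if n > axis_len:
            log.warning("top-%d clamped to axis length %d", n, axis_len)
            n = axis_len
        return max(n, 0)


def _as_row_vectors(m: LabeledMatrix, axis: str) -> np.ndarray:
    """View of values with the normalized/filtered axis along axis 0."""
    return m.values if _check_axis(axis) == "rows" else m.values.T


def zscore(m: LabeledMatrix, spec: NormalizationSpec | None = None) -> LabeledMatrix:
    """Center and scale each vector along ``spec.axis`` to mean 0, s.d. 1.

    Statistics use non-missing entries only; constant vectors (zero s.d.)
    and vectors with too few entries for the requested ``ddof`` map to all
    zeros, which keeps them clusterable. Missingness is preserved.
    """
    spec = spec or NormalizationSpec(method="zscore")
    if spec.method != "zscore":
        raise ValueError("spec.method must be 'zscore'")
    out = m.copy()
    v = _as_row_vectors(out, spec.axis)
    if v.shape[1] <= spec.ddof:
        raise ValueError(
            f"axis length {v.shape[1]} must exceed ddof={spec.ddof}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = np.nanmean(v, axis=1, keepdims=True)
        n_obs = np.sum(~np.isnan(v), axis=1, keepdims=True)
        sd = np.full_like(mu, np.nan)
        ok = (n_obs > spec.ddof).ravel()
        if ok.any():
            sd[ok, 0] = np.nanstd(v[ok, :], axis=1, ddof=spec.ddof)
        z = (v - mu) / sd
    degenerate = ~np.isfinite(sd) | (sd == 0)
    z[degenerate.ravel(), :] = 0.0
    z[np.isnan(v)] = np.nan
    v[:, :] = z
    return out


def quantile_normalize(
    m: LabeledMatrix,
    spec: NormalizationSpec | None = None,
    missing: str = "error",
) -> LabeledMatrix:
    """Force all vectors along ``spec.axis`` onto a common distribution.

    The reference distribution is the per-rank mean (or median, per
    ``spec.reference``) of the sorted vectors; each entry is replaced by
    the reference value at its rank, tied entries receiving the mean of
    their tied reference values, so within-vector rank order is preserved.

    ``missing="error"`` (default) rejects incomplete vectors. With
    ``missing="interpolate"``, each vector's non-missing entries are mapped
    through the reference's quantile function (linear interpolation), and
    the reference itself is built on a common quantile grid — the standard
    treatment when normalization must precede missing-value filtering.
    """
    spec = spec or NormalizationSpec(method="quantile", axis="columns")
    if spec.method != "quantile":
        raise ValueError("spec.method must be 'quantile'")
    if missing not in ("error", "interpolate"):
        raise ValueError("missing must be 'error' or 'interpolate'")
    out = m.copy()
    v = _as_row_vectors(out, spec.axis)  # vectors along rows of this view
    has_nan = bool(np.isnan(v).any())
    if has_nan and missing == "error":
        raise ValueError(
            "quantile normalization requires complete vectors; filter or "
            "impute missing values first, or pass missing='interpolate'"
        )
    summarize = np.mean if spec.reference == "mean" else np.median

    if not has_nan:
        order = np.argsort(v, axis=1, kind="stable")
        ref = summarize(np.sort(v, axis=1), axis=0)
        res = np.empty_like(v)
        rows = np.arange(v.shape[0])[:, None]
        res[rows, order] = ref[None, :]
        # average reference values across ties within each vector
        for i in range(v.shape[0]):
            res[i] = _average_ties(v[i], res[i])
        v[:, :] = res
        return out

    # interpolating variant on a common quantile grid
    grid = np.linspace(0.0, 1.0, v.shape[1])
    curves = []
    for i in range(v.shape[0]):
        obs = np.sort(v[i][~np.isnan(v[i])])
        if obs.size == 0:
            raise ValueError(f"vector {i} along {spec.axis} is entirely missing")
        q = np.linspace(0.0, 1.0, obs.size)
        curves.append(np.interp(grid, q, obs))
    ref = summarize(np.vstack(curves), axis=0)
    for i in range(v.shape[0]):
        mask = ~np.isnan(v[i])
        obs = v[i][mask]
        k = obs.size
        ranks = np.empty(k)
        ranks[np.argsort(obs, kind="stable")] = np.arange(k)
        q = ranks / (k - 1) if k > 1 else np.array([0.5])
        new = np.interp(q, grid, ref)
        new = _average_ties(obs, new)
        v[i, mask] = new
    return out


def _average_ties(original: np.ndarray, assigned: np.ndarray) -> np.ndarray:
    """Replace assigned values of tied originals by their group mean."""
    uniq, inv = np.unique(original, return_inverse=True)
    if uniq.size == original.size:
        return assigned
    sums = np.bincount(inv, weights=assigned)
    counts = np.bincount(inv)
    return (sums / counts)[inv]


def _metric_values(v: np.ndarray, metric: str, ddof: int = 1) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        if metric == "sum":
            x = np.nansum(v, axis=1)
        elif metric == "absolute-sum":
            x = np.nansum(np.abs(v), axis=1)
        else:  # variance
            n_obs = np.sum(~np.isnan(v), axis=1)
            x = np.full(v.shape[0], -np.inf)
            ok = n_obs > ddof
            if ok.any():
                x[ok] = np.nanvar(v[ok, :], axis=1, ddof=ddof)
    # uncomputable metrics sort last
    return np.where(np.isnan(x), -np.inf, x)


def filter_top(m: LabeledMatrix, spec: FilterSpec) -> LabeledMatrix:
    """Keep the vectors with the largest metric along ``spec.axis``.

    Exactly ``min(N, axis length)`` vectors survive; ties are broken by
    original position (earlier wins) and survivors keep their original
    relative order, so the operation is a stable selection.
    """
    if m.values.size == 0:
        raise ValueError("cannot filter an empty matrix")
    v = _as_row_vectors(m, spec.axis)
    n = spec.n_keep(v.shape[0])
    metric = _metric_values(v, spec.metric)
    # stable sort on descending metric: earlier index wins ties
    order = np.argsort(-metric, kind="stable")[:n]
    keep = np.sort(order)
    return m.subset_rows(keep) if spec.axis == "rows" else m.subset_cols(keep)


def filter_missing(m: LabeledMatrix, max_missing: int, axis: str = "rows") -> LabeledMatrix:
    """Drop vectors along ``axis`` with more than ``max_missing`` NaNs."""
    if max_missing < 0:
        raise ValueError("max_missing must be >= 0")
    v = _as_row_vectors(m, axis)
    counts = np.sum(np.isnan(v), axis=1)
    keep = np.flatnonzero(counts <= max_missing)
    return m.subset_rows(keep) if axis == "rows" else m.subset_cols(keep)


def impute_vector_mean(values: np.ndarray) -> np.ndarray:
    """Replace NaNs in each row by that row's non-missing mean (0 if none).

    Used transiently at distance-computation time; never written back to a
    :class:`LabeledMatrix`.
    """
    v = np.array(values, dtype=float)
    with np.errstate(invalid="ignore"):
        mu = np.nanmean(np.where(np.isnan(v), np.nan, v), axis=1)
    mu = np.where(np.isnan(mu), 0.0, mu)
    idx = np.isnan(v)
    v[idx] = np.broadcast_to(mu[:, None], v.shape)[idx]
    return v


def ratio_to_reference(
    m: LabeledMatrix, reference: Union[str, Mapping[str, str]]
) -> LabeledMatrix:
    """Divide each sample column by its mapped reference column.

    ``reference`` is either a single column label (shared reference) or a
    mapping ``sample label -> reference label`` (e.g. one reference per
    multiplex run). Reference columns are dropped from the output. Where a
    reference entry is zero or missing, the quotient is missing.
    """
    if isinstance(reference, str):
        ref_labels = {reference}
        mapping = {
            lab: reference for lab in m.col_labels if lab != reference
        }
    else:
        mapping = dict(reference)
        ref_labels = set(mapping.values())
    col_index = {lab: j for j, lab in enumerate(m.col_labels)}
    for lab in ref_labels:
        if lab not in col_index:
            raise KeyError(f"reference column {lab!r} not found")
    sample_idx = [
        j for j, lab in enumerate(m.col_labels) if lab not in ref_labels
    ]
    unmapped = [m.col_labels[j] for j in sample_idx if m.col_labels[j] not in mapping]
    if unmapped:
        raise KeyError(f"sample columns without a mapped reference: {unmapped}")

    out = m.subset_cols(sample_idx)
    for k, j in enumerate(sample_idx):
        ref = m.values[:, col_index[mapping[m.col_labels[j]]]]
        with np.errstate(divide="ignore", invalid="ignore"):
            q = m.values[:, j] / ref
        q[~np.isfinite(ref) | (ref == 0)] = np.nan
        q[~np.isfinite(q)] = np.nan
        out.values[:, k] = q
    return out
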