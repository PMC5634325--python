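"""Distances, agglomerative clustering, dendrogram slicing, and rank orders.

The agglomeration is implemented directly (Lance–Williams updates on a
dense distance matrix) rather than delegated, because the engine promises a
fully deterministic merge sequence: among equal-distance cluster pairs, the
pair whose smallest original member index is lowest wins (then the other
cluster's smallest index). Average linkage (UPGMA) with cosine distance is
the default, matching the conventional clustered-heatmap setup for omics
matrices.

A fitted :class:`LinkageTree` can be cut at any fraction of its maximum
merge height; :func:`slice_groups` produces the flat partitions shown as
dendrogram "slices", with group ids numbered along the display leaf order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .matrix_io import CategoryTrack, LabeledMatrix, _check_axis
from .preprocess import impute_vector_mean, _metric_values

__all__ = [
    "DistanceSpec",
    "LinkageSpec",
    "LinkageTree",
    "GroupLevels",
    "RankOrders",
    "pairwise_distance",
    "linkage",
    "leaf_ordering",
    "slice_groups",
    "rank_orders",
    "similarity_matrix",
    "DEFAULT_GROUP_FRACTIONS",
]

#: Ten equally spaced slice thresholds, as fractions of the max merge height.
DEFAULT_GROUP_FRACTIONS = tuple(round(0.1 * k, 1) for k in range(1, 11))

_METRICS = ("cosine", "euclidean", "correlation")
_LINKAGES = ("average", "single", "complete")


@dataclass
class DistanceSpec:
    """Pairwise distance configuration.

    Zero-norm vectors under cosine/correlation get distance 1 to any
    non-degenerate vector and 0 to each other (avoids 0/0).
    """

    metric: str = "cosine"

    def __post_init__(self) -> None:
        if self.metric not in _METRICS:
            raise ValueError(f"metric must be one of {_METRICS}, got {self.metric!r}")


@dataclass
class LinkageSpec:
    method: str = "average"

    def __post_init__(self) -> None:
        if self.method not in _LINKAGES:
            raise ValueError(f"method must be one of {_LINKAGES}, got {self.method!r}")


@dataclass
class LinkageTree:
    """Merge sequence of an agglomerative clustering over ``n_leaves``.

    ``merges`` holds ``(left_id, right_id, height, size)`` with scipy-style
    ids: leaves are 0..n-1 and the i-th merge creates cluster ``n + i``.
    Heights are non-decreasing. ``leaf_order`` is the deterministic display
    permutation (at each merge the subtree containing the smallest original
    index comes first).
    """

    n_leaves: int
    merges: list[tuple[int, int, float, int]]
    leaf_order: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_leaves < 1:
            raise ValueError("need at least one leaf")
        if len(self.merges) not in (0, self.n_leaves - 1):
            raise ValueError("merge list must be empty or have n_leaves - 1 entries")
        last = 0.0
        for a, b, h, size in self.merges:
            if h < last - 1e-12:
                raise ValueError("merge heights must be non-decreasing")
            last = max(last, h)
        if self.merges and self.merges[-1][3] != self.n_leaves:
            raise ValueError("final merge must contain every leaf")
        if not self.leaf_order:
            self.leaf_order = leaf_ordering(self)
        if sorted(self.leaf_order) != list(range(self.n_leaves)):
            raise ValueError("leaf_order is not a permutation of the leaves")

    @property
    def max_height(self) -> float:
        return self.merges[-1][2] if self.merges else 0.0


@dataclass
class GroupLevels:
    """Per-leaf group ids at each slice threshold.

    ``fractions`` are increasing thresholds in (0, 1] of the max merge
    height; ``assignments[i]`` maps each leaf to its group id at level i.
    Lower levels refine higher ones.
    """

    fractions: list[float]
    assignments: list[list[int]]

    def n_groups(self, level: int) -> int:
        return len(set(self.assignments[level]))


@dataclass
class RankOrders:
    """Named permutations of one axis: initial, alphabetical, sum, variance,
    cluster (= dendrogram leaf order). Sum/variance are descending with
    stable ties; alphabetical is case-insensitive."""

    orders: dict[str, list[int]]


# ---------------------------------------------------------------------------
# distances


def pairwise_distance(
    m: LabeledMatrix, axis: str = "rows", spec: DistanceSpec | None = None
) -> np.ndarray:
    """Symmetric zero-diagonal distance matrix between vectors along ``axis``.

    Missing entries are imputed, transiently, to their vector's non-missing
    mean before the computation.
    """
    spec = spec or DistanceSpec()
    v = m.values if _check_axis(axis) == "rows" else m.values.T
    if v.shape[0] < 2:
        raise ValueError("need at least two vectors to compute distances")
    v = impute_vector_mean(v)
    if spec.metric == "euclidean":
        sq = np.sum(v * v, axis=1)
        d2 = sq[:, None] + sq[None, :] - 2.0 * (v @ v.T)
        d = np.sqrt(np.maximum(d2, 0.0))
    else:
        if spec.metric == "correlation":
            v = v - v.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(v, axis=1)
        zero = norms == 0
        safe = np.where(zero, 1.0, norms)
        unit = v / safe[:, None]
        d = 1.0 - unit @ unit.T
        # zero-norm policy: distance 1 to anything nonzero, 0 to a peer
        d[zero, :] = 1.0
        d[:, zero] = 1.0
        d[np.ix_(zero, zero)] = 0.0
        np.clip(d, 0.0, 2.0, out=d)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d


def similarity_matrix(
    m: LabeledMatrix, axis: str = "rows", spec: DistanceSpec | None = None
) -> LabeledMatrix:
    """Square similarity heatmap for one axis: ``1 - distance``, diagonal 1.

    Labels and category tracks are copied from the chosen axis onto both
    axes of the result.
    """
    d = pairwise_distance(m, axis, spec)
    s = 1.0 - d
    np.fill_diagonal(s, 1.0)
    labels = list(m.axis_labels(axis))
    cats = [CategoryTrack(t.name, t.kind, list(t.entries)) for t in m.axis_categories(axis)]
    cats2 = [CategoryTrack(t.name, t.kind, list(t.entries)) for t in m.axis_categories(axis)]
    return LabeledMatrix(s, labels, list(labels), cats, cats2)


# ---------------------------------------------------------------------------
# agglomeration


def linkage(d: np.ndarray, spec: LinkageSpec | None = None) -> LinkageTree:
    """Agglomerate a distance matrix into a :class:`LinkageTree`.

    Average linkage merges the pair of clusters with the minimal mean
    inter-cluster distance (single: min; complete: max), with the
    deterministic tie-break described in the module docstring.
    """
    spec = spec or LinkageSpec()
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(d < -1e-12):
        raise ValueError("distances must be non-negative")
    n = d.shape[0]
    if n == 1:
        return LinkageTree(1, [])

    # Working matrix is compacted as clusters merge: slots [0, k) are live.
    work = d.copy().astype(float)
    np.fill_diagonal(work, np.inf)
    slot_id = np.arange(n)              # scipy-style cluster id per slot
    sizes = np.ones(n, dtype=int)
    min_member = np.arange(n)           # smallest original leaf per slot
    merges: list[tuple[int, int, float, int]] = []
    last_h = 0.0
    k = n

    for step in range(n - 1):
        w = work[:k, :k]
        row_min = w.min(axis=1)
        h = row_min.min()
        # deterministic tie-break: lowest (smaller, larger) min-member pair
        rows = np.flatnonzero(row_min == h)
        best = None
        for i in rows:
            for j in np.flatnonzero(w[i] == h):
                if i == j:
                    continue
                a, b = int(min_member[i]), int(min_member[j])
                key = (min(a, b), max(a, b))
                if best is None or key < best[0]:
                    best = (key, int(min(i, j)), int(max(i, j)))
        _, i, j = best
        ni, nj = int(sizes[i]), int(sizes[j])
        h = float(max(h, last_h))  # guard float jitter; UPGMA is monotone
        last_h = h
        if min_member[i] <= min_member[j]:
            left, right = int(slot_id[i]), int(slot_id[j])
        else:
            left, right = int(slot_id[j]), int(slot_id[i])
        merges.append((left, right, h, ni + nj))

        # Lance–Williams update into slot i
        di, dj = w[i, :], w[j, :]
        if spec.method == "average":
            new = (ni * di + nj * dj) / (ni + nj)
        elif spec.method == "single":
            new = np.minimum(di, dj)
        else:
            new = np.maximum(di, dj)
        w[i, :] = new
        w[:, i] = new
        w[i, i] = np.inf
        sizes[i] = ni + nj
        min_member[i] = min(min_member[i], min_member[j])
        slot_id[i] = n + step
        # retire slot j by moving the last live slot into it
        last = k - 1
        if j != last:
            w[j, :] = w[last, :]
            w[:, j] = w[:, last]
            w[j, j] = np.inf
            slot_id[j] = slot_id[last]
            sizes[j] = sizes[last]
            min_member[j] = min_member[last]
        k -= 1

    return LinkageTree(n, merges)


def leaf_ordering(t: LinkageTree) -> list[int]:
    """Display order: at each merge, the child subtree containing the
    smallest original index is placed first. Iterative (trees can be deep)."""
    n = t.n_leaves
    if not t.merges:
        return list(range(n))
    min_leaf = list(range(n)) + [0] * len(t.merges)
    children = {}
    for k, (a, b, _, _) in enumerate(t.merges):
        cid = n + k
        children[cid] = (a, b)
        min_leaf[cid] = min(min_leaf[a], min_leaf[b])
    order: list[int] = []
    stack = [n + len(t.merges) - 1]
    while stack:
        c = stack.pop()
        if c < n:
            order.append(c)
            continue
        a, b = children[c]
        first, second = (a, b) if min_leaf[a] <= min_leaf[b] else (b, a)
        stack.append(second)  # LIFO: push second so first pops next
        stack.append(first)
    return order


def slice_groups(t: LinkageTree, fractions=DEFAULT_GROUP_FRACTIONS) -> GroupLevels:
    """Cut the dendrogram at each fraction of the max merge height.

    At threshold f the merges with height <= f * max_height are applied;
    leaves connected below the cut share a group. Group ids are numbered by
    the position of each group's first member in the display leaf order, so
    id 0 is always the left-most group on screen.
    """
    fr = [float(f) for f in fractions]
    if any(not (0 < f <= 1) for f in fr):
        raise ValueError("slice fractions must lie in (0, 1]")
    if sorted(fr) != fr or len(set(fr)) != len(fr):
        raise ValueError("slice fractions must be strictly increasing")
    n = t.n_leaves
    hmax = t.max_height
    order_pos = {leaf: pos for pos, leaf in enumerate(t.leaf_order)}
    assignments = []
    for f in fr:
        cut = f * hmax
        parent = list(range(2 * n - 1))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for k, (a, b, h, _) in enumerate(t.merges):
            if h <= cut:
                cid = n + k
                parent[find(a)] = cid
                parent[find(b)] = cid
        roots = [find(leaf) for leaf in range(n)]
        # number groups by first appearance along the display order
        first_pos: dict[int, int] = {}
        for leaf in range(n):
            r = roots[leaf]
            p = order_pos[leaf]
            if r not in first_pos or p < first_pos[r]:
                first_pos[r] = p
        ranked = sorted(first_pos, key=first_pos.get)
        gid = {r: g for g, r in enumerate(ranked)}
        assignments.append([gid[r] for r in roots])
    return GroupLevels(fr, assignments)


# ---------------------------------------------------------------------------
# rank orders


def rank_orders(
    m: LabeledMatrix,
    t_rows: LinkageTree | None = None,
    t_cols: LinkageTree | None = None,
) -> dict[str, RankOrders]:
    """Reordering permutations per axis: initial, alphabetical, sum,
    variance, and hierarchical-cluster order."""
    out = {}
    for axis, tree in (("rows", t_rows), ("columns", t_cols)):
        v = m.values if axis == "rows" else m.values.T
        labels = m.axis_labels(axis)
        if tree is not None and tree.n_leaves != v.shape[0]:
            raise ValueError(f"{axis} tree has {tree.n_leaves} leaves for {v.shape[0]} labels")
        n = v.shape[0]
        orders = {
            "initial": list(range(n)),
            "alphabetical": sorted(range(n), key=lambda i: (labels[i].lower(), i)),
            "sum": list(np.argsort(-_metric_values(v, "sum"), kind="stable")),
            "variance": list(np.argsort(-_metric_values(v, "variance"), kind="stable")),
        }
        if tree is not None:
            orders["cluster"] = list(tree.leaf_order)
        out[axis] = RankOrders({k: [int(x) for x in v_] for k, v_ in orders.items()})
    return out
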