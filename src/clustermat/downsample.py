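"""K-means downsampling with category propagation, seeded subsampling,
and cluster-to-observation label transfer.

Downsampling replaces n observations (rows) by K centroid rows, which makes
very large single-cell matrices (e.g. mass-cytometry runs with hundreds of
thousands of cells) drawable as a clustered heatmap. Each centroid carries:

* a numeric ``number in clust`` track (cluster size; sizes sum to n);
* for every categorical row track of the input, a ``Majority-<name>`` track
  holding the cluster's modal value (lexicographically smallest mode on
  ties, which keeps runs reproducible);
* for every numeric row track, the per-cluster mean under the same name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.cluster import KMeans, MiniBatchKMeans

from .matrix_io import CategoryTrack, LabeledMatrix

log = logging.getLogger(__name__)

__all__ = [
    "DownsampleSpec",
    "DownsampleResult",
    "kmeans_downsample",
    "random_subsample",
    "transfer_labels",
    "SIZE_TRACK_NAME",
]

SIZE_TRACK_NAME = "number in clust"
MAJORITY_PREFIX = "Majority-"


@dataclass
class DownsampleSpec:
    """Cluster budget K, RNG seed, and algorithm (``lloyd`` for full-batch
    K-means, ``minibatch`` for very large n)."""

    K: int
    seed: int = 0
    algorithm: str = "lloyd"
    max_iter: int = 100

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.algorithm not in ("lloyd", "minibatch"):
            raise ValueError(f"algorithm must be lloyd or minibatch, got {self.algorithm!r}")


@dataclass
class DownsampleResult:
    """Exactly K centroid rows plus per-cluster annotation tracks."""

    centroids: LabeledMatrix
    membership: np.ndarray  # observation -> cluster id, shape (n,)
    size_track: CategoryTrack = field(init=False)

    def __post_init__(self) -> None:
        self.size_track = self.centroids.get_track("rows", SIZE_TRACK_NAME)


def kmeans_downsample(m: LabeledMatrix, spec: DownsampleSpec) -> DownsampleResult:
    """Replace the rows of ``m`` by exactly ``spec.K`` cluster-mean rows.

    Uses scikit-learn's K-means (full-batch or mini-batch per the spec);
    clusters left empty by the fit are re-seeded with the points farthest
    from their assigned centroids, so the output always has K non-empty
    clusters. Final centroids are recomputed as exact member means.
    Deterministic for a fixed seed.
    """
    X = m.values
    n = X.shape[0]
    if np.isnan(X).any():
        raise ValueError("K-means downsampling requires a complete matrix; "
                         "impute or filter missing values first")
    if spec.K > n:
        raise ValueError(f"K={spec.K} exceeds the {n} observations")
    if spec.algorithm == "minibatch":
        km = MiniBatchKMeans(
            n_clusters=spec.K,
            random_state=spec.seed,
            max_iter=spec.max_iter,
            batch_size=4096,
            n_init=3,
        )
    else:
        km = KMeans(
            n_clusters=spec.K,
            random_state=spec.seed,
            max_iter=spec.max_iter,
            n_init=1,
        )
    labels = km.fit_predict(X).astype(int)
    labels = _fill_empty_clusters(X, labels, km.cluster_centers_, spec.K)

    # exact member means (holds for both algorithms after reassignment)
    centroids = np.zeros((spec.K, X.shape[1]))
    counts = np.bincount(labels, minlength=spec.K)
    np.add.at(centroids, labels, X)
    centroids /= counts[:, None]

    row_labels = [f"C-{k}" for k in range(spec.K)]
    tracks: list[CategoryTrack] = [
        CategoryTrack(SIZE_TRACK_NAME, "numeric", [float(c) for c in counts])
    ]
    for tr in m.row_categories:
        if tr.kind == "categorical":
            tracks.append(
                CategoryTrack(
                    MAJORITY_PREFIX + tr.name,
                    "categorical",
                    _majority_per_cluster(labels, tr.entries, spec.K),
                )
            )
        else:
            per = np.zeros(spec.K)
            np.add.at(per, labels, np.asarray(tr.entries, dtype=float))
            tracks.append(CategoryTrack(tr.name, "numeric", list(per / counts)))
    cents = LabeledMatrix(
        centroids,
        row_labels,
        list(m.col_labels),
        tracks,
        [CategoryTrack(t.name, t.kind, list(t.entries)) for t in m.col_categories],
    )
    return DownsampleResult(cents, labels)


def _fill_empty_clusters(
    X: np.ndarray, labels: np.ndarray, centers: np.ndarray, K: int
) -> np.ndarray:
    """Assign the globally farthest points (from their centroids) to any
    empty clusters, one point each, so every cluster id 0..K-1 is used."""
    labels = labels.copy()
    counts = np.bincount(labels, minlength=K)
    empty = [k for k in range(K) if counts[k] == 0]
    if not empty:
        return labels
    log.warning("re-seeding %d empty K-means clusters from farthest points", len(empty))
    dist = np.linalg.norm(X - centers[labels], axis=1)
    order = np.argsort(-dist, kind="stable")
    it = iter(order)
    for k in empty:
        while True:
            i = int(next(it))
            if counts[labels[i]] > 1:
                counts[labels[i]] -= 1
                labels[i] = k
                counts[k] = 1
                break
    return labels


def _majority_per_cluster(labels: np.ndarray, entries: Sequence[str], K: int) -> list[str]:
    values = sorted(set(entries))
    vidx = {v: i for i, v in enumerate(values)}
    tally = np.zeros((K, len(values)), dtype=int)
    ent_idx = np.fromiter((vidx[e] for e in entries), dtype=int, count=len(entries))
    np.add.at(tally, (labels, ent_idx), 1)
    out = []
    ties = 0
    for k in range(K):
        row = tally[k]
        best = int(np.argmax(row))  # argmax takes first max: lexicographic mode
        if int(np.sum(row == row[best])) > 1:
            ties += 1
        out.append(values[best])
    if ties:
        log.info("%d clusters had tied modal values; smallest value kept", ties)
    return out


def random_subsample(
    m: LabeledMatrix,
    n_per_group: int,
    group_track: str | None = None,
    seed: int = 0,
) -> LabeledMatrix:
    """Draw ``min(n_per_group, group size)`` rows uniformly without
    replacement from each group of ``group_track`` (all rows form one group
    when no track is given). Sampled rows keep their original order.
    Groups are visited in sorted value order, so the draw is a pure function
    of (matrix, parameters, seed).
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    n = m.shape[0]
    if group_track is None:
        groups = {"": np.arange(n)}
    else:
        tr = m.get_track("rows", group_track)
        if tr.kind != "categorical":
            raise ValueError(f"group track {group_track!r} must be categorical")
        ent = np.asarray(tr.entries)
        groups = {v: np.flatnonzero(ent == v) for v in sorted(set(tr.entries))}
    chosen: list[int] = []
    for v in sorted(groups):
        idx = groups[v]
        take = min(n_per_group, idx.size)
        chosen.extend(rng.choice(idx, size=take, replace=False).tolist())
    chosen.sort()
    return m.subset_rows(chosen)


def transfer_labels(
    membership: Sequence[int], cluster_labels: Mapping[int, str]
) -> list[str]:
    """Propagate per-cluster labels back to the observations.

    Every cluster id present in ``membership`` must be labeled; the
    per-label observation counts equal the summed sizes of the clusters
    carrying that label.
    """
    membership = [int(c) for c in membership]
    missing = sorted({c for c in membership if c not in cluster_labels})
    if missing:
        raise KeyError(f"unlabeled cluster ids: {missing}")
    return [cluster_labels[c] for c in membership]
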