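import numpy as np
import pytest

from clustermat import CategoryTrack, LabeledMatrix


def random_labeled_matrix(
    seed: int,
    n_rows: int = 6,
    n_cols: int = 4,
    missing_rate: float = 0.0,
    with_categories: bool = True,
) -> LabeledMatrix:
    rng = np.random.default_rng(seed)
    vals = rng.normal(size=(n_rows, n_cols)).round(6)
    if missing_rate:
        vals[rng.random(vals.shape) < missing_rate] = np.nan
    row_cats, col_cats = [], []
    if with_categories:
        row_cats = [
            CategoryTrack(
                "group", "categorical",
                [f"g{rng.integers(0, 3)}" for _ in range(n_rows)],
            ),
            CategoryTrack("score", "numeric", list(rng.integers(0, 100, n_rows).astype(float))),
        ]
        col_cats = [
            CategoryTrack(
                "batch", "categorical",
                [f"b{rng.integers(0, 2)}" for _ in range(n_cols)],
            )
        ]
    return LabeledMatrix(
        vals,
        [f"row-{i}" for i in range(n_rows)],
        [f"col-{j}" for j in range(n_cols)],
        row_cats,
        col_cats,
    )


@pytest.fixture
def small_matrix():
    return LabeledMatrix(
        np.array([[1.0, 2.0], [3.0, 4.0]]),
        ["G1", "G2"],
        ["S1", "S2"],
    )


def brute_force_agglomerate(d: np.ndarray, method: str = "average"):
    """Independent agglomeration oracle: exhaustively recompute every
    inter-cluster distance from the original matrix at each step, with the
    lowest-smallest-member tie-break."""
    n = d.shape[0]
    clusters = {i: [i] for i in range(n)}
    ids = {i: i for i in range(n)}
    merges = []
    nxt = n
    while len(clusters) > 1:
        best = None
        keys = sorted(clusters)
        for x in range(len(keys)):
            for y in range(x + 1, len(keys)):
                a, b = keys[x], keys[y]
                vals = [d[p, q] for p in clusters[a] for q in clusters[b]]
                if method == "average":
                    v = sum(vals) / len(vals)
                elif method == "single":
                    v = min(vals)
                else:
                    v = max(vals)
                ma, mb = min(clusters[a]), min(clusters[b])
                key = (min(ma, mb), max(ma, mb))
                if (
                    best is None
                    or v < best[0] - 1e-12
                    or (abs(v - best[0]) <= 1e-12 and key < best[1])
                ):
                    best = (v, key, a, b)
        v, _, a, b = best
        la, lb = ids[a], ids[b]
        if min(clusters[a]) > min(clusters[b]):
            la, lb = lb, la
        merged = clusters.pop(a) + clusters.pop(b)
        merges.append((la, lb, v, len(merged)))
        clusters[a] = merged
        ids[a] = nxt
        nxt += 1
    return merges
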