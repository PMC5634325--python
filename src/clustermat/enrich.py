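"""Category composition and enrichment statistics for dendrogram clusters.

For a cluster of n leaves in which k carry some category value whose
global frequency is p0, enrichment is scored with the exact one-sided
binomial tail P(X >= k), X ~ Binomial(n, p0) — the upper tail only, since
the question is over-representation. The normal-approximation z statistic
(k/n - p0) / sqrt(p0 (1 - p0) / n) is reported alongside for reference.
Raw P-values are returned; Benjamini–Hochberg adjustment is available as
an opt-in.

A small offline gene-symbol matcher is included so callers can decide
whether row labels look like official gene symbols (the cue the original
heatmap ecosystem uses to enable gene-centric lookups) without any network
access.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Sequence

from scipy.stats import binom

from .cluster import GroupLevels
from .matrix_io import CategoryTrack

log = logging.getLogger(__name__)

__all__ = [
    "EnrichmentResult",
    "category_breakdown",
    "binom_enrichment",
    "cluster_enrichment",
    "looks_like_gene_symbols",
    "bundled_gene_symbols",
    "benjamini_hochberg",
]


@dataclass
class EnrichmentResult:
    """One (cluster, category value) enrichment record."""

    category_name: str
    category_value: str
    n: int          # cluster size
    k: int          # members of the cluster carrying the value
    p0: float       # background proportion across all leaves
    p_value: float  # exact upper-tail binomial probability
    z: float        # normal-approximation z statistic, for reference

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.n):
            raise ValueError(f"need 0 <= k <= n, got k={self.k}, n={self.n}")
        if not (0 <= self.p0 <= 1):
            raise ValueError(f"p0 must lie in [0, 1], got {self.p0}")


def category_breakdown(leaves: Sequence[int], track: CategoryTrack) -> dict[str, int]:
    """Counts of each category value among ``leaves``; counts sum to |leaves|."""
    if len(leaves) == 0:
        raise ValueError("empty leaf set")
    out: dict[str, int] = {}
    for leaf in leaves:
        if not (0 <= leaf < len(track.entries)):
            raise IndexError(f"leaf {leaf} outside track {track.name!r}")
        v = str(track.entries[leaf])
        out[v] = out.get(v, 0) + 1
    return out


def binom_enrichment(k: int, n: int, p0: float) -> float:
    """Exact upper-tail binomial probability P(X >= k), X ~ Binomial(n, p0).

    k = 0 returns 1 (the whole sample space); degenerate backgrounds
    p0 in {0, 1} short-circuit to 1, since no over-representation is
    definable against them.
    """
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if p0 <= 0.0 or p0 >= 1.0 or k == 0:
        return 1.0
    # survival function at k-1: stable tail sum via the regularized beta
    return float(min(1.0, binom.sf(k - 1, n, p0)))


def _z_stat(k: int, n: int, p0: float) -> float:
    if p0 <= 0.0 or p0 >= 1.0 or n == 0:
        return 0.0
    return (k / n - p0) / math.sqrt(p0 * (1.0 - p0) / n)


def cluster_enrichment(
    groups: GroupLevels,
    level: int,
    tracks: Sequence[CategoryTrack],
    adjust: bool = False,
) -> dict[int, list[EnrichmentResult]]:
    """Enrichment of every categorical value in every group at one level.

    The background proportion of a value is its frequency over all leaves
    (the cluster included). Numeric tracks are skipped with a notice.
    Each group's results are sorted by ascending P-value (ties by name and
    value); with ``adjust=True`` P-values are Benjamini–Hochberg adjusted
    within each group.
    """
    if not (0 <= level < len(groups.fractions)):
        raise IndexError(f"level {level} outside 0..{len(groups.fractions) - 1}")
    assignment = groups.assignments[level]
    n_total = len(assignment)
    members: dict[int, list[int]] = {}
    for leaf, g in enumerate(assignment):
        members.setdefault(g, []).append(leaf)

    out: dict[int, list[EnrichmentResult]] = {}
    for g, leaves in sorted(members.items()):
        results = []
        for tr in tracks:
            if tr.kind != "categorical":
                log.info("skipping numeric track %r in enrichment", tr.name)
                continue
            if len(tr.entries) != n_total:
                raise ValueError(
                    f"track {tr.name!r} has {len(tr.entries)} entries for {n_total} leaves"
                )
            global_counts = category_breakdown(range(n_total), tr)
            local_counts = category_breakdown(leaves, tr)
            for value, k in sorted(local_counts.items()):
                p0 = global_counts[value] / n_total
                results.append(
                    EnrichmentResult(
                        tr.name, value, len(leaves), k, p0,
                        binom_enrichment(k, len(leaves), p0),
                        _z_stat(k, len(leaves), p0),
                    )
                )
        if adjust and results:
            adj = benjamini_hochberg([r.p_value for r in results])
            for r, q in zip(results, adj):
                r.p_value = q
        results.sort(key=lambda r: (r.p_value, r.category_name, r.category_value))
        out[g] = results
    return out


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """BH step-up adjusted P-values (monotone, capped at 1)."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p_values[i] * m / rank_from_top)
        adj[i] = running
    return adj


def bundled_gene_symbols() -> list[str]:
    """The small reference list of official human gene symbols shipped with
    the package (one symbol per line)."""
    text = resources.files("clustermat").joinpath("data/gene_symbols.txt").read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def looks_like_gene_symbols(
    labels: Sequence[str], reference: Iterable[str] | None = None
) -> float:
    """Fraction of labels matching the reference symbol list,
    case-insensitively. Callers typically enable gene-centric features when
    this exceeds a threshold of their choosing."""
    labels = list(labels)
    if not labels:
        raise ValueError("empty label list")
    ref = {s.strip().upper() for s in (reference if reference is not None else bundled_gene_symbols())}
    hits = sum(1 for lab in labels if lab.strip().upper() in ref)
    return hits / len(labels)
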