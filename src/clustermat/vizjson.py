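"""Assembly, serialization, and validation of the visualization document.

The document is the complete, front-end-ready description of a clustered
heatmap: per-node metadata (initial position, cluster order, rank orders,
multi-level dendrogram group ids, category values), the dense value grid,
pre-computed row-filtered *views* (filter, then re-cluster), optional
row/column similarity matrices, the slice thresholds, and provenance.

Everything is computed once, up front, so a renderer can slice, filter and
reorder without re-running any numerics. Serialization is canonical
(sorted keys, fixed separators, ``null`` for missing values), hence a given
input, configuration and seed always produce byte-identical JSON.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from . import __version__
from .cluster import (
    DEFAULT_GROUP_FRACTIONS,
    DistanceSpec,
    GroupLevels,
    LinkageSpec,
    LinkageTree,
    linkage,
    pairwise_distance,
    rank_orders,
    similarity_matrix,
    slice_groups,
)
from .matrix_io import LabeledMatrix
from .preprocess import FilterSpec, filter_top

import logging

log = logging.getLogger(__name__)

__all__ = [
    "SCHEMA_VERSION",
    "ViewSpec",
    "ClusterConfig",
    "VisualizationDocument",
    "build_views",
    "assemble_document",
    "build_document",
    "write_json",
    "read_json",
    "validate",
    "DocumentError",
]

SCHEMA_VERSION = "cm-1"


class DocumentError(ValueError):
    """Raised when document components cannot be assembled consistently."""


@dataclass
class ViewSpec:
    """One row-filtered view: keep the top ``keep_fraction`` of rows by
    ``filter_metric`` (none = unfiltered), then re-cluster."""

    filter_metric: str = "none"
    keep_fraction: float = 1.0
    axis: str = "rows"

    def __post_init__(self) -> None:
        if self.filter_metric not in ("none", "sum", "variance"):
            raise ValueError(f"filter metric must be none/sum/variance, got {self.filter_metric!r}")
        if not (0 < self.keep_fraction <= 1):
            raise ValueError("keep_fraction must lie in (0, 1]")
        if self.axis != "rows":
            raise ValueError("views filter rows only")

    def to_dict(self) -> dict:
        return {
            "filter_metric": self.filter_metric,
            "keep_fraction": self.keep_fraction,
            "axis": self.axis,
        }


def default_view_specs() -> list[ViewSpec]:
    """The default ladder: the unfiltered view, then row-sum and
    row-variance filters at fractions 0.9, 0.8, ..., 0.1."""
    specs = [ViewSpec()]
    for metric in ("sum", "variance"):
        for k in range(9, 0, -1):
            specs.append(ViewSpec(metric, round(0.1 * k, 1)))
    return specs


@dataclass
class ClusterConfig:
    """Engine configuration shared by the document builder and workflows."""

    metric: str = "cosine"
    linkage_method: str = "average"
    group_fractions: Sequence[float] = DEFAULT_GROUP_FRACTIONS
    views: Sequence[ViewSpec] | None = None  # None -> default ladder
    include_similarity: bool = True
    normalization: str = "none"  # provenance only; applied by the caller
    seed: int = 0

    def distance_spec(self) -> DistanceSpec:
        return DistanceSpec(self.metric)

    def linkage_spec(self) -> LinkageSpec:
        return LinkageSpec(self.linkage_method)

    def view_specs(self) -> list[ViewSpec]:
        if self.views is None:
            return default_view_specs()
        specs = list(self.views)
        if not specs or specs[0].filter_metric != "none" or specs[0].keep_fraction != 1.0:
            specs = [ViewSpec()] + [s for s in specs if s.filter_metric != "none"]
        return specs


@dataclass
class VisualizationDocument:
    """In-memory form of the serialized document; see module docstring."""

    row_nodes: list[dict]
    col_nodes: list[dict]
    mat: list[list[float | None]]
    views: list[dict]
    group_levels: list[float]
    provenance: dict
    row_similarity: dict | None = None
    col_similarity: dict | None = None
    schema_version: str = SCHEMA_VERSION

    def to_dict(self) -> dict:
        d: dict[str, Any] = {
            "schema_version": self.schema_version,
            "group_levels": list(self.group_levels),
            "provenance": self.provenance,
            "row_nodes": self.row_nodes,
            "col_nodes": self.col_nodes,
            "mat": self.mat,
            "views": self.views,
        }
        if self.row_similarity is not None:
            d["row_similarity"] = self.row_similarity
        if self.col_similarity is not None:
            d["col_similarity"] = self.col_similarity
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VisualizationDocument":
        return cls(
            row_nodes=d["row_nodes"],
            col_nodes=d["col_nodes"],
            mat=d["mat"],
            views=d["views"],
            group_levels=d["group_levels"],
            provenance=d["provenance"],
            row_similarity=d.get("row_similarity"),
            col_similarity=d.get("col_similarity"),
            schema_version=d["schema_version"],
        )


# ---------------------------------------------------------------------------
# node construction


def _axis_nodes(
    m: LabeledMatrix, axis: str, tree: LinkageTree, groups: GroupLevels, ranks
) -> list[dict]:
    labels = m.axis_labels(axis)
    tracks = m.axis_categories(axis)
    orders = ranks[axis].orders
    pos = {
        name: {leaf: p for p, leaf in enumerate(perm)} for name, perm in orders.items()
    }
    nodes = []
    for i, lab in enumerate(labels):
        cats = {}
        for tr in tracks:
            v = tr.entries[i]
            cats[tr.name] = float(v) if tr.kind == "numeric" else str(v)
        nodes.append(
            {
                "name": lab,
                "ini": i,
                "clust": pos["cluster"][i],
                "rank_sum": pos["sum"][i],
                "rank_var": pos["variance"][i],
                "group": [groups.assignments[lv][i] for lv in range(len(groups.fractions))],
                "cat": cats,
            }
        )
    return nodes


def _mat_payload(values: np.ndarray) -> list[list[float | None]]:
    out = []
    for row in values:
        out.append([None if math.isnan(x) else float(x) for x in row])
    return out


def _cluster_axes(m: LabeledMatrix, config: ClusterConfig):
    dspec, lspec = config.distance_spec(), config.linkage_spec()
    t_rows = linkage(pairwise_distance(m, "rows", dspec), lspec)
    t_cols = linkage(pairwise_distance(m, "columns", dspec), lspec)
    g_rows = slice_groups(t_rows, config.group_fractions)
    g_cols = slice_groups(t_cols, config.group_fractions)
    ranks = rank_orders(m, t_rows, t_cols)
    return t_rows, t_cols, g_rows, g_cols, ranks


def build_views(
    m: LabeledMatrix, specs: Sequence[ViewSpec], config: ClusterConfig
) -> list[dict]:
    """Compute each view: filter rows, re-cluster both axes, emit nodes+mat.

    The unfiltered view reproduces the base clustering. Views whose
    fraction leaves fewer than two rows are skipped with a warning.
    Normalization is never re-applied inside a view.
    """
    out = []
    for spec in specs:
        if spec.filter_metric == "none":
            sub = m
        else:
            sub = filter_top(m, FilterSpec(spec.filter_metric, float(spec.keep_fraction), "rows"))
        if sub.shape[0] < 2:
            log.warning(
                "skipping view %s@%.2f: only %d rows remain",
                spec.filter_metric, spec.keep_fraction, sub.shape[0],
            )
            continue
        t_r, t_c, g_r, g_c, ranks = _cluster_axes(sub, config)
        out.append(
            {
                "spec": spec.to_dict(),
                "row_nodes": _axis_nodes(sub, "rows", t_r, g_r, ranks),
                "col_nodes": _axis_nodes(sub, "columns", t_c, g_c, ranks),
                "mat": _mat_payload(sub.values),
            }
        )
    return out


def _similarity_block(m: LabeledMatrix, axis: str, config: ClusterConfig) -> dict:
    sim = similarity_matrix(m, axis, config.distance_spec())
    t_r, t_c, g_r, g_c, ranks = _cluster_axes(sim, config)
    return {
        "axis": axis,
        "row_nodes": _axis_nodes(sim, "rows", t_r, g_r, ranks),
        "col_nodes": _axis_nodes(sim, "columns", t_c, g_c, ranks),
        "mat": _mat_payload(sim.values),
    }


def assemble_document(
    m: LabeledMatrix,
    trees: tuple[LinkageTree, LinkageTree],
    groups: tuple[GroupLevels, GroupLevels],
    ranks,
    views: list[dict],
    similarities: tuple[dict | None, dict | None],
    provenance: dict,
) -> VisualizationDocument:
    """Assemble pre-computed components into a validated document."""
    t_rows, t_cols = trees
    g_rows, g_cols = groups
    n, mcols = m.shape
    for name, tree, want in (("rows", t_rows, n), ("columns", t_cols, mcols)):
        if tree.n_leaves != want:
            raise DocumentError(f"{name} tree has {tree.n_leaves} leaves for {want} labels")
    doc = VisualizationDocument(
        row_nodes=_axis_nodes(m, "rows", t_rows, g_rows, ranks),
        col_nodes=_axis_nodes(m, "columns", t_cols, g_cols, ranks),
        mat=_mat_payload(m.values),
        views=views,
        group_levels=[float(f) for f in g_rows.fractions],
        provenance=provenance,
        row_similarity=similarities[0],
        col_similarity=similarities[1],
    )
    problems = validate(doc)
    if problems:
        raise DocumentError("assembled document is invalid: " + "; ".join(problems))
    return doc


def build_document(m: LabeledMatrix, config: ClusterConfig | None = None) -> VisualizationDocument:
    """One-shot pipeline: cluster both axes, slice groups, compute rank
    orders, the view ladder and (optionally) both similarity blocks, then
    assemble the document."""
    config = config or ClusterConfig()
    t_r, t_c, g_r, g_c, ranks = _cluster_axes(m, config)
    views = build_views(m, config.view_specs(), config)
    sims = (None, None)
    if config.include_similarity:
        sims = (
            _similarity_block(m, "rows", config),
            _similarity_block(m, "columns", config),
        )
    provenance = {
        "distance_metric": config.metric,
        "linkage": config.linkage_method,
        "normalization": config.normalization,
        "seed": config.seed,
        "tool_version": __version__,
    }
    return assemble_document(
        m, (t_r, t_c), (g_r, g_c), ranks, views, sims, provenance
    )


# ---------------------------------------------------------------------------
# serialization


def write_json(doc: VisualizationDocument) -> bytes:
    """Canonical serialization: sorted keys, fixed separators, UTF-8."""
    return json.dumps(
        doc.to_dict(), sort_keys=True, separators=(",", ":"), allow_nan=False
    ).encode("utf-8")


def read_json(data: bytes | str) -> VisualizationDocument:
    d = json.loads(data)
    return VisualizationDocument.from_dict(d)


# ---------------------------------------------------------------------------
# validation


def validate(doc) -> list[str]:
    """Structural validation; returns a list of violations, each prefixed
    with the JSON path of the offending element. Empty list = valid.

    Accepts a document, a dict, or serialized bytes/str.
    """
    if isinstance(doc, (bytes, str)):
        try:
            doc = json.loads(doc)
        except json.JSONDecodeError as exc:
            return [f"$: not valid JSON ({exc})"]
    if isinstance(doc, VisualizationDocument):
        doc = doc.to_dict()
    problems: list[str] = []
    for key in ("schema_version", "group_levels", "provenance", "row_nodes", "col_nodes", "mat", "views"):
        if key not in doc:
            problems.append(f"$.{key}: missing")
    if problems:
        return problems
    if doc["schema_version"] != SCHEMA_VERSION:
        problems.append(
            f"$.schema_version: expected {SCHEMA_VERSION!r}, got {doc['schema_version']!r}"
        )
    levels = doc["group_levels"]
    if sorted(levels) != list(levels) or len(set(levels)) != len(levels):
        problems.append("$.group_levels: fractions must be strictly increasing")

    def check_block(path: str, block: dict) -> None:
        rn, cn, mat = block.get("row_nodes"), block.get("col_nodes"), block.get("mat")
        if rn is None or cn is None or mat is None:
            problems.append(f"{path}: missing row_nodes/col_nodes/mat")
            return
        if len(mat) != len(rn):
            problems.append(f"{path}.mat: {len(mat)} rows for {len(rn)} row_nodes")
        for i, row in enumerate(mat):
            if len(row) != len(cn):
                problems.append(f"{path}.mat[{i}]: {len(row)} values for {len(cn)} col_nodes")
                break
        for side, nodes in (("row_nodes", rn), ("col_nodes", cn)):
            for i, node in enumerate(nodes):
                for fld in ("name", "ini", "clust", "group", "cat"):
                    if fld not in node:
                        problems.append(f"{path}.{side}[{i}].{fld}: missing")

    check_block("$", doc)
    # refinement monotonicity of the base node groups
    for side in ("row_nodes", "col_nodes"):
        nodes = doc[side]
        L = len(levels)
        for node in nodes:
            if len(node.get("group", [])) != L:
                problems.append(f"$.{side}: node {node.get('name')!r} lacks {L} group ids")
                break
        else:
            for lv in range(L - 1):
                fine = [n["group"][lv] for n in nodes]
                coarse = [n["group"][lv + 1] for n in nodes]
                mapping: dict[int, int] = {}
                for f, c in zip(fine, coarse):
                    if f in mapping and mapping[f] != c:
                        problems.append(
                            f"$.{side}: groups at level {lv} do not refine level {lv + 1}"
                        )
                        break
                    mapping[f] = c
                else:
                    continue
                break
    for v, view in enumerate(doc["views"]):
        check_block(f"$.views[{v}]", view)
        if "spec" not in view:
            problems.append(f"$.views[{v}].spec: missing")
    if doc["views"]:
        spec0 = doc["views"][0].get("spec", {})
        if spec0.get("filter_metric") != "none" or spec0.get("keep_fraction") != 1.0:
            problems.append("$.views[0]: first view must be the unfiltered view")
    for key in ("row_similarity", "col_similarity"):
        if doc.get(key) is not None:
            check_block(f"$.{key}", doc[key])
    return problems
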