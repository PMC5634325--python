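"""The three case-study pipelines, composed from the library primitives.

Each workflow is a configured sequence of preprocessing, clustering and
document-assembly steps and returns its visualization document(s) plus a
:class:`WorkflowReport` recording every stage's input/output dimensions,
parameters and seeds — the chain of dimensions is asserted as it is built.

* :func:`run_ptm_workflow` — tumor-vs-reference PTM panel: ratio to the
  per-run reference, per-column quantile normalization, missing-value
  filter (rows with more than ``max_missing`` gaps dropped), row Z-score;
  in parallel the expression block keeps its top ``n_expr_keep`` genes by
  variance and is row Z-scored; the two blocks are stacked over the
  intersection of their cell-line columns and clustered.
* :func:`run_cytof_workflow` — single-cell panel: column Z-score, then
  (a) K-means downsampling in surface-marker space with majority-treatment
  and cluster-size tracks, clustered into the surface document, and
  (b) per-treatment random subsampling in phospho-marker space for the
  phospho document (a K-means variant of (b) is available via config).
* :func:`run_ccle_workflow` — per-tissue expression: subset columns to one
  tissue, keep the top ``n_keep`` most variable genes, row Z-score,
  cluster; histology/sub-histology/gender tracks survive into the nodes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .downsample import (
    DownsampleSpec,
    kmeans_downsample,
    random_subsample,
)
from .matrix_io import CategoryTrack, LabeledMatrix
from .preprocess import (
    FilterSpec,
    NormalizationSpec,
    filter_missing,
    filter_top,
    quantile_normalize,
    ratio_to_reference,
    zscore,
)
from .vizjson import ClusterConfig, VisualizationDocument, build_document

log = logging.getLogger(__name__)

__all__ = [
    "WorkflowReport",
    "run_ptm_workflow",
    "run_cytof_workflow",
    "run_ccle_workflow",
]


@dataclass
class WorkflowReport:
    """Ordered stage log; consecutive dimensions must chain."""

    name: str
    stages: list[dict] = field(default_factory=list)

    def add(self, stage: str, shape_in, shape_out, **params) -> None:
        prev = self._last_shape(stage)
        if prev is not None and tuple(prev) != tuple(shape_in):
            raise ValueError(
                f"{self.name}: stage {stage!r} input {shape_in} does not chain "
                f"from previous output {prev}"
            )
        self.stages.append(
            {
                "stage": stage,
                "shape_in": tuple(shape_in),
                "shape_out": tuple(shape_out),
                "params": params,
            }
        )

    def _last_shape(self, stage: str):
        # stages may belong to parallel branches, marked by a '/' prefix;
        # chaining is only enforced within a branch
        branch = stage.split("/")[0] if "/" in stage else None
        for rec in reversed(self.stages):
            other = rec["stage"]
            ob = other.split("/")[0] if "/" in other else None
            if ob == branch:
                return rec["shape_out"]
        return None

    def to_text(self) -> str:
        lines = [f"workflow: {self.name}"]
        for rec in self.stages:
            p = ", ".join(f"{k}={v}" for k, v in rec["params"].items())
            lines.append(
                f"  {rec['stage']}: {rec['shape_in']} -> {rec['shape_out']}"
                + (f"  [{p}]" if p else "")
            )
        return "\n".join(lines)


def _stack_blocks(a: LabeledMatrix, b: LabeledMatrix, track_name: str,
                  a_value: str, b_value: str) -> LabeledMatrix:
    """Vertically stack two blocks over the intersection of their columns
    (in the first block's order), tagging rows with a data-type track."""
    common = [lab for lab in a.col_labels if lab in set(b.col_labels)]
    if not common:
        raise ValueError("no shared columns between the two blocks")
    ai = [a.col_labels.index(lab) for lab in common]
    bi = [b.col_labels.index(lab) for lab in common]
    a2, b2 = a.subset_cols(ai), b.subset_cols(bi)
    row_labels = list(a2.row_labels) + [
        lab if lab not in set(a2.row_labels) else f"{lab}-expr"
        for lab in b2.row_labels
    ]
    tracks = [
        CategoryTrack(
            track_name,
            "categorical",
            [a_value] * a2.shape[0] + [b_value] * b2.shape[0],
        )
    ]
    return LabeledMatrix(
        np.vstack([a2.values, b2.values]),
        row_labels,
        common,
        tracks,
        [CategoryTrack(t.name, t.kind, list(t.entries)) for t in a2.col_categories],
    )


def run_ptm_workflow(
    ptm: LabeledMatrix,
    expr: LabeledMatrix,
    reference: Mapping[str, str] | str,
    config: ClusterConfig | None = None,
    max_missing: int = 7,
    n_expr_keep: int = 1000,
) -> tuple[VisualizationDocument, WorkflowReport]:
    """Combined PTM + expression document (see module docstring).

    ``reference`` maps each PTM sample column to its multiplex run's
    reference column (or names a single shared reference). Quantile
    normalization runs per column before the missing-value filter, so the
    interpolating variant is used on the still-incomplete matrix.
    """
    config = config or ClusterConfig(normalization="zscore-rows")
    report = WorkflowReport("ptm")

    shape0 = ptm.shape
    ratios = ratio_to_reference(ptm, reference)
    report.add("ptm/ratio_to_reference", shape0, ratios.shape)

    qn = quantile_normalize(
        ratios, NormalizationSpec(method="quantile", axis="columns"),
        missing="interpolate" if np.isnan(ratios.values).any() else "error",
    )
    report.add("ptm/quantile_normalize", ratios.shape, qn.shape, axis="columns")

    kept = filter_missing(qn, max_missing, "rows")
    report.add("ptm/filter_missing", qn.shape, kept.shape, max_missing=max_missing)

    ptm_z = zscore(kept, NormalizationSpec(method="zscore", axis="rows"))
    report.add("ptm/zscore", kept.shape, ptm_z.shape, axis="rows")

    expr_top = filter_top(expr, FilterSpec("variance", int(n_expr_keep), "rows"))
    report.add("expr/filter_top", expr.shape, expr_top.shape,
               metric="variance", keep=n_expr_keep)
    expr_z = zscore(expr_top, NormalizationSpec(method="zscore", axis="rows"))
    report.add("expr/zscore", expr_top.shape, expr_z.shape, axis="rows")

    combined = _stack_blocks(ptm_z, expr_z, "data-type", "PTM", "expression")
    report.add("combine", (ptm_z.shape[0] + expr_z.shape[0], combined.shape[1]),
               combined.shape, rule="column-intersection")

    doc = build_document(combined, config)
    report.add("cluster", combined.shape, combined.shape,
               metric=config.metric, linkage=config.linkage_method)
    return doc, report


def run_cytof_workflow(
    cells: LabeledMatrix,
    config: ClusterConfig | None = None,
    K: int = 2000,
    n_per_group: int = 2000,
    treatment_track: str = "Treatment",
    marker_class_track: str = "Marker-Type",
    phospho_mode: str = "subsample",
    seed: int = 0,
) -> tuple[VisualizationDocument, VisualizationDocument, WorkflowReport]:
    """Surface-space (downsampled) and phospho-space documents.

    ``phospho_mode`` picks random subsampling (default) or K-means
    downsampling for the phospho-space document. The K-means algorithm
    switches to mini-batch above 50,000 cells.
    """
    config = config or ClusterConfig(normalization="zscore-columns", seed=seed)
    report = WorkflowReport("cytof")
    classes = cells.get_track("columns", marker_class_track)
    cells.get_track("rows", treatment_track)  # existence check
    surface_idx = [j for j, v in enumerate(classes.entries) if v == "surface"]
    phospho_idx = [j for j, v in enumerate(classes.entries) if v == "phospho"]
    if not surface_idx or not phospho_idx:
        raise ValueError(
            f"marker-class track {marker_class_track!r} must tag both "
            "'surface' and 'phospho' columns"
        )

    z = zscore(cells, NormalizationSpec(method="zscore", axis="columns"))
    report.add("zscore", cells.shape, z.shape, axis="columns")

    algorithm = "minibatch" if z.shape[0] > 50_000 else "lloyd"
    surface = z.subset_cols(surface_idx)
    ds = kmeans_downsample(surface, DownsampleSpec(K=K, seed=seed, algorithm=algorithm))
    report.add("surface/kmeans_downsample", surface.shape, ds.centroids.shape,
               K=K, algorithm=algorithm, seed=seed)
    surface_doc = build_document(ds.centroids, config)
    report.add("surface/cluster", ds.centroids.shape, ds.centroids.shape,
               metric=config.metric, linkage=config.linkage_method)

    phospho = z.subset_cols(phospho_idx)
    if phospho_mode == "subsample":
        sub = random_subsample(phospho, n_per_group, treatment_track, seed=seed)
        report.add("phospho/random_subsample", phospho.shape, sub.shape,
                   n_per_group=n_per_group, group_track=treatment_track, seed=seed)
        phospho_mat = sub
    elif phospho_mode == "kmeans":
        ds2 = kmeans_downsample(
            phospho, DownsampleSpec(K=K, seed=seed, algorithm=algorithm)
        )
        report.add("phospho/kmeans_downsample", phospho.shape,
                   ds2.centroids.shape, K=K, algorithm=algorithm, seed=seed)
        phospho_mat = ds2.centroids
    else:
        raise ValueError("phospho_mode must be 'subsample' or 'kmeans'")
    phospho_doc = build_document(phospho_mat, config)
    report.add(
        f"phospho/cluster", phospho_mat.shape, phospho_mat.shape,
        metric=config.metric, linkage=config.linkage_method,
    )
    return surface_doc, phospho_doc, report


def run_ccle_workflow(
    expr: LabeledMatrix,
    tissue: str,
    config: ClusterConfig | None = None,
    tissue_track: str = "tissue",
    n_keep: int = 250,
) -> tuple[VisualizationDocument, WorkflowReport]:
    """Per-tissue expression document: tissue subset, top-``n_keep``
    variance filter (clamped with a warning when fewer genes qualify),
    row Z-score, clustering with the engine defaults."""
    config = config or ClusterConfig(normalization="zscore-rows")
    report = WorkflowReport("ccle")
    tr = expr.get_track("columns", tissue_track)
    idx = [j for j, v in enumerate(tr.entries) if v == tissue]
    if not idx:
        raise KeyError(
            f"tissue {tissue!r} not present; available: {sorted(set(tr.entries))}"
        )
    sub = expr.subset_cols(idx)
    report.add("subset_tissue", expr.shape, sub.shape, tissue=tissue)

    top = filter_top(sub, FilterSpec("variance", int(n_keep), "rows"))
    report.add("filter_top", sub.shape, top.shape, metric="variance", keep=n_keep)

    z = zscore(top, NormalizationSpec(method="zscore", axis="rows"))
    report.add("zscore", top.shape, z.shape, axis="rows")

    doc = build_document(z, config)
    report.add("cluster", z.shape, z.shape,
               metric=config.metric, linkage=config.linkage_method)
    return doc, report
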