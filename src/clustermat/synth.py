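"""Seeded synthetic fixtures with the statistical structure the workflows
assume.

Three families are generated, all bit-reproducible from one explicit seed
(every generator owns a ``numpy.random.Generator``; no global RNG state):

* generic block matrices — rows and columns partitioned into blocks, each
  block given a Gaussian mean scaled by ``effect`` (in units of the noise
  s.d.), so planted partitions are recoverable by clustering when the
  effect is large and at chance when it is zero;
* CyTOF-like single-cell matrices — a Gaussian mixture of cell types in
  surface-marker space (18 surface + 10 phospho markers by default), a
  two-arm treatment track (untreated plasma vs PMA), and one designated
  responder cell type whose PMA-treated cells shift on four phospho
  markers (pCREB, pMAPKAP2, pp38, pERK1/2 — named after the markers such an
  experiment reports, as a planted effect only);
* PTM/expression pairs — positive tandem-mass-tag-style PTM levels for a
  panel of cell lines measured in multiplex runs, each run carrying a
  non-cancerous reference column, with planted missingness; plus an
  expression block whose first ``n_variable`` genes carry boosted variance
  so a top-N variance filter has a known right answer.

A CCLE-like expression panel (tissues × histology tracks) rounds out the
set for the per-tissue workflow.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .matrix_io import CategoryTrack, LabeledMatrix

log = logging.getLogger(__name__)

__all__ = [
    "FixtureSpec",
    "make_block_matrix",
    "make_cytof_like",
    "make_ptm_like",
    "make_ccle_like",
    "PHOSPHO_RESPONDER_MARKERS",
]

#: Phospho markers carrying the planted treatment response.
PHOSPHO_RESPONDER_MARKERS = ("pCREB", "pMAPKAP2", "pp38", "pERK1/2")

SURFACE_MARKERS_18 = (
    "CD45", "CD3", "CD4", "CD8", "CD19", "CD14", "CD16", "CD56", "CD11c",
    "CD123", "CD38", "HLADR", "CD25", "CD27", "CD45RA", "CD66b", "CD61",
    "CD127",
)
PHOSPHO_MARKERS_10 = (
    "pCREB", "pMAPKAP2", "pp38", "pERK1/2", "pSTAT1", "pSTAT3", "pSTAT5",
    "pS6", "pNFkB", "pPLCg2",
)


@dataclass
class FixtureSpec:
    """Parameters of a generic planted-block matrix."""

    n_rows: int = 40
    n_cols: int = 20
    n_blocks: int = 2
    effect: float = 10.0
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_rows, self.n_cols, self.n_blocks) < 1:
            raise ValueError("counts must be >= 1")
        if self.n_blocks > min(self.n_rows, self.n_cols):
            raise ValueError("n_blocks must not exceed either dimension")
        if not (0 <= self.missing_rate <= 1):
            raise ValueError("missing_rate must lie in [0, 1]")


def make_block_matrix(spec: FixtureSpec) -> LabeledMatrix:
    """Planted row/column block structure plus Gaussian noise.

    Entry (i, j) = effect * noise_sd * B[rb(i), cb(j)] + Normal(0, noise_sd),
    where B is the identity plus mild Gaussian jitter: rows of one block
    peak on their matching column block, so block profiles are mutually
    near-orthogonal and recoverable whenever ``effect`` dominates the
    noise (and pure noise when ``effect`` is zero). Block ids are attached
    as categorical tracks ``row-block`` / ``col-block``.
    """
    rng = np.random.default_rng(spec.seed)
    rb = np.sort(np.arange(spec.n_rows) % spec.n_blocks)
    cb = np.sort(np.arange(spec.n_cols) % spec.n_blocks)
    B = np.eye(spec.n_blocks) + 0.1 * rng.normal(size=(spec.n_blocks, spec.n_blocks))
    vals = spec.effect * spec.noise_sd * B[np.ix_(rb, cb)] + rng.normal(
        scale=spec.noise_sd, size=(spec.n_rows, spec.n_cols)
    )
    if spec.missing_rate > 0:
        vals[rng.random(vals.shape) < spec.missing_rate] = np.nan
    return LabeledMatrix(
        vals,
        [f"R{i}" for i in range(spec.n_rows)],
        [f"S{j}" for j in range(spec.n_cols)],
        [CategoryTrack("row-block", "categorical", [f"block-{b}" for b in rb])],
        [CategoryTrack("col-block", "categorical", [f"block-{b}" for b in cb])],
    )


def make_cytof_like(
    n_cells: int = 220_000,
    n_surface: int = 18,
    n_phospho: int = 10,
    n_types: int = 8,
    treatment_fraction: float = 0.5,
    separation: float = 8.0,
    response_shift: float = 5.0,
    seed: int = 0,
) -> LabeledMatrix:
    """Gaussian-mixture single cells over surface + phospho markers.

    Cell-type means live in surface space at pairwise separation set by
    ``separation`` (in noise-s.d. units); phospho levels are baseline
    standard normal except for the responder type (type 0), whose treated
    cells shift by ``response_shift`` on the four responder markers.
    The treated arm holds exactly ``round(treatment_fraction * n_cells)``
    cells. Row tracks: ``Treatment`` (Plasma/PMA) and ``Cell-Type``;
    column track: ``Marker-Type`` (surface/phospho).
    """
    if n_types < 1:
        raise ValueError("n_types must be >= 1")
    rng = np.random.default_rng(seed)
    n_pma = int(round(treatment_fraction * n_cells))
    treatment = np.array(["Plasma"] * (n_cells - n_pma) + ["PMA"] * n_pma)
    rng.shuffle(treatment)
    cell_type = rng.integers(0, n_types, size=n_cells)

    # orthonormal-ish type directions scaled to the requested separation
    raw = rng.normal(size=(n_types, n_surface))
    q, _ = np.linalg.qr(raw.T)
    type_means = q.T[:n_types] * separation

    surface = type_means[cell_type] + rng.normal(size=(n_cells, n_surface))
    phospho = rng.normal(size=(n_cells, n_phospho))
    responder = (cell_type == 0) & (treatment == "PMA")
    n_resp = min(len(PHOSPHO_RESPONDER_MARKERS), n_phospho)
    phospho[np.ix_(responder, np.arange(n_resp))] += response_shift

    surface_names = list(SURFACE_MARKERS_18[:n_surface])
    surface_names += [f"CD-x{k}" for k in range(len(surface_names), n_surface)]
    phospho_names = list(PHOSPHO_MARKERS_10[:n_phospho])
    phospho_names += [f"pX{k}" for k in range(len(phospho_names), n_phospho)]

    return LabeledMatrix(
        np.hstack([surface, phospho]),
        [f"cell_{i}" for i in range(n_cells)],
        surface_names + phospho_names,
        [
            CategoryTrack("Treatment", "categorical", list(treatment)),
            CategoryTrack("Cell-Type", "categorical", [f"type-{t}" for t in cell_type]),
        ],
        [
            CategoryTrack(
                "Marker-Type",
                "categorical",
                ["surface"] * n_surface + ["phospho"] * n_phospho,
            )
        ],
    )


def make_ptm_like(
    n_ptm: int = 1730,
    n_expr: int = 5000,
    n_lines: int = 37,
    n_runs: int = 8,
    n_variable: int = 1000,
    missing_rate: float = 0.08,
    effect: float = 10.0,
    seed: int = 0,
) -> tuple[LabeledMatrix, LabeledMatrix, dict[str, str]]:
    """PTM panel with per-run reference columns, plus an expression block.

    Returns ``(ptm, expr, reference_map)``. The PTM matrix has one column
    per cell line plus one ``ref-run<r>`` reference column per multiplex
    run; ``reference_map`` maps each cell-line column to its run's
    reference. Levels are positive (log-normal). Sample columns carry
    planted missingness at ``missing_rate``; references are complete.
    The expression block's first ``n_variable`` genes get their s.d.
    multiplied by ``effect`` so they are exactly the top-variance set.
    """
    if n_lines < n_runs:
        raise ValueError("need at least one cell line per run")
    if n_variable > n_expr:
        log.warning("n_variable=%d clamped to n_expr=%d", n_variable, n_expr)
        n_variable = n_expr
    rng = np.random.default_rng(seed)
    lines = [f"LC-{i + 1}" for i in range(n_lines)]
    run_of = {lab: (i % n_runs) + 1 for i, lab in enumerate(lines)}
    if n_lines % n_runs:
        log.info("runs are uneven: %d lines over %d runs", n_lines, n_runs)

    base = rng.lognormal(mean=0.0, sigma=0.5, size=(n_ptm, 1))
    sample_vals = base * rng.lognormal(mean=0.0, sigma=0.4, size=(n_ptm, n_lines))
    ref_vals = base * rng.lognormal(mean=0.0, sigma=0.2, size=(n_ptm, n_runs))
    mask = rng.random(sample_vals.shape) < missing_rate
    sample_vals[mask] = np.nan

    ref_labels = [f"ref-run{r + 1}" for r in range(n_runs)]
    ptm = LabeledMatrix(
        np.hstack([sample_vals, ref_vals]),
        [f"PTM-{i + 1}" for i in range(n_ptm)],
        lines + ref_labels,
        [],
        [
            CategoryTrack(
                "TMT-Run",
                "categorical",
                [f"run-{run_of[lab]}" for lab in lines]
                + [f"run-{r + 1}" for r in range(n_runs)],
            ),
            CategoryTrack(
                "Role", "categorical", ["sample"] * n_lines + ["reference"] * n_runs
            ),
        ],
    )
    reference_map = {lab: f"ref-run{run_of[lab]}" for lab in lines}

    sd = np.ones(n_expr)
    sd[:n_variable] = effect
    expr_vals = rng.normal(size=(n_expr, n_lines)) * sd[:, None]
    expr = LabeledMatrix(
        expr_vals,
        [f"GENE-{i + 1}" for i in range(n_expr)],
        list(lines),
        [],
        [],
    )
    return ptm, expr, reference_map


def make_ccle_like(
    n_genes: int = 1000,
    n_lines_per_tissue: int = 15,
    n_tissues: int = 3,
    n_histologies: int = 2,
    effect: float = 6.0,
    seed: int = 0,
) -> LabeledMatrix:
    """Expression panel whose columns are cell lines grouped by tissue,
    with ``histology``, ``sub-histology`` and ``gender`` column tracks.
    Within each tissue, histology groups get distinct mean profiles on a
    random subset of genes (scaled by ``effect``)."""
    rng = np.random.default_rng(seed)
    n_cols = n_tissues * n_lines_per_tissue
    vals = rng.normal(size=(n_genes, n_cols))
    tissues, hist, subhist, gender, labels = [], [], [], [], []
    for t in range(n_tissues):
        signature = rng.choice(n_genes, size=max(n_genes // 10, 1), replace=False)
        for j in range(n_lines_per_tissue):
            col = t * n_lines_per_tissue + j
            h = j % n_histologies
            tissues.append(f"tissue-{t}")
            hist.append(f"histology-{t}.{h}")
            subhist.append(f"subhist-{t}.{h}.{j % 2}")
            gender.append("F" if rng.random() < 0.5 else "M")
            labels.append(f"CL-{t}-{j}")
            vals[signature, col] += effect * ((h + 1) / n_histologies)
    return LabeledMatrix(
        vals,
        [f"GENE-{i + 1}" for i in range(n_genes)],
        labels,
        [],
        [
            CategoryTrack("tissue", "categorical", tissues),
            CategoryTrack("histology", "categorical", hist),
            CategoryTrack("sub-histology", "categorical", subhist),
            CategoryTrack("gender", "categorical", gender),
        ],
    )
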