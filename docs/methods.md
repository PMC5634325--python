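# Methods

This note records the models, conventions and numerical choices behind
`clustermat`, the reasoning for the choices that were genuinely open, and
what the synthetic fixtures do and do not establish about real data.

## Data model

A `LabeledMatrix` is a dense float matrix with `NaN` as the missing-value
marker, unique tab-free labels per axis, and any number of *category
tracks* per axis. A track is categorical (strings) or numeric (finite
reals); a track is promoted to numeric only when **every** entry parses as
a finite real, which prevents mixed-type tracks from a single stray
numeric-looking cell. Duplicate labels are made unique by appending
`-2`, `-3`, … with a logged warning, because clustering and the document
schema require distinct node identities.

The TSV dialect carries categories either inline on labels
(`|`-separated `Name: value` segments, the written form) or as extra
`Name: value` header rows/columns (accepted and auto-detected on read).
The field's common tools each use their own encoding here; ours is a
declared convention chosen so that write→read is the exact identity,
which the test suite asserts property-style over randomized matrices.

## Normalization and filtering

- **Z-score**: per-vector centering/scaling over non-missing entries,
  `ddof = 1` (sample s.d.) by default to match the dataframe conventions
  of the surrounding ecosystem; configurable. Constant vectors map to all
  zeros rather than NaN so they remain clusterable. Z-scoring is
  idempotent to 1e-9, which the suite checks.
- **Quantile normalization**: the reference distribution is the per-rank
  mean (median available) of the sorted vectors; entries are replaced by
  the reference value at their rank, with tied entries receiving the mean
  of their tied reference values, so within-vector rank order is
  preserved exactly. The strict form refuses missing values. Because the
  PTM pipeline quantile-normalizes *before* its missing-value filter, an
  interpolating variant maps each incomplete vector through the
  reference quantile function on a common grid (the same treatment limma's
  `normalizeQuantiles` applies); it is only used when gaps are present.
- **Top-N filtering** by sum, variance, or absolute sum is a *stable*
  selection: ties break toward earlier rows and survivors keep their
  original order, making results independent of sort internals. Fractions
  keep `ceil(f·n)` vectors. Requests larger than the axis clamp with a
  warning. Vectors whose metric is uncomputable (variance with < 2
  observations) sort last.
- **Ratio to reference** divides each sample column by its mapped
  reference column (per multiplex run, or one shared column) and drops the
  references; zero or missing reference entries yield missing quotients
  rather than infinities.
- **Missing values at distance time** are imputed, transiently, to the
  vector's non-missing mean (equivalently 0 after a row Z-score). The
  imputation is never written back. This is a declared policy: retained
  rows may carry up to 7 gaps in the PTM pipeline and some treatment of
  those gaps inside the distance kernel is unavoidable; the vector mean is
  the choice that leaves cosine geometry least perturbed.

## Clustering engine

Distances: cosine (`1 − u·v/‖u‖‖v‖`, the default), Euclidean, and
correlation (cosine after centering). Zero-norm vectors under
cosine/correlation get distance 1 to any non-degenerate vector and 0 to
each other — the 0/0 case must be fixed by convention, and this one keeps
all-zero rows clusterable as their own tight group.

Agglomeration (average/UPGMA default, single and complete available) is
implemented directly with Lance–Williams updates on a dense matrix rather
than delegated, because the engine promises a *fully deterministic* merge
sequence: among cluster pairs at the minimal distance, the pair whose
smallest original member index is lowest wins (then the other cluster's
smallest index). Library implementations leave tie order unspecified,
which would make document bytes depend on BLAS details. The implementation
is verified merge-by-merge against an exhaustive brute-force agglomerator
on all instances with ≤ 8 leaves over 100 seeds (all three linkages) and
cross-checked against scipy on tie-free metric instances. The working
matrix is compacted as clusters merge, so clustering 2,000 leaves takes
about a second. Average linkage is monotone; a `max(h, previous h)` guard
absorbs float jitter in the heights.

Leaf order is the recursive rule "subtree containing the smallest original
index first", applied iteratively (trees can be thousands deep). Dendrogram
*slices* cut the tree at `f · h_max` for fractions `f ∈ (0, 1]`; merges
with height ≤ the cut are applied, so `f = 1` always yields one group and
any cut below the first merge yields all singletons. Group ids are
numbered by each group's first member along the display leaf order, so
id 0 is the left-most group on screen. The default ladder is ten equal
fractions 0.1…1.0 — slider-style slicing needs a fixed small number of
levels and ten gives one-decimal thresholds; finer control is a parameter
away. Because thresholds are *relative* fractions, group structures are
comparable across datasets without rescaling heights.

## Downsampling

K-means downsampling replaces n rows by exactly K centroid rows.
scikit-learn performs the fit (full-batch Lloyd by default; mini-batch is
used above 50,000 rows, where Lloyd's per-iteration cost stops paying for
its slightly tighter centroids — the *count* contract is identical).
Clusters the fit leaves empty are re-seeded with the points farthest from
their assigned centroids, one each, so K is exact; final centroids are
recomputed as exact member means (asserted to 1e-7). Each centroid carries
`number in clust` (sizes sum to n, asserted always), a `Majority-<track>`
value per categorical track (ties resolve to the lexicographically
smallest mode, logged — determinism over any claim about the "right"
mode), and per-cluster means for numeric tracks, the natural numeric
analogue of the majority rule.

Random subsampling draws without replacement per group of a categorical
track, visiting groups in sorted value order with one seeded generator, so
the draw is a pure function of (matrix, parameters, seed). Label transfer
maps per-cluster labels back to observations and refuses unlabeled
clusters, listing their ids.

## Enrichment

The cluster-category score is the **exact** one-sided binomial upper tail
`P(X ≥ k)` (via the regularized incomplete beta, checked against a naive
coefficient-sum oracle to 1e-12 for all n ≤ 30), not the normal
approximation: dendrogram clusters are routinely small enough (n < 30)
that the z-test is unreliable, and the exact tail is well-defined at every
size. The z statistic is still reported per record for reference.
`k = 0` and degenerate backgrounds (`p0 ∈ {0, 1}`) short-circuit to 1.
The background proportion is computed over *all* leaves of the clustered
axis, the cluster included — this matches the "breakdown of categories
present" framing and makes expected values exactly computable in tests.
Raw P-values are reported (one test per visible cluster/value pair is the
display unit); Benjamini–Hochberg adjustment is an opt-in flag.

An offline gene-symbol matcher (case-insensitive exact match against a
bundled list of ~200 official human symbols, or any caller-supplied list)
lets front ends decide whether rows look gene-centric without network
calls.

## The visualization document

Schema `cm-1` (a faithful-by-content design; no wire-compatibility with
any particular front end is claimed). Per-node: name, initial index,
cluster-order position, sum/variance rank positions, group id per slice
level, category values. Plus: the dense grid (`null` for missing), the
view list, optional row/column similarity blocks, the slice fractions, and
provenance (metric, linkage, normalization, seed, version). Views filter
rows (default ladder: unfiltered, then sum and variance at fractions
0.9…0.1), then re-cluster both axes; they never re-normalize, so all
views remain on one scale. Views that would leave fewer than two rows are
skipped with a warning.

Serialization is canonical: sorted keys, fixed separators, shortest-exact
float repr. Same input + config + seed ⇒ byte-identical output, asserted
end-to-end. The validator is a hand-written structural checker reporting
each violation with its JSON path (node/grid dimension agreement per
block, group-refinement monotonicity across levels, the
unfiltered-view-first rule, schema version).

## Workflows and fixtures

The three pipelines run the stages listed in the README, assert that
consecutive stage dimensions chain (per branch), and record every
parameter and seed in a plain-text report. When the PTM and expression
blocks are stacked, columns are *intersected* (only cell lines present in
both datasets are kept) and rows get a `data-type` track.

The synthetic generators define the test conditions:

- `make_block_matrix` plants row/column blocks via a near-identity block
  mean matrix (identity + 0.1 Gaussian jitter) scaled by `effect` in
  noise-s.d. units: block profiles are near-orthogonal, so recovery by
  slicing is guaranteed at `effect = 10`, and `effect = 0` gives chance
  (adjusted Rand ≈ 0), both asserted.
- `make_cytof_like` (defaults: 220,000 cells, 18 surface + 10 phospho
  markers, two equal treatment arms) draws cell types as a Gaussian
  mixture with orthonormal type directions at separation 8 s.d. — well
  clear of the noise floor so majority-type recovery after downsampling
  exceeds 95%, asserted — and shifts four designated phospho markers
  (pCREB, pMAPKAP2, pp38, pERK1/2) by 5 s.d. in treated responder cells
  as a planted, detectable effect.
- `make_ptm_like` (defaults: 1,730 PTMs × 37 cell lines in 8 runs,
  missing rate 0.08 — of the order seen in multiplexed PTM panels while
  leaving most rows under the 7-gap threshold) produces positive
  log-normal levels, per-run reference columns, and an expression block
  whose first 1,000 genes carry 10× s.d. so the top-variance set is known
  exactly.
- `make_ccle_like` gives tissues × histology structure for the per-tissue
  workflow.

What passing these tests shows: the pipelines apply the right operations
with the right parameters, conserve what they must, and are deterministic.
What they do not show: behavior under real mass-cytometry artifacts
(spillover, debarcoding errors, zero-inflation), real PTM chemistry, or
real batch structure — none of which the Gaussian/log-normal fixtures
model.

## Problem sizes and determinism

Unit and property tests run on matrices up to a few hundred rows; the
case-study-scale checks (220,000 × 28 generation, mini-batch downsampling
to 2,000 clusters) run in well under a minute together. All randomness in
the package flows from explicit integer seeds through per-call
`numpy.random.Generator` instances; nothing touches global RNG state.
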