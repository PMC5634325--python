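"""Labeled matrices with category tracks, and their tab-separated dialect.

The central container is :class:`LabeledMatrix`: a dense numeric matrix
(``NaN`` marks missing entries) whose rows and columns carry unique string
labels plus any number of *category tracks*. A track is a named per-label
annotation and is either categorical (strings, e.g. a histology) or numeric
(finite reals, e.g. the size of a downsampled cluster).

Two TSV encodings of categories are accepted and auto-detected:

``label dialect``
    Categories ride on the label cell as ``|``-separated segments of the
    form ``Name: value``, e.g. ``cell_001|Treatment: PMA|number in clust: 37``.

``block dialect``
    Extra header rows (below the column-label row) and/or extra leading
    columns (after the row-label column) hold one ``Name: value`` cell per
    label, with a single shared ``Name`` per row/column of the block.

Writers emit the label dialect, which round-trips exactly.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "CategoryTrack",
    "LabeledMatrix",
    "TsvDialect",
    "MatrixFormatError",
    "parse_category_label",
    "read_matrix_tsv",
    "write_matrix_tsv",
]


class MatrixFormatError(ValueError):
    """Raised for malformed matrix files or invalid container contents."""


_MISSING_TOKENS = {"", "na", "nan"}
_KV_RE = re.compile(r"^\s*(?P<name>[^:]+?)\s*:\s*(?P<value>.*?)\s*$")


def _try_float(text: str) -> float | None:
    """Parse ``text`` as a finite real, or return None."""
    try:
        x = float(text)
    except ValueError:
        return None
    return x if math.isfinite(x) else None


@dataclass
class TsvDialect:
    """Knobs of the tab-separated encoding.

    ``category_sep`` separates label segments in the label dialect;
    ``kv_sep`` separates a category name from its value inside a segment.
    """

    category_sep: str = "|"
    kv_sep: str = ": "


@dataclass
class CategoryTrack:
    """A named per-label annotation along one axis.

    ``kind`` is ``"categorical"`` (string entries) or ``"numeric"``
    (finite-real entries). A track is numeric only when *every* entry
    parses as a finite real; mixed tracks are kept categorical.
    """

    name: str
    kind: str
    entries: list

    def __post_init__(self) -> None:
        if self.kind not in ("categorical", "numeric"):
            raise MatrixFormatError(f"unknown track kind {self.kind!r}")
        self.entries = list(self.entries)
        if self.kind == "numeric":
            for v in self.entries:
                if not (isinstance(v, (int, float)) and math.isfinite(v)):
                    raise MatrixFormatError(
                        f"numeric track {self.name!r} has non-finite entry {v!r}"
                    )
        else:
            self.entries = [str(v) for v in self.entries]

    def subset(self, idx: Sequence[int]) -> "CategoryTrack":
        return CategoryTrack(self.name, self.kind, [self.entries[i] for i in idx])

    def __eq__(self, other) -> bool:
        if not isinstance(other, CategoryTrack):
            return NotImplemented
        return (
            self.name == other.name
            and self.kind == other.kind
            and len(self.entries) == len(other.entries)
            and all(
                (a == b or (self.kind == "numeric" and math.isclose(a, b, rel_tol=0, abs_tol=0.0)))
                for a, b in zip(self.entries, other.entries)
            )
        )


@dataclass
class LabeledMatrix:
    """Dense numeric matrix with labeled, annotated rows and columns.

    ``values`` is float ndarray of shape ``(len(row_labels), len(col_labels))``
    with ``NaN`` for missing entries. Labels must be unique and tab-free;
    every category track carries exactly one entry per label on its axis.
    """

    values: np.ndarray
    row_labels: list[str]
    col_labels: list[str]
    row_categories: list[CategoryTrack] = field(default_factory=list)
    col_categories: list[CategoryTrack] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise MatrixFormatError("values must be 2-D")
        self.row_labels = [str(s) for s in self.row_labels]
        self.col_labels = [str(s) for s in self.col_labels]
        self.validate()

    # -- contracts -------------------------------------------------------
    def validate(self) -> None:
        n, m = self.values.shape
        if n != len(self.row_labels) or m != len(self.col_labels):
            raise MatrixFormatError(
                f"shape {self.values.shape} does not match "
                f"{len(self.row_labels)} row / {len(self.col_labels)} col labels"
            )
        for axis_name, labels in (("row", self.row_labels), ("column", self.col_labels)):
            for lab in labels:
                if not lab:
                    raise MatrixFormatError(f"empty {axis_name} label")
                if "\t" in lab:
                    raise MatrixFormatError(f"{axis_name} label contains a tab: {lab!r}")
            dupes = _duplicates(labels)
            if dupes:
                raise MatrixFormatError(f"duplicate {axis_name} labels: {sorted(dupes)}")
        for axis_name, labels, tracks in (
            ("row", self.row_labels, self.row_categories),
            ("column", self.col_labels, self.col_categories),
        ):
            for tr in tracks:
                if len(tr.entries) != len(labels):
                    raise MatrixFormatError(
                        f"{axis_name} track {tr.name!r} has {len(tr.entries)} entries "
                        f"for {len(labels)} labels"
                    )

    # -- conveniences ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "LabeledMatrix":
        return LabeledMatrix(
            self.values.copy(),
            list(self.row_labels),
            list(self.col_labels),
            [replace(t, entries=list(t.entries)) for t in self.row_categories],
            [replace(t, entries=list(t.entries)) for t in self.col_categories],
        )

    def subset_rows(self, idx: Sequence[int]) -> "LabeledMatrix":
        idx = list(idx)
        return LabeledMatrix(
            self.values[idx, :],
            [self.row_labels[i] for i in idx],
            list(self.col_labels),
            [t.subset(idx) for t in self.row_categories],
            [replace(t, entries=list(t.entries)) for t in self.col_categories],
        )

    def subset_cols(self, idx: Sequence[int]) -> "LabeledMatrix":
        idx = list(idx)
        return LabeledMatrix(
            self.values[:, idx],
            list(self.row_labels),
            [self.col_labels[i] for i in idx],
            [replace(t, entries=list(t.entries)) for t in self.row_categories],
            [t.subset(idx) for t in self.col_categories],
        )

    def transpose(self) -> "LabeledMatrix":
        return LabeledMatrix(
            self.values.T.copy(),
            list(self.col_labels),
            list(self.row_labels),
            [replace(t, entries=list(t.entries)) for t in self.col_categories],
            [replace(t, entries=list(t.entries)) for t in self.row_categories],
        )

    def axis_labels(self, axis: str) -> list[str]:
        return self.row_labels if _check_axis(axis) == "rows" else self.col_labels

    def axis_categories(self, axis: str) -> list[CategoryTrack]:
        return self.row_categories if _check_axis(axis) == "rows" else self.col_categories

    def get_track(self, axis: str, name: str) -> CategoryTrack:
        for tr in self.axis_categories(axis):
            if tr.name == name:
                return tr
        raise KeyError(
            f"no {axis} category track named {name!r}; available: "
            f"{[t.name for t in self.axis_categories(axis)]}"
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, LabeledMatrix):
            return NotImplemented
        if self.row_labels != other.row_labels or self.col_labels != other.col_labels:
            return False
        if self.row_categories != other.row_categories:
            return False
        if self.col_categories != other.col_categories:
            return False
        if self.values.shape != other.values.shape:
            return False
        a, b = self.values, other.values
        return bool(np.all((a == b) | (np.isnan(a) & np.isnan(b))))


def _check_axis(axis: str) -> str:
    if axis not in ("rows", "columns"):
        raise ValueError(f"axis must be 'rows' or 'columns', got {axis!r}")
    return axis


def _duplicates(items: Iterable[str]) -> set:
    seen, dup = set(), set()
    for x in items:
        if x in seen:
            dup.add(x)
        seen.add(x)
    return dup


def disambiguate_labels(labels: Sequence[str]) -> list[str]:
    """Make labels unique by appending ``-2``, ``-3``, ... to repeats."""
    counts: dict[str, int] = {}
    out = []
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
        out.append(lab if counts[lab] == 1 else f"{lab}-{counts[lab]}")
    if len(set(labels)) != len(labels):
        log.warning("duplicate labels disambiguated with numeric suffixes")
    return out


# ---------------------------------------------------------------------------
# label parsing


def parse_category_label(
    raw: str, dialect: TsvDialect | None = None
) -> tuple[str, list[tuple[str, Union[str, float]]]]:
    """Split a label cell into its base label and (name, value) categories.

    Segments after the first are split on the dialect's ``kv_sep``; values
    that parse as finite reals are returned as floats (the track assembler
    decides the final track kind). A label without the separator yields an
    empty category list.

    >>> parse_category_label("cell_001|Majority-Treatment: PMA")
    ('cell_001', [('Majority-Treatment', 'PMA')])
    """
    dialect = dialect or TsvDialect()
    if raw is None or raw == "":
        raise MatrixFormatError("empty label")
    parts = raw.split(dialect.category_sep)
    base = parts[0].strip()
    if not base:
        raise MatrixFormatError(f"empty base label in {raw!r}")
    cats: list[tuple[str, Union[str, float]]] = []
    for seg in parts[1:]:
        m = _KV_RE.match(seg)
        if not m:
            raise MatrixFormatError(
                f"category segment {seg!r} in label {raw!r} is not 'Name: value'"
            )
        name, value = m.group("name"), m.group("value")
        num = _try_float(value)
        cats.append((name, num if num is not None else value))
    return base, cats


def _assemble_tracks(
    per_label: list[list[tuple[str, Union[str, float]]]], n: int
) -> list[CategoryTrack]:
    """Build tracks from per-label (name, value) lists.

    Track order follows first appearance. A label missing a named category
    gets the empty string (forcing the track categorical). A track is
    numeric only if every entry parsed as a finite real.
    """
    order: list[str] = []
    values: dict[str, dict[int, Union[str, float]]] = {}
    for i, cats in enumerate(per_label):
        for name, value in cats:
            if name not in values:
                order.append(name)
                values[name] = {}
            values[name][i] = value
    tracks = []
    for name in order:
        got = values[name]
        complete = len(got) == n
        numeric = complete and all(isinstance(v, float) for v in got.values())
        if numeric:
            entries: list = [float(got[i]) for i in range(n)]
            tracks.append(CategoryTrack(name, "numeric", entries))
        else:
            entries = [_cat_str(got.get(i, "")) for i in range(n)]
            tracks.append(CategoryTrack(name, "categorical", entries))
    return tracks


def _cat_str(v: Union[str, float]) -> str:
    if isinstance(v, float):
        return _fmt_number(v)
    return v


def _fmt_number(x: float) -> str:
    """Shortest exact decimal form; integers lose the trailing '.0'."""
    x = float(x)
    if math.isfinite(x) and x == int(x) and abs(x) < 1e16:
        return str(int(x))
    return repr(x)


# ---------------------------------------------------------------------------
# reading


def read_matrix_tsv(path, dialect: TsvDialect | None = None) -> LabeledMatrix:
    """Read a tab-separated labeled matrix (see module docstring for dialects).

    Raises :class:`MatrixFormatError` for ragged rows (naming the line),
    non-numeric value cells (with 1-based row/column coordinates), or files
    too small to hold a matrix. Duplicate labels are disambiguated with a
    numeric suffix and a logged warning.
    """
    dialect = dialect or TsvDialect()
    text = Path(path).read_text(encoding="utf-8")
    lines = text.splitlines()
    while lines and lines[-1] == "":
        lines.pop()
    if len(lines) < 2:
        raise MatrixFormatError(f"{path}: need a header line and at least one data row")
    rows = [line.split("\t") for line in lines]
    width = len(rows[0])
    if width < 2:
        raise MatrixFormatError(f"{path}: header has no data columns")
    for i, r in enumerate(rows[1:], start=2):
        if len(r) != width:
            raise MatrixFormatError(
                f"{path}: ragged row at line {i}: {len(r)} fields, expected {width}"
            )

    # Block dialect, part 1: header rows whose payload cells all share one
    # 'Name: value' category name describe a column category each.
    col_cat_rows = []
    r = 1
    while r < len(rows) - 1:
        name = _block_line_name([c for c in rows[r][1:]])
        if name is None:
            break
        col_cat_rows.append(r)
        r += 1
    first_data_row = r

    # Block dialect, part 2: leading columns (after the label column) whose
    # data cells all share one 'Name: value' category name.
    row_cat_cols = []
    c = 1
    while c < width - 1:
        name = _block_line_name([rows[i][c] for i in range(first_data_row, len(rows))])
        if name is None:
            break
        row_cat_cols.append(c)
        c += 1
    first_data_col = c

    n_rows = len(rows) - first_data_row
    n_cols = width - first_data_col
    if n_rows < 1 or n_cols < 1:
        raise MatrixFormatError(f"{path}: no value block found")

    # column labels + label-dialect categories
    col_parsed = [
        parse_category_label(rows[0][first_data_col + j], dialect) for j in range(n_cols)
    ]
    col_labels = disambiguate_labels([b for b, _ in col_parsed])
    col_cats_per_label = [c for _, c in col_parsed]
    # block-dialect column categories appended after label-dialect ones
    for r in col_cat_rows:
        name = _block_line_name(rows[r][1:])
        for j in range(n_cols):
            m = _KV_RE.match(rows[r][first_data_col + j])
            value = m.group("value") if m else ""
            num = _try_float(value)
            col_cats_per_label[j].append((name, num if num is not None else value))

    row_cat_names = {
        c0: _block_line_name([rows[k][c0] for k in range(first_data_row, len(rows))])
        for c0 in row_cat_cols
    }
    row_parsed = []
    vals = np.empty((n_rows, n_cols), dtype=float)
    for i in range(n_rows):
        line = rows[first_data_row + i]
        base, cats = parse_category_label(line[0], dialect)
        for c0 in row_cat_cols:
            mkv = _KV_RE.match(line[c0])
            value = mkv.group("value") if mkv else ""
            num = _try_float(value)
            cats.append((row_cat_names[c0], num if num is not None else value))
        row_parsed.append((base, cats))
        for j in range(n_cols):
            cell = line[first_data_col + j].strip()
            if cell.lower() in _MISSING_TOKENS:
                vals[i, j] = np.nan
                continue
            num = _try_float(cell)
            if num is None:
                raise MatrixFormatError(
                    f"{path}: non-numeric value {cell!r} at matrix row "
                    f"{i + 1}, column {j + 1}"
                )
            vals[i, j] = num

    row_labels = disambiguate_labels([b for b, _ in row_parsed])
    return LabeledMatrix(
        vals,
        row_labels,
        col_labels,
        _assemble_tracks([c for _, c in row_parsed], n_rows),
        _assemble_tracks(col_cats_per_label, n_cols),
    )


def _block_line_name(cells: list[str]) -> str | None:
    """Shared category name if every non-empty cell is 'Name: value' with
    one name (empty cells — the corner region — are ignored)."""
    names = set()
    for cell in cells:
        if cell == "":
            continue
        m = _KV_RE.match(cell)
        if not m or not m.group("value"):
            return None
        names.add(m.group("name"))
    if len(names) != 1:
        return None
    return names.pop()


# ---------------------------------------------------------------------------
# writing


def _label_with_cats(
    label: str, tracks: list[CategoryTrack], i: int, dialect: TsvDialect
) -> str:
    segs = [label]
    for tr in tracks:
        v = tr.entries[i]
        segs.append(f"{tr.name}{dialect.kv_sep}{_cat_str(v)}")
    return dialect.category_sep.join(segs)


def write_matrix_tsv(m: LabeledMatrix, path, dialect: TsvDialect | None = None) -> None:
    """Write ``m`` in the label dialect; ``read_matrix_tsv`` inverts exactly."""
    dialect = dialect or TsvDialect()
    m.validate()
    with open(path, "w", encoding="utf-8") as fh:
        header = [""] + [
            _label_with_cats(lab, m.col_categories, j, dialect)
            for j, lab in enumerate(m.col_labels)
        ]
        fh.write("\t".join(header) + "\n")
        for i, lab in enumerate(m.row_labels):
            cells = [_label_with_cats(lab, m.row_categories, i, dialect)]
            for x in m.values[i, :]:
                cells.append("" if math.isnan(x) else _fmt_number(x))
            fh.write("\t".join(cells) + "\n")
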