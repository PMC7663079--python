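"""Data model and file I/O for binary bipartite networks.

A bipartite network links two disjoint guilds (e.g. plants and their
pollinators, or sellers and buyers).  The package represents it by its
*biadjacency* matrix ``B``: an ``n x m`` 0/1 matrix whose rows are one
guild and whose columns are the other, with ``b_ij = 1`` iff row-node
``i`` interacts with column-node ``j``.

Two dense-matrix dialects are supported (CSV and TSV, with optional
header row and row-label column, any positive weight meaning presence)
plus a two-column edge list.  Weighted inputs are binarized on read.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "BipartiteNetwork",
    "DegreeSequences",
    "NetworkDescriptors",
    "ValidationError",
    "ParseError",
    "read_matrix",
    "read_edgelist",
    "write_matrix",
    "degree_sequences",
    "descriptors",
]


class ValidationError(ValueError):
    """An object violates the bipartite-network contracts."""


class ParseError(ValueError):
    """A file could not be parsed as a bipartite network."""


def _default_row_labels(n: int) -> tuple[str, ...]:
    return tuple(f"R{i + 1}" for i in range(n))


def _default_col_labels(m: int) -> tuple[str, ...]:
    return tuple(f"C{j + 1}" for j in range(m))


@dataclass(frozen=True, eq=False)
class BipartiteNetwork:
    """A binary bipartite network given by its biadjacency matrix.

    Zero-degree rows or columns are legal: null-model samples can
    disconnect nodes, and every metric is required to tolerate them.
    """

    matrix: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        mat = np.asarray(self.matrix)
        if mat.ndim != 2 or mat.shape[0] < 1 or mat.shape[1] < 1:
            raise ValidationError(f"matrix must be 2-D and non-empty, got shape {mat.shape}")
        if not np.isin(mat, (0, 1)).all():
            raise ValidationError("matrix entries must all be 0 or 1")
        mat = mat.astype(np.int8)
        mat.setflags(write=False)
        object.__setattr__(self, "matrix", mat)
        n, m = mat.shape
        rl = tuple(self.row_labels) if self.row_labels else _default_row_labels(n)
        cl = tuple(self.col_labels) if self.col_labels else _default_col_labels(m)
        if len(rl) != n:
            raise ValidationError(f"{len(rl)} row labels for {n} rows")
        if len(cl) != m:
            raise ValidationError(f"{len(cl)} column labels for {m} columns")
        if len(set(rl)) != n:
            raise ValidationError("row labels are not unique")
        if len(set(cl)) != m:
            raise ValidationError("column labels are not unique")
        object.__setattr__(self, "row_labels", tuple(map(str, rl)))
        object.__setattr__(self, "col_labels", tuple(map(str, cl)))

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    @property
    def n_links(self) -> int:
        """E, the number of 1-entries."""
        return int(self.matrix.sum())

    @property
    def fill(self) -> float:
        """E / (n * m), the density of contacts."""
        return self.n_links / (self.n_rows * self.n_cols)

    def row_degrees(self) -> np.ndarray:
        return self.matrix.sum(axis=1).astype(np.int64)

    def col_degrees(self) -> np.ndarray:
        return self.matrix.sum(axis=0).astype(np.int64)

    def transpose(self) -> "BipartiteNetwork":
        """Swap the two guilds."""
        return BipartiteNetwork(self.matrix.T.copy(), self.col_labels, self.row_labels)

    def permuted(self, row_order: Sequence[int], col_order: Sequence[int]) -> "BipartiteNetwork":
        row_order = np.asarray(row_order)
        col_order = np.asarray(col_order)
        return BipartiteNetwork(
            self.matrix[np.ix_(row_order, col_order)].copy(),
            tuple(self.row_labels[i] for i in row_order),
            tuple(self.col_labels[j] for j in col_order),
        )

    def trimmed(self) -> "BipartiteNetwork":
        """Drop zero-degree rows and columns.

        Raises :class:`ValidationError` on the all-zero matrix, which
        has no connected node in either guild.
        """
        rows = np.flatnonzero(self.row_degrees() > 0)
        cols = np.flatnonzero(self.col_degrees() > 0)
        if rows.size == 0 or cols.size == 0:
            raise ValidationError("cannot trim an edgeless network")
        return self.permuted(rows, cols)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BipartiteNetwork):
            return NotImplemented
        return (
            self.matrix.shape == other.matrix.shape
            and bool((self.matrix == other.matrix).all())
            and self.row_labels == other.row_labels
            and self.col_labels == other.col_labels
        )

    def __repr__(self) -> str:
        return (
            f"BipartiteNetwork(n={self.n_rows}, m={self.n_cols}, "
            f"E={self.n_links})"
        )


@dataclass(frozen=True)
class DegreeSequences:
    row_degrees: tuple[int, ...]
    col_degrees: tuple[int, ...]


@dataclass(frozen=True)
class NetworkDescriptors:
    """The four structural descriptors used by the dependency analyses.

    ``fill_matrix`` is E/(n*m) (the density of contacts the metrics use)
    while ``links_per_node`` is E/(n+m) (the fill covariate of the
    regressions).  Both conventions are kept, under distinct names.
    """

    size_s: int
    fill_matrix: float
    links_per_node: float
    eccentricity: float
    degeneracy_g: float


def degree_sequences(net: BipartiteNetwork) -> DegreeSequences:
    return DegreeSequences(
        tuple(int(d) for d in net.row_degrees()),
        tuple(int(d) for d in net.col_degrees()),
    )


def _degeneracy(net: BipartiteNetwork) -> float:
    # A node is degenerate when its degree value occurs more than once
    # within its own guild; cross-guild coincidences do not count.
    total = 0
    for degs in (net.row_degrees(), net.col_degrees()):
        counts = Counter(degs.tolist())
        total += sum(c for c in counts.values() if c > 1)
    return total / (net.n_rows + net.n_cols)


def descriptors(net: BipartiteNetwork) -> NetworkDescriptors:
    n, m = net.n_rows, net.n_cols
    e = net.n_links
    return NetworkDescriptors(
        size_s=n + m,
        fill_matrix=e / (n * m),
        links_per_node=e / (n + m),
        eccentricity=abs(n - m) / (n + m),
        degeneracy_g=_degeneracy(net),
    )


# ---------------------------------------------------------------------------
# file I/O


def _sniff_delimiter(path: Path, first_line: str) -> str:
    if "\t" in first_line:
        return "\t"
    if "," in first_line:
        return ","
    suffix = path.suffix.lower()
    return "\t" if suffix in {".tsv", ".tab", ".txt"} else ","


def _is_number(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def read_matrix(
    path: str | Path,
    delimiter: str | None = None,
    header: bool | None = None,
    row_label_column: bool | None = None,
) -> BipartiteNetwork:
    """Read a dense 0/1 (or weighted) matrix file.

    ``header`` and ``row_label_column`` default to auto-detection: a
    first row (column) whose non-corner cells are not all numeric is
    treated as labels.  Any positive cell value is binarized to 1.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError(f"{path}: file is empty")
    delim = delimiter or _sniff_delimiter(path, lines[0])
    rows = list(csv.reader(lines, delimiter=delim))
    width = len(rows[0])
    for k, r in enumerate(rows):
        if len(r) != width:
            raise ParseError(f"{path}: line {k + 1} has {len(r)} cells, expected {width}")

    if header is None:
        # A non-numeric cell past the first marks a header row; the first
        # cell alone may instead be a row label.  Single-column files fall
        # back on the first cell.
        header = any(not _is_number(c) for c in rows[0][1:]) or (
            len(rows[0]) == 1 and not _is_number(rows[0][0])
        )
    body = rows[1:] if header else rows
    if not body:
        raise ParseError(f"{path}: no data rows below the header")
    if row_label_column is None:
        row_label_column = any(not _is_number(r[0]) for r in body)

    col_labels: tuple[str, ...] = ()
    row_labels: list[str] = []
    if header:
        hdr = rows[0][1:] if row_label_column else rows[0]
        col_labels = tuple(c.strip() for c in hdr)

    data = []
    for k, r in enumerate(body):
        line_no = k + 2 if header else k + 1
        cells = r
        if row_label_column:
            row_labels.append(cells[0].strip())
            cells = cells[1:]
        try:
            values = [float(c) for c in cells]
        except ValueError as exc:
            raise ParseError(f"{path}: line {line_no}: {exc}") from None
        if any(v < 0 for v in values):
            raise ValidationError(f"{path}: line {line_no}: negative entry")
        data.append([1 if v > 0 else 0 for v in values])

    matrix = np.array(data, dtype=np.int8)
    return BipartiteNetwork(
        matrix,
        tuple(row_labels) if row_labels else (),
        col_labels,
    )


def read_edgelist(path: str | Path, delimiter: str | None = None) -> BipartiteNetwork:
    """Read a two-column edge list (row-guild id first).

    Duplicate edges collapse to a single link; label order follows
    first appearance.  An identifier seen in both columns is rejected,
    since the guild of such a node cannot be inferred.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if not lines:
        raise ValidationError(f"{path}: edge list is empty")
    delim = delimiter or _sniff_delimiter(path, lines[0])
    edges: list[tuple[str, str]] = []
    for k, ln in enumerate(lines):
        parts = [p.strip() for p in ln.split(delim)]
        if len(parts) != 2 or not parts[0] or not parts[1]:
            raise ParseError(f"{path}: line {k + 1}: expected two columns, got {ln!r}")
        edges.append((parts[0], parts[1]))

    row_ids = {r for r, _ in edges}
    col_ids = {c for _, c in edges}
    overlap = row_ids & col_ids
    if overlap:
        raise ValidationError(
            f"{path}: identifiers appear in both guilds, guild inference is "
            f"ambiguous: {sorted(overlap)[:5]}"
        )

    row_labels: list[str] = []
    col_labels: list[str] = []
    row_index: dict[str, int] = {}
    col_index: dict[str, int] = {}
    for r, c in edges:
        if r not in row_index:
            row_index[r] = len(row_labels)
            row_labels.append(r)
        if c not in col_index:
            col_index[c] = len(col_labels)
            col_labels.append(c)
    matrix = np.zeros((len(row_labels), len(col_labels)), dtype=np.int8)
    for r, c in edges:
        matrix[row_index[r], col_index[c]] = 1
    return BipartiteNetwork(matrix, tuple(row_labels), tuple(col_labels))


def write_matrix(
    net: BipartiteNetwork,
    path: str | Path,
    delimiter: str | None = None,
    include_labels: bool | None = None,
) -> None:
    """Write a network as a dense matrix file.

    Labels are written only when they differ from the auto-generated
    defaults (``include_labels=None``), so an unlabeled matrix
    round-trips to the bare numeric file it came from.
    """
    path = Path(path)
    delim = delimiter or ("\t" if path.suffix.lower() in {".tsv", ".tab"} else ",")
    if include_labels is None:
        include_labels = (
            net.row_labels != _default_row_labels(net.n_rows)
            or net.col_labels != _default_col_labels(net.n_cols)
        )
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delim, lineterminator="\n")
        if include_labels:
            writer.writerow(["", *net.col_labels])
            for label, row in zip(net.row_labels, net.matrix):
                writer.writerow([label, *map(int, row)])
        else:
            for row in net.matrix:
                writer.writerow(list(map(int, row)))
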