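"""Maximally packed configurations and the perfectly nested reference.

Packing reorders rows and columns by non-increasing degree so that the
filled region concentrates toward the top-left corner; several of the
indices (temperature, discrepancy, NMD, NODF) are defined on the packed
matrix.  The perfectly nested reference of given shape and link count is
built on the unit-square mapping: cell centers get coordinates
``x_j = (j - 1/2)/m`` and ``y_i = (i - 1/2)/n`` and the E cells with the
smallest Manhattan distance ``x_j + y_i`` to the nested corner are
filled.  The isocline of perfect nestedness (IPN) used by the
temperature index is the discrete staircase boundary of that reference
matrix, which makes the temperature of a perfectly nested matrix exactly
zero by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .network import BipartiteNetwork, ValidationError

__all__ = [
    "PackedNetwork",
    "UnitSquareMap",
    "IsoclineModel",
    "pack",
    "canonical_nested",
    "ipn_boundary",
    "unexpectedness_set",
]

_MAX_PACK_PASSES = 100

UnexpectedKind = Literal["unexpected_presence", "unexpected_absence"]


@dataclass(frozen=True)
class UnitSquareMap:
    """Cell-center coordinates of an n x m matrix mapped into (0,1)^2."""

    n: int
    m: int

    def x_of_col(self, j: int) -> float:
        """x coordinate of column ``j`` (1-based)."""
        return (j - 0.5) / self.m

    def y_of_row(self, i: int) -> float:
        """y coordinate of row ``i`` (1-based)."""
        return (i - 0.5) / self.n

    def cell_distance(self, i: int, j: int) -> float:
        """Manhattan distance of cell (i, j) from the nested corner."""
        return self.x_of_col(j) + self.y_of_row(i)


@dataclass(frozen=True)
class PackedNetwork:
    """A network together with the permutations that pack it."""

    network: BipartiteNetwork
    row_order: tuple[int, ...]
    col_order: tuple[int, ...]

    @property
    def matrix(self) -> np.ndarray:
        """The packed biadjacency matrix."""
        return self.network.matrix[np.ix_(self.row_order, self.col_order)]

    def packed_network(self) -> BipartiteNetwork:
        return self.network.permuted(list(self.row_order), list(self.col_order))


@dataclass(frozen=True)
class IsoclineModel:
    """Discrete isocline of perfect nestedness for given (n, m, E).

    ``boundary[i]`` is the number of filled cells in packed row ``i`` of
    the perfectly nested reference: cells (i, j <= boundary[i]) lie on
    the filled side.
    """

    n: int
    m: int
    e: int
    boundary: tuple[int, ...]


def _order_axis(matrix: np.ndarray, other_ranks: np.ndarray) -> np.ndarray:
    """Order rows of ``matrix`` by decreasing degree; ties by decreasing
    sum of partner column ranks, then by original index."""
    degrees = matrix.sum(axis=1)
    rank_sums = matrix @ other_ranks
    order = sorted(
        range(matrix.shape[0]),
        key=lambda i: (-degrees[i], -rank_sums[i], i),
    )
    return np.asarray(order)


def pack(net: BipartiteNetwork) -> PackedNetwork:
    """Bring a network to its maximally packed configuration.

    Deterministic degree sorting, alternating between the guilds until
    the orders are stable (or a fixed pass limit is hit): rows sorted by
    decreasing degree with ties broken by decreasing sum of the packed
    ranks of their partner columns, then original index; columns
    symmetrically.
    """
    mat = net.matrix
    n, m = mat.shape
    row_order = np.arange(n)
    col_order = np.arange(m)
    for _ in range(_MAX_PACK_PASSES):
        col_ranks = np.empty(m, dtype=np.int64)
        col_ranks[col_order] = np.arange(1, m + 1)
        new_rows = _order_axis(mat, col_ranks)
        row_ranks = np.empty(n, dtype=np.int64)
        row_ranks[new_rows] = np.arange(1, n + 1)
        new_cols = _order_axis(mat.T, row_ranks)
        if (new_rows == row_order).all() and (new_cols == col_order).all():
            break
        row_order, col_order = new_rows, new_cols
    return PackedNetwork(net, tuple(int(i) for i in row_order), tuple(int(j) for j in col_order))


def canonical_nested(n: int, m: int, e: int) -> BipartiteNetwork:
    """The perfectly nested reference matrix of shape (n, m) with E links.

    Fills the ``e`` cells with smallest unit-square Manhattan distance
    ``(j - 1/2)/m + (i - 1/2)/n``; ties are resolved in favor of smaller
    row index, then smaller column index.  The result is a staircase:
    every row's support is a prefix of the columns, with non-increasing
    lengths.
    """
    if not (0 <= e <= n * m):
        raise ValidationError(f"E={e} outside [0, {n * m}] for a {n}x{m} matrix")
    matrix = np.zeros((n, m), dtype=np.int8)
    if e > 0:
        i_idx, j_idx = np.divmod(np.arange(n * m), m)
        # integer-scaled Manhattan cost, 2*n*m * ((j+.5)/m + (i+.5)/n),
        # so distance ties are detected exactly
        cost = (2 * j_idx + 1) * n + (2 * i_idx + 1) * m
        # lexsort: last key is primary
        order = np.lexsort((j_idx, i_idx, cost))
        chosen = order[:e]
        matrix[i_idx[chosen], j_idx[chosen]] = 1
    return BipartiteNetwork(matrix)


def ipn_boundary(n: int, m: int, e: int) -> IsoclineModel:
    """Isocline of perfect nestedness for (n, m, E): the staircase
    boundary of the canonical nested matrix, as per-row thresholds."""
    reference = canonical_nested(n, m, e)
    c = reference.matrix.sum(axis=1)
    return IsoclineModel(n=n, m=m, e=e, boundary=tuple(int(x) for x in c))


def unexpectedness_set(
    packed: PackedNetwork, ipn: IsoclineModel
) -> set[tuple[int, int, UnexpectedKind]]:
    """Cells of a packed matrix on the wrong side of the isocline.

    Returns 0-based ``(row, col, kind)`` triples: 1-cells beyond the
    boundary are unexpected presences, 0-cells inside it unexpected
    absences.  When the matrix has exactly ``ipn.e`` links the two sets
    have equal cardinality.
    """
    mat = packed.matrix
    n, m = mat.shape
    if (n, m) != (ipn.n, ipn.m):
        raise ValidationError(
            f"isocline built for {ipn.n}x{ipn.m}, matrix is {n}x{m}"
        )
    out: set[tuple[int, int, UnexpectedKind]] = set()
    boundary = ipn.boundary
    for i in range(n):
        c = boundary[i]
        row = mat[i]
        for j in np.flatnonzero(row[c:]):
            out.add((i, int(c + j), "unexpected_presence"))
        for j in np.flatnonzero(row[:c] == 0):
            out.add((i, int(j), "unexpected_absence"))
    return out
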