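"""Nestedness indices for binary bipartite networks.

Eight indices are implemented, spanning the three families found in the
literature:

* misplaced-interaction counts against a perfectly nested template
  (Brualdi–Sanderson discrepancy),
* distance-weighted misplacement (Atmar–Patterson temperature, the
  Manhattan-distance index tau/NMD),
* global structural properties (NODF and stable-NODF overlap indices,
  the robustness-based NIR, and the spectral radius raw and normalized).

Where an index is oriented "smaller = more nested" a transformed 0-100
companion with the opposite orientation is reported as well:
``T = 100 - T_AP``, ``NMD = 100 (1 - tau)`` and ``Delta' = 100 (1 -
Delta/E)``.

Indices that are mathematically undefined for an input (no links at
all; complete fill for NIR and the Manhattan index) raise
:class:`UndefinedMetricError`; :func:`compute_all` converts that into an
explicitly flagged entry rather than a silent zero or NaN.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Literal

import numpy as np

from .network import BipartiteNetwork, ValidationError
from .packing import (
    IsoclineModel,
    PackedNetwork,
    UnitSquareMap,
    canonical_nested,
    ipn_boundary,
    pack,
    unexpectedness_set,
)

__all__ = [
    "UndefinedMetricError",
    "AttackToleranceCurve",
    "MetricEntry",
    "MetricReport",
    "MetricConfig",
    "METRIC_NAMES",
    "U_MAX",
    "temperature",
    "nmd",
    "nodf",
    "stable_nodf",
    "discrepancy",
    "atc",
    "nir",
    "spectral_radius",
    "normalized_spectral_radius",
    "compute_all",
    "metric_value",
]

#: Normalization constant of the Atmar–Patterson temperature, the value
#: used by the original 1993 implementation and its descendants.  It
#: only rescales T_AP.
U_MAX = 0.04145


class UndefinedMetricError(ValueError):
    """The requested index is mathematically undefined for this input."""


# ---------------------------------------------------------------------------
# temperature


def _diagonal_crossing(
    boundary: tuple[int, ...],
    n: int,
    m: int,
    i: int,
    j: int,
) -> tuple[float, float]:
    """Distance geometry for one unexpected cell (0-based ``i, j``).

    The cell center is mapped into the unit square and the diagonal line
    of slope +1 through it is intersected with the staircase isocline.
    Returns ``(d, D)``: distance from the cell to the nearest crossing
    and the full chord length of the diagonal inside the square.  If the
    diagonal never meets the staircase the far end of the chord is used,
    i.e. the cell counts as maximally displaced along its diagonal.
    """
    x0 = (j + 0.5) / m
    y0 = (i + 0.5) / n
    s_min = -min(x0, y0)
    s_max = min(1.0 - x0, 1.0 - y0)
    eps = 1e-12
    candidates: list[float] = []
    for k in range(n):
        # vertical boundary segment of row band k: x = c_k/m, y in [k/n, (k+1)/n]
        s = boundary[k] / m - x0
        y = y0 + s
        if k / n - eps <= y <= (k + 1) / n + eps and s_min - eps <= s <= s_max + eps:
            candidates.append(s)
        # horizontal connector at y = (k+1)/n between bands k and k+1
        if k + 1 < n and boundary[k] != boundary[k + 1]:
            s = (k + 1) / n - y0
            x = x0 + s
            lo, hi = boundary[k + 1] / m, boundary[k] / m
            if lo - eps <= x <= hi + eps and s_min - eps <= s <= s_max + eps:
                candidates.append(s)
    if candidates:
        s_cross = min(candidates, key=abs)
    else:
        # diagonal lies entirely on one side of the staircase
        s_cross = s_min if abs(s_min) > abs(s_max) else s_max
    d = math.sqrt(2.0) * abs(s_cross)
    big_d = math.sqrt(2.0) * (s_max - s_min)
    return d, big_d


def temperature(net: BipartiteNetwork) -> tuple[float, float]:
    """Atmar–Patterson temperature ``(T_AP, T)`` with ``T = 100 - T_AP``.

    The matrix is packed, the discrete isocline for its (n, m, E) is
    built, and every unexpected presence or absence contributes the
    squared relative displacement ``(d_ij / D_ij)**2`` measured along
    the unit-square diagonal through the cell.  A perfectly nested
    matrix has an empty unexpectedness set and hence ``T_AP = 0``.
    """
    if net.n_links == 0:
        raise UndefinedMetricError("temperature is undefined for an edgeless network")
    packed = pack(net)
    n, m = net.n_rows, net.n_cols
    ipn = ipn_boundary(n, m, net.n_links)
    cells = unexpectedness_set(packed, ipn)
    total = 0.0
    for i, j, _kind in cells:
        d, big_d = _diagonal_crossing(ipn.boundary, n, m, i, j)
        if big_d > 0:
            total += (d / big_d) ** 2
    t_ap = 100.0 / (U_MAX * n * m) * total
    t = min(100.0, max(0.0, 100.0 - t_ap))
    return t_ap, t


# ---------------------------------------------------------------------------
# Manhattan-distance index


def _manhattan_sum(matrix: np.ndarray) -> float:
    n, m = matrix.shape
    x = (np.arange(m) + 0.5) / m
    y = (np.arange(n) + 0.5) / n
    return float((matrix * (x[None, :] + y[:, None])).sum())


def nmd(net: BipartiteNetwork) -> tuple[float, float]:
    """Manhattan-distance index ``(tau, NMD)`` with ``NMD = 100 (1 - tau)``.

    ``tau = (d - d_nest) / (d_rand - d_nest)`` where ``d`` sums the
    unit-square Manhattan distances of the packed matrix's links,
    ``d_nest`` those of the perfectly nested reference with the same
    (n, m, E), and ``d_rand = E`` is the exact expectation under uniform
    placement of E links (each cell's mean coordinate sum is 1).
    """
    e = net.n_links
    if e == 0:
        raise UndefinedMetricError("tau is undefined for an edgeless network")
    n, m = net.n_rows, net.n_cols
    if e == n * m:
        raise UndefinedMetricError(
            "tau is undefined at complete fill: the random and nested "
            "references coincide"
        )
    d = _manhattan_sum(pack(net).matrix)
    d_nest = _manhattan_sum(canonical_nested(n, m, e).matrix)
    d_rand = float(e)
    tau = (d - d_nest) / (d_rand - d_nest)
    tau = min(1.0, max(0.0, tau))
    return tau, 100.0 * (1.0 - tau)


# ---------------------------------------------------------------------------
# overlap indices


def _overlap_terms(matrix: np.ndarray, penalize_ties: bool) -> float:
    """Sum over ordered pairs i<j (by decreasing degree) of
    overlap(i, j) / d_j, optionally suppressed when d_i == d_j."""
    degrees = matrix.sum(axis=1)
    order = np.argsort(-degrees, kind="stable")
    mat = matrix[order]
    deg = degrees[order]
    overlap = (mat @ mat.T).astype(float)
    total = 0.0
    k = mat.shape[0]
    for jj in range(1, k):
        if deg[jj] == 0:
            continue
        upper = overlap[:jj, jj]
        if penalize_ties:
            valid = deg[:jj] > deg[jj]
            total += float(upper[valid].sum()) / deg[jj]
        else:
            total += float(upper.sum()) / deg[jj]
    return total


def _k_norm(n: int, m: int) -> float:
    return (n * (n - 1) + m * (m - 1)) / 200.0


def nodf(net: BipartiteNetwork) -> float:
    """NODF: paired overlap with the decreasing-fill condition.

    A pair of rows (columns) contributes the fraction of the
    lower-degree member's links shared with the higher-degree member;
    pairs with equal degrees (or an empty lower member) contribute
    nothing, which is what makes the index penalize degree repetition.
    """
    n, m = net.n_rows, net.n_cols
    k = _k_norm(n, m)
    if k == 0:
        raise UndefinedMetricError("NODF needs at least two rows or two columns")
    total = _overlap_terms(net.matrix, penalize_ties=True)
    total += _overlap_terms(net.matrix.T, penalize_ties=True)
    return total / k


def stable_nodf(net: BipartiteNetwork) -> float:
    """stable-NODF: NODF without the decreasing-fill suppression, so
    tied degrees are not penalized."""
    n, m = net.n_rows, net.n_cols
    k = _k_norm(n, m)
    if k == 0:
        raise UndefinedMetricError("stable-NODF needs at least two rows or two columns")
    total = _overlap_terms(net.matrix, penalize_ties=False)
    total += _overlap_terms(net.matrix.T, penalize_ties=False)
    return total / k


# ---------------------------------------------------------------------------
# discrepancy


def discrepancy(net: BipartiteNetwork) -> tuple[float, float]:
    """Brualdi–Sanderson discrepancy ``(Delta, Delta')``.

    After packing, each row's nested template fills its ``d_i`` leftmost
    cells; Delta counts the 1-cells falling outside that template.  The
    normalized orientation is ``Delta' = 100 (1 - Delta/E)`` (division
    by E removes the gross fill dependence).  The count depends on the
    packed configuration; one deterministic packing is used, never an
    average over alternatives.
    """
    e = net.n_links
    if e == 0:
        raise UndefinedMetricError("discrepancy is undefined for an edgeless network")
    mat = pack(net).matrix
    degrees = mat.sum(axis=1)
    inside = sum(int(mat[i, : degrees[i]].sum()) for i in range(mat.shape[0]))
    delta = float(e - inside)
    return delta, 100.0 * (1.0 - delta / e)


# ---------------------------------------------------------------------------
# attack tolerance and NIR


@dataclass(frozen=True)
class AttackToleranceCurve:
    """Survival profile under sequential node removal.

    ``surviving_fraction[k]`` is the fraction of opposite-guild nodes
    that keep at least one link just before the (k+1)-th removal; the
    area is its left-Riemann sum, ``(1/N) * sum_k surviving_fraction[k]``.
    """

    removed_fraction: tuple[float, ...]
    surviving_fraction: tuple[float, ...]
    area: float


RemovalStrategy = Literal["DDR", "IDR"]


def _removal_order(degrees: np.ndarray, strategy: RemovalStrategy, rng: np.random.Generator) -> np.ndarray:
    tiebreak = rng.random(degrees.size)
    if strategy == "DDR":
        return np.lexsort((tiebreak, -degrees))
    if strategy == "IDR":
        return np.lexsort((tiebreak, degrees))
    raise ValueError(f"unknown strategy {strategy!r}")


def _atc_from_matrix(
    mat: np.ndarray, strategy: RemovalStrategy, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """ATC for ``mat`` oriented (survivor guild x removed guild)."""
    n_removed = mat.shape[1]
    order = _removal_order(mat.sum(axis=0), strategy, rng)
    position = np.empty(n_removed, dtype=np.int64)
    position[order] = np.arange(1, n_removed + 1)
    # a survivor dies when its last partner is removed
    death = (mat * position[None, :]).max(axis=1)
    ks = np.arange(n_removed)
    surviving = (death[:, None] > ks[None, :]).mean(axis=0)
    return surviving, float(surviving.mean())


def atc(
    net: BipartiteNetwork,
    removed_guild: Literal["rows", "cols"] = "cols",
    strategy: RemovalStrategy = "DDR",
    tie_seed: int = 0,
) -> AttackToleranceCurve:
    """Attack tolerance curve for one guild and one removal strategy.

    Nodes of ``removed_guild`` are deleted one at a time in decreasing
    (DDR) or increasing (IDR) degree order, degree ties permuted by
    ``tie_seed``.  The surviving fraction is taken over *all* nodes of
    the opposite guild, so initially isolated nodes count as dead from
    the start.
    """
    mat = net.matrix if removed_guild == "cols" else net.matrix.T
    rng = np.random.default_rng(tie_seed)
    surviving, area = _atc_from_matrix(mat, strategy, rng)
    n_removed = mat.shape[1]
    return AttackToleranceCurve(
        removed_fraction=tuple(k / n_removed for k in range(n_removed)),
        surviving_fraction=tuple(float(v) for v in surviving),
        area=area,
    )


def nir(net: BipartiteNetwork, n_orderings: int = 100, seed: int = 0) -> float:
    """Nestedness index based on network robustness.

    For each guild, the areas under the attack tolerance curves for the
    increasing- and decreasing-degree removal strategies are averaged
    over ``n_orderings`` random permutations of degree ties, and the
    guild's contribution is ``(R_IDR - R_DDR) / (1 - phi)``; the index
    is the mean over the two guilds.  Isolated nodes are dropped first
    and ``phi`` is the fill of the trimmed matrix: the robustness
    analysis concerns the interacting community, and this keeps the
    perfect-nested identity ``NIR = 1`` intact when the triangular
    reference leaves empty rows.
    """
    if net.n_links == 0:
        raise UndefinedMetricError("NIR is undefined for an edgeless network")
    trimmed = net.trimmed()
    phi = trimmed.fill
    if phi >= 1.0:
        raise UndefinedMetricError(
            "NIR is undefined at complete fill: the IDR and DDR curves coincide"
        )
    rng = np.random.default_rng(seed)
    contributions = []
    for mat in (trimmed.matrix, trimmed.matrix.T):
        r_idr = np.mean([_atc_from_matrix(mat, "IDR", rng)[1] for _ in range(n_orderings)])
        r_ddr = np.mean([_atc_from_matrix(mat, "DDR", rng)[1] for _ in range(n_orderings)])
        contributions.append((r_idr - r_ddr) / (1.0 - phi))
    return float(np.mean(contributions))


# ---------------------------------------------------------------------------
# spectral radius


def spectral_radius(net: BipartiteNetwork) -> float:
    """Largest singular value of the biadjacency matrix.

    Equals the spectral radius of the symmetric adjacency matrix of the
    full two-guild graph, and is invariant under any row or column
    permutation (no packing needed).
    """
    if net.n_links == 0:
        return 0.0
    return float(np.linalg.svd(net.matrix.astype(float), compute_uv=False)[0])


def normalized_spectral_radius(net: BipartiteNetwork) -> float:
    """``100 * rho / rho_max`` with ``rho_max`` from the perfectly
    nested reference of the same (n, m, E).

    The canonical reference is the maximizer up to rare tie-break
    effects; should the ratio exceed 100 it is reported unclamped with
    a warning.
    """
    if net.n_links == 0:
        raise UndefinedMetricError(
            "normalized spectral radius is undefined for an edgeless network"
        )
    rho = spectral_radius(net)
    rho_max = spectral_radius(canonical_nested(net.n_rows, net.n_cols, net.n_links))
    value = 100.0 * rho / rho_max
    if value > 100.0 + 1e-9:
        # static message so repeated ensemble evaluations dedup to one report
        warnings.warn(
            "normalized spectral radius exceeds 100: the nested reference "
            "is not the exact spectral-radius maximizer for every (n, m, E); "
            "the value is reported unclamped",
            stacklevel=2,
        )
    return value


# ---------------------------------------------------------------------------
# aggregation


METRIC_NAMES = (
    "temperature",
    "nmd",
    "nodf",
    "stable_nodf",
    "discrepancy",
    "nir",
    "spectral_radius",
    "rho_norm",
)


@dataclass(frozen=True)
class MetricConfig:
    """Options shared by the batch metric computations."""

    metrics: tuple[str, ...] = METRIC_NAMES
    nir_orderings: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.metrics) - set(METRIC_NAMES)
        if unknown:
            raise ValueError(f"unknown metrics: {sorted(unknown)}")


@dataclass(frozen=True)
class MetricEntry:
    name: str
    raw_value: float | None
    transformed_value: float | None
    defined: bool
    note: str = ""


@dataclass(frozen=True)
class MetricReport:
    """Named index values (raw + 0-100 orientation) for one network."""

    entries: dict[str, MetricEntry]

    def __getitem__(self, name: str) -> MetricEntry:
        return self.entries[name]

    def to_dict(self) -> dict:
        return {
            name: {
                "raw_value": e.raw_value,
                "transformed_value": e.transformed_value,
                "defined": e.defined,
                "note": e.note,
            }
            for name, e in self.entries.items()
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "MetricReport":
        payload = json.loads(text)
        return cls(
            entries={
                name: MetricEntry(
                    name=name,
                    raw_value=d["raw_value"],
                    transformed_value=d["transformed_value"],
                    defined=d["defined"],
                    note=d.get("note", ""),
                )
                for name, d in payload.items()
            }
        )

    def to_csv_row(self) -> dict[str, float | str | None]:
        """Flat one-row mapping for batch concatenation."""
        row: dict[str, float | str | None] = {}
        for name, e in self.entries.items():
            row[f"{name}_raw"] = e.raw_value if e.defined else None
            row[f"{name}_transformed"] = e.transformed_value if e.defined else None
        return row


def _entry(name: str, fn: Callable[[], tuple[float | None, float | None, str]]) -> MetricEntry:
    try:
        raw, transformed, note = fn()
    except UndefinedMetricError as exc:
        return MetricEntry(name, None, None, defined=False, note=str(exc))
    return MetricEntry(name, raw, transformed, defined=True, note=note)


def compute_all(net: BipartiteNetwork, config: MetricConfig | None = None) -> MetricReport:
    """All requested indices for one network, undefined cases flagged."""
    cfg = config or MetricConfig()
    builders: dict[str, Callable[[], tuple[float | None, float | None, str]]] = {
        "temperature": lambda: (*temperature(net), "raw T_AP; transformed T = 100 - T_AP"),
        "nmd": lambda: (*nmd(net), "raw tau; transformed NMD = 100 (1 - tau)"),
        "nodf": lambda: ((v := nodf(net)), v, "already on the 0-100 scale"),
        "stable_nodf": lambda: ((v := stable_nodf(net)), v, "already on the 0-100 scale"),
        "discrepancy": lambda: (
            *discrepancy(net),
            "raw Delta; transformed Delta' = 100 (1 - Delta/E)",
        ),
        "nir": lambda: (
            (v := nir(net, n_orderings=cfg.nir_orderings, seed=cfg.seed)),
            100.0 * v,
            "raw in [~0, 1]; transformed x100",
        ),
        "spectral_radius": lambda: (spectral_radius(net), None, "unnormalized"),
        "rho_norm": lambda: ((v := normalized_spectral_radius(net)), v, "100 rho / rho_max"),
    }
    return MetricReport(
        entries={name: _entry(name, builders[name]) for name in cfg.metrics}
    )


def metric_value(name: str, net: BipartiteNetwork, config: MetricConfig | None = None) -> float:
    """The headline scalar of one index, as used for ensemble z-scores.

    Bounded indices are reported on their 0-100 "larger = more nested"
    orientation; NIR and the raw spectral radius on their native scale.
    Raises :class:`UndefinedMetricError` where the index is undefined.
    """
    cfg = config or MetricConfig()
    if name == "temperature":
        return temperature(net)[1]
    if name == "nmd":
        return nmd(net)[1]
    if name == "nodf":
        return nodf(net)
    if name == "stable_nodf":
        return stable_nodf(net)
    if name == "discrepancy":
        return discrepancy(net)[1]
    if name == "nir":
        return nir(net, n_orderings=cfg.nir_orderings, seed=cfg.seed)
    if name == "spectral_radius":
        return spectral_radius(net)
    if name == "rho_norm":
        return normalized_spectral_radius(net)
    raise ValueError(f"unknown metric {name!r}")
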