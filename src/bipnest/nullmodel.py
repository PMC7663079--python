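"""Maximum-entropy / maximum-likelihood null ensemble (bipartite
configuration model).

The ensemble maximizes Shannon entropy subject to the two degree
sequences being preserved *on average*; the resulting exponential
random-graph family factorizes over pairs, with link probabilities

    p_ij = x_i * y_j / (1 + x_i * y_j)

where the non-negative Lagrange multipliers ``x_i`` (one per row) and
``y_j`` (one per column) are fixed by maximizing the likelihood of the
observed degree sequences — equivalently, by solving the moment
equations ``sum_j p_ij = d_i`` and ``sum_i p_ij = e_j``.

Structurally forced nodes (degree zero, or degree equal to the whole
opposite guild) are clamped to p = 0 / p = 1 analytically before
solving, cascading until the residual system is interior.  The interior
system is reduced to its distinct degree classes and solved by a damped
fixed-point iteration, repeated from several starting points which must
agree on the expected degrees.

Sampling the ensemble draws each cell as an independent Bernoulli;
samples may therefore contain zero-degree nodes, which the data model
and the metrics tolerate by contract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy import optimize

from .metrics import METRIC_NAMES, MetricConfig, UndefinedMetricError, metric_value
from .network import BipartiteNetwork

__all__ = [
    "SolverError",
    "LagrangeMultipliers",
    "ProbabilityMatrix",
    "EnsembleMetricStat",
    "EnsembleSummary",
    "fit_bicm",
    "loglikelihood",
    "sample",
    "ensemble_metrics",
]


class SolverError(RuntimeError):
    """The likelihood equations could not be solved to tolerance."""


@dataclass(frozen=True)
class LagrangeMultipliers:
    """Fitted multipliers plus structural-clamp bookkeeping.

    ``row_params`` / ``col_params`` hold finite multipliers for free
    nodes and NaN for clamped ones; the clamp status is carried in
    ``row_status`` / ``col_status`` (``free`` / ``empty`` /
    ``saturated``) and the per-cell forced probabilities in ``forced``
    (-1 where the pair is governed by the multipliers).
    """

    row_params: np.ndarray
    col_params: np.ndarray
    row_status: tuple[str, ...]
    col_status: tuple[str, ...]
    forced: np.ndarray

    def probabilities(self) -> np.ndarray:
        """Rebuild the full probability matrix p_ij."""
        x = np.nan_to_num(self.row_params, nan=0.0)
        y = np.nan_to_num(self.col_params, nan=0.0)
        xy = np.outer(x, y)
        probs = xy / (1.0 + xy)
        mask = self.forced >= 0
        probs[mask] = self.forced[mask]
        return probs

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {
                "row_params": [None if np.isnan(v) else float(v) for v in self.row_params],
                "col_params": [None if np.isnan(v) else float(v) for v in self.col_params],
                "row_status": list(self.row_status),
                "col_status": list(self.col_status),
            },
            **kwargs,
        )


@dataclass(frozen=True)
class ProbabilityMatrix:
    """Per-pair connection probabilities of the fitted ensemble."""

    probs: np.ndarray
    multipliers: LagrangeMultipliers
    residual: float

    @property
    def shape(self) -> tuple[int, int]:
        return self.probs.shape

    def expected_row_degrees(self) -> np.ndarray:
        return self.probs.sum(axis=1)

    def expected_col_degrees(self) -> np.ndarray:
        return self.probs.sum(axis=0)

    def save_csv(self, path) -> None:
        np.savetxt(path, self.probs, delimiter=",", fmt="%.12g")


class _BlockState:
    """Mutable global state shared by the recursive block solver."""

    def __init__(self, n: int, m: int, tol: float, max_iter: int,
                 noise_rng: np.random.Generator | None):
        self.forced = np.full((n, m), -1, dtype=np.int8)
        self.x = np.full(n, np.nan)
        self.y = np.full(m, np.nan)
        self.row_status = ["free"] * n
        self.col_status = ["free"] * m
        self.tol = tol
        self.max_iter = max_iter
        self.noise_rng = noise_rng
        self.ok = True


def _cascade_block(state: _BlockState, rows: np.ndarray, cols: np.ndarray,
                   r: np.ndarray, c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-node clamps within one block, iterated to a fixed point.

    A node with residual degree 0 forces zeros across the block's free
    part; one whose residual degree equals the free opposite-guild size
    forces ones.  Returns the local free masks; residual degrees are
    updated in place.
    """
    row_free = np.ones(rows.size, dtype=bool)
    col_free = np.ones(cols.size, dtype=bool)
    changed = True
    while changed:
        changed = False
        n_free_cols = int(col_free.sum())
        for a in np.flatnonzero(row_free):
            if r[a] == 0:
                state.forced[rows[a], cols[col_free]] = 0
                row_free[a] = False
                state.row_status[rows[a]] = "empty"
                changed = True
            elif r[a] == n_free_cols:
                state.forced[rows[a], cols[col_free]] = 1
                c[col_free] -= 1
                row_free[a] = False
                state.row_status[rows[a]] = "saturated"
                changed = True
        n_free_rows = int(row_free.sum())
        for b in np.flatnonzero(col_free):
            if c[b] == 0:
                state.forced[rows[row_free], cols[b]] = 0
                col_free[b] = False
                state.col_status[cols[b]] = "empty"
                changed = True
            elif c[b] == n_free_rows:
                state.forced[rows[row_free], cols[b]] = 1
                r[row_free] -= 1
                col_free[b] = False
                state.col_status[cols[b]] = "saturated"
                changed = True
    return row_free, col_free


def _tight_prefix(r_sorted: np.ndarray, c: np.ndarray) -> int | None:
    """Smallest k (1 <= k < #rows) at which the Gale-Ryser bound
    ``sum_{i<=k} r_i <= sum_j min(c_j, k)`` holds with equality.

    Such an equality puts the degree sequence on a face of the margin
    polytope: the top-k rows must fill every column of degree >= k, and
    the remaining rows must avoid every column of degree < k.  After
    the per-node cascade the minimal tight k always falls on a strict
    degree step, so the split is unambiguous.
    """
    partial = 0
    for k in range(1, r_sorted.size):
        partial += int(r_sorted[k - 1])
        bound = int(np.minimum(c, k).sum())
        if partial == bound:
            return k
    return None


def _solve_block(state: _BlockState, rows: np.ndarray, cols: np.ndarray,
                 r: np.ndarray, c: np.ndarray) -> None:
    """Solve one independent subsystem, recursing on polytope faces."""
    if not state.ok:
        return
    row_free, col_free = _cascade_block(state, rows, cols, r, c)
    if not row_free.any() or not col_free.any():
        return
    f_rows = rows[row_free]
    f_cols = cols[col_free]
    rf = r[row_free]
    cf = c[col_free]

    order = np.argsort(-rf, kind="stable")
    k = _tight_prefix(rf[order], cf)
    if k is not None:
        top = order[:k]
        rest = order[k:]
        in_b = cf >= k
        # forced blocks: top-k rows fill the high-degree columns; the
        # remaining rows avoid the low-degree columns entirely
        state.forced[np.ix_(f_rows[top], f_cols[in_b])] = 1
        state.forced[np.ix_(f_rows[rest], f_cols[~in_b])] = 0
        _solve_block(state, f_rows[top], f_cols[~in_b],
                     rf[top] - int(in_b.sum()), cf[~in_b])
        _solve_block(state, f_rows[rest], f_cols[in_b],
                     rf[rest], cf[in_b] - k)
        return

    # interior system: reduce to degree classes and solve
    d_r, inv_r = np.unique(rf.astype(float), return_inverse=True)
    w_r = np.bincount(inv_r).astype(float)
    d_c, inv_c = np.unique(cf.astype(float), return_inverse=True)
    w_c = np.bincount(inv_c).astype(float)
    scale = np.sqrt(rf.sum()) if rf.sum() > 0 else 1.0
    x0 = d_r / scale
    y0 = d_c / scale
    if state.noise_rng is not None:
        x0 = x0 * state.noise_rng.lognormal(0.0, 1.0, size=d_r.size)
        y0 = y0 * state.noise_rng.lognormal(0.0, 1.0, size=d_c.size)
    x0 = np.clip(x0, 1e-10, None)
    y0 = np.clip(y0, 1e-10, None)
    x, y, residual, ok = _reduced_fixed_point(
        d_r, w_r, d_c, w_c, x0, y0, tol=state.tol, max_iter=state.max_iter
    )
    if not ok:
        state.ok = False
        state.last_residual = residual
        return
    state.x[f_rows] = x[inv_r]
    state.y[f_cols] = y[inv_c]


def _class_probs(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    xy = np.outer(x, y)
    return xy / (1.0 + xy)


def _class_residual(
    x: np.ndarray, y: np.ndarray, d_r, w_r, d_c, w_c
) -> float:
    p = _class_probs(x, y)
    res_r = np.abs((w_c * p).sum(axis=1) - d_r).max() if d_r.size else 0.0
    res_c = np.abs((w_r[:, None] * p).sum(axis=0) - d_c).max() if d_c.size else 0.0
    return float(max(res_r, res_c))


def _reduced_fixed_point(
    d_r: np.ndarray,
    w_r: np.ndarray,
    d_c: np.ndarray,
    w_c: np.ndarray,
    x0: np.ndarray,
    y0: np.ndarray,
    tol: float,
    max_iter: int,
    damping: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Solve the class-level moment equations.

    ``d_r`` are distinct residual row degrees with multiplicities
    ``w_r`` (likewise columns).  A Newton root search on the
    log-multipliers does the heavy lifting (the moment equations are
    smooth and the class system small); the classical likelihood fixed
    point ``x_r <- d_r / sum_c w_c y_c / (1 + x_r y_c)``, damped,
    serves as warm-up and as fallback when the root search stalls —
    near-threshold degree sequences push multipliers toward 0/infinity,
    where plain iteration converges only slowly.
    """
    x = x0.copy()
    y = y0.copy()
    # damped fixed-point warm-up to reach Newton's basin
    for _ in range(50):
        xy = np.outer(x, y)
        x_new = d_r / ((w_c * y) / (1.0 + xy)).sum(axis=1)
        x = damping * x + (1.0 - damping) * x_new
        xy = np.outer(x, y)
        y_new = d_c / ((w_r[:, None] * x[:, None]) / (1.0 + xy)).sum(axis=0)
        y = damping * y + (1.0 - damping) * y_new

    r, c = d_r.size, d_c.size

    def fun_jac(theta: np.ndarray):
        xx = np.exp(theta[:r])
        yy = np.exp(theta[r:])
        p = _class_probs(xx, yy)
        q = p * (1.0 - p)  # dp/dlog-multiplier, either side
        f = np.concatenate(
            [(w_c * p).sum(axis=1) - d_r, (w_r[:, None] * p).sum(axis=0) - d_c]
        )
        jac = np.zeros((r + c, r + c))
        jac[:r, :r] = np.diag((w_c * q).sum(axis=1))
        jac[:r, r:] = w_c * q
        jac[r:, :r] = (w_r[:, None] * q).T
        jac[r:, r:] = np.diag((w_r[:, None] * q).sum(axis=0))
        return f, jac

    theta0 = np.log(np.clip(np.concatenate([x, y]), 1e-300, None))
    sol = optimize.root(fun_jac, theta0, jac=True, method="hybr")
    if sol.success:
        cand_x = np.exp(sol.x[:r])
        cand_y = np.exp(sol.x[r:])
        if _class_residual(cand_x, cand_y, d_r, w_r, d_c, w_c) <= tol:
            x, y = cand_x, cand_y
            return x, y, _class_residual(x, y, d_r, w_r, d_c, w_c), True

    # fallback: keep iterating the damped fixed point
    residual = np.inf
    for _ in range(max_iter):
        xy = np.outer(x, y)
        x_new = d_r / ((w_c * y) / (1.0 + xy)).sum(axis=1)
        x = damping * x + (1.0 - damping) * x_new
        xy = np.outer(x, y)
        y_new = d_c / ((w_r[:, None] * x[:, None]) / (1.0 + xy)).sum(axis=0)
        y = damping * y + (1.0 - damping) * y_new
        residual = _class_residual(x, y, d_r, w_r, d_c, w_c)
        if residual <= tol:
            return x, y, residual, True
    return x, y, residual, False


def fit_bicm(
    net: BipartiteNetwork,
    tol: float | None = None,
    max_iter: int = 5000,
    n_starts: int = 8,
    seed: int = 0,
) -> tuple[LagrangeMultipliers, ProbabilityMatrix]:
    """Fit the degree-preserving maximum-entropy ensemble to a network.

    Returns the multipliers and the probability matrix whose row and
    column sums reproduce the observed degrees within ``tol`` (default
    ``1e-8 * max(n, m)``).  The solver runs from ``n_starts`` initial
    conditions (one heuristic, the rest seeded random); all converged
    starts must agree on the expected degrees within ``10 * tol``.
    """
    n, m = net.n_rows, net.n_cols
    if tol is None:
        tol = 1e-8 * max(n, m)
    row_deg = net.row_degrees()
    col_deg = net.col_degrees()

    rng = np.random.default_rng(seed)
    candidates: list[LagrangeMultipliers] = []
    best_residual = np.inf
    for start in range(n_starts):
        state = _BlockState(
            n, m, tol=tol, max_iter=max_iter,
            noise_rng=None if start == 0 else rng,
        )
        _solve_block(
            state,
            np.arange(n), np.arange(m),
            row_deg.astype(np.int64).copy(), col_deg.astype(np.int64).copy(),
        )
        if state.ok:
            candidates.append(
                LagrangeMultipliers(
                    row_params=state.x,
                    col_params=state.y,
                    row_status=tuple(state.row_status),
                    col_status=tuple(state.col_status),
                    forced=state.forced,
                )
            )
        else:
            best_residual = min(best_residual, getattr(state, "last_residual", np.inf))
    if not candidates:
        raise SolverError(
            f"likelihood equations did not converge in {max_iter} iterations "
            f"from any of {n_starts} starts; best residual "
            f"{best_residual:.3e} (tol {tol:.3e})"
        )

    def expected(mult: LagrangeMultipliers) -> np.ndarray:
        p = mult.probabilities()
        return np.concatenate([p.sum(axis=1), p.sum(axis=0)])

    mult = candidates[0]
    ref = expected(mult)
    for other in candidates[1:]:
        if np.abs(expected(other) - ref).max() > 10.0 * tol:
            raise SolverError(
                "multi-start solutions disagree on expected degrees beyond "
                f"10*tol={10 * tol:.3e}; the likelihood surface may be "
                "ill-conditioned for this degree sequence"
            )

    probs = mult.probabilities()
    residual = max(
        np.abs(probs.sum(axis=1) - row_deg).max(),
        np.abs(probs.sum(axis=0) - col_deg).max(),
    )
    if residual > 10.0 * tol:
        raise SolverError(
            f"final probability matrix misses the observed degrees by "
            f"{residual:.3e} (tol {tol:.3e})"
        )
    return mult, ProbabilityMatrix(probs=probs, multipliers=mult, residual=float(residual))


def loglikelihood(net: BipartiteNetwork, mult: LagrangeMultipliers) -> float:
    """Bernoulli log-likelihood of the observed matrix under the model.

    Cells whose probability is exactly the observed value contribute
    ``log 1 = 0``; an impossible observation (p = 0 with a link, or
    p = 1 without) yields ``-inf``.
    """
    probs = mult.probabilities()
    b = net.matrix.astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(b > 0, np.log(probs), np.log1p(-probs))
    if np.isnan(terms).any():
        return float("-inf")
    return float(terms.sum())


def sample(
    P: ProbabilityMatrix | np.ndarray,
    n_samples: int,
    seed: int = 0,
) -> Iterator[BipartiteNetwork]:
    """Draw independent networks from the ensemble.

    Each cell is an independent Bernoulli(p_ij).  The master seed
    spawns one substream per sample, so sample ``k`` is reproducible
    regardless of how many samples are drawn in total.
    """
    probs = P.probs if isinstance(P, ProbabilityMatrix) else np.asarray(P)
    master = np.random.SeedSequence(seed)
    for child in master.spawn(n_samples):
        rng = np.random.default_rng(child)
        matrix = (rng.random(probs.shape) < probs).astype(np.int8)
        yield BipartiteNetwork(matrix)


@dataclass(frozen=True)
class EnsembleMetricStat:
    """Mean, spread and z-score of one index over the null ensemble."""

    real_value: float | None
    mean: float | None
    std: float | None
    z_score: float | None
    n_samples: int
    n_undefined: int
    note: str = ""


@dataclass(frozen=True)
class EnsembleSummary:
    metrics: dict[str, EnsembleMetricStat]
    n_samples: int
    seed: int
    mean_fill: float
    mean_zero_degree_nodes: float

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "seed": self.seed,
            "diagnostics": {
                "mean_fill": self.mean_fill,
                "mean_zero_degree_nodes": self.mean_zero_degree_nodes,
            },
            "metrics": {
                name: {
                    "real_value": s.real_value,
                    "mean": s.mean,
                    "std": s.std,
                    "z_score": s.z_score,
                    "n_samples": s.n_samples,
                    "n_undefined": s.n_undefined,
                    "note": s.note,
                }
                for name, s in self.metrics.items()
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def ensemble_metrics(
    net: BipartiteNetwork,
    P: ProbabilityMatrix,
    metric_names: Sequence[str] = METRIC_NAMES,
    n_samples: int = 10_000,
    seed: int = 0,
    config: MetricConfig | None = None,
) -> EnsembleSummary:
    """Sample the ensemble and z-score the observed index values.

    Samples for which an index is undefined are excluded from that
    index's statistics and counted.  ``z = (real - mean)/std`` with the
    sample standard deviation (denominator ``n - 1``); a zero std or an
    undefined real value flags the z-score as undefined instead of
    propagating NaN or infinity.
    """
    cfg = config or MetricConfig(metrics=tuple(metric_names))
    values: dict[str, list[float]] = {name: [] for name in metric_names}
    undefined: dict[str, int] = {name: 0 for name in metric_names}
    fills: list[float] = []
    zero_nodes: list[int] = []
    for draw in sample(P, n_samples, seed=seed):
        fills.append(draw.fill)
        zero_nodes.append(
            int((draw.row_degrees() == 0).sum() + (draw.col_degrees() == 0).sum())
        )
        for name in metric_names:
            try:
                values[name].append(metric_value(name, draw, cfg))
            except UndefinedMetricError:
                undefined[name] += 1

    stats: dict[str, EnsembleMetricStat] = {}
    for name in metric_names:
        vals = np.asarray(values[name], dtype=float)
        try:
            real = metric_value(name, net, cfg)
        except UndefinedMetricError as exc:
            real = None
            real_note = str(exc)
        else:
            real_note = ""
        if vals.size == 0:
            stats[name] = EnsembleMetricStat(
                real_value=real,
                mean=None,
                std=None,
                z_score=None,
                n_samples=0,
                n_undefined=undefined[name],
                note="undefined on every sample",
            )
            continue
        mean = float(vals.mean())
        std = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        if real is None:
            z, note = None, real_note or "real value undefined"
        elif std > 0:
            z, note = (real - mean) / std, ""
        else:
            z, note = None, "zero ensemble spread: z-score undefined"
        stats[name] = EnsembleMetricStat(
            real_value=real,
            mean=mean,
            std=std,
            z_score=z,
            n_samples=int(vals.size),
            n_undefined=undefined[name],
            note=note,
        )
    return EnsembleSummary(
        metrics=stats,
        n_samples=n_samples,
        seed=seed,
        mean_fill=float(np.mean(fills)),
        mean_zero_degree_nodes=float(np.mean(zero_nodes)),
    )
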