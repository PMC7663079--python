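"""Seeded generators of bipartite networks for testing and simulation.

Three families cover the structural range the analyses need:

* ``gen_perfect_nested`` — the perfectly nested reference (staircase);
* ``gen_bernoulli`` — i.i.d. Bernoulli fill, the unstructured baseline;
* ``gen_noisy_nested`` — the nested reference degraded by random
  checkerboard swaps.  A swap replaces a 2x2 submatrix [[1,0],[0,1]] by
  [[0,1],[1,0]] (or vice versa) and therefore preserves both degree
  sequences exactly, so nestedness varies while the degree-sequence
  null model's fit target stays constant.

``fixture_battery`` crosses sizes, fills, eccentricities and noise
levels into a reproducible collection of networks standing in for a
survey of real mutualistic webs; it does not emulate phylogenetic or
spatial structure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .network import BipartiteNetwork, ValidationError, descriptors, write_matrix
from .packing import canonical_nested

__all__ = [
    "gen_perfect_nested",
    "gen_bernoulli",
    "gen_noisy_nested",
    "fixture_battery",
    "export_battery",
]


def gen_perfect_nested(n: int, m: int, e: int) -> BipartiteNetwork:
    """Perfectly nested matrix of shape (n, m) with E links."""
    return canonical_nested(n, m, e)


def gen_bernoulli(n: int, m: int, fill: float, seed: int = 0) -> BipartiteNetwork:
    """Random matrix with i.i.d. Bernoulli(fill) cells."""
    if not 0.0 <= fill <= 1.0:
        raise ValidationError(f"fill {fill} outside [0, 1]")
    rng = np.random.default_rng(seed)
    matrix = (rng.random((n, m)) < fill).astype(np.int8)
    return BipartiteNetwork(matrix)


def _attempt_swap(matrix: np.ndarray, rng: np.random.Generator) -> bool:
    """One checkerboard-swap attempt; True if a swap was performed.

    Two distinct rows are drawn and one column is drawn from each side
    of their support symmetric difference, which samples a checkerboard
    whenever the two rows are not mutually nested.  The swap flips the
    2x2 checkerboard and leaves both degree sequences untouched.
    """
    n = matrix.shape[0]
    i1, i2 = rng.choice(n, size=2, replace=False)
    r1, r2 = matrix[i1], matrix[i2]
    only1 = np.flatnonzero(r1 & ~r2)
    only2 = np.flatnonzero(~r1 & r2)
    if only1.size == 0 or only2.size == 0:
        return False
    j1 = int(only1[rng.integers(only1.size)])
    j2 = int(only2[rng.integers(only2.size)])
    matrix[i1, j1], matrix[i1, j2] = 0, 1
    matrix[i2, j1], matrix[i2, j2] = 1, 0
    return True


def _plant_defect(matrix: np.ndarray) -> None:
    """Relocate the outermost staircase link to the far empty corner.

    A perfectly nested matrix contains no 2x2 checkerboard (row
    supports are totally ordered by inclusion), so its degree sequence
    is uniquely realizable and degree-preserving swaps have nothing to
    act on.  One link moved from the staircase boundary to the
    highest-cost empty cell breaks that rigidity while leaving the
    matrix one relocation away from perfect nestedness.
    """
    n, m = matrix.shape
    ones = np.argwhere(matrix == 1)
    zeros = np.argwhere(matrix == 0)
    cost = lambda ij: (ij[:, 1] + 0.5) / m + (ij[:, 0] + 0.5) / n
    src = ones[np.argmax(cost(ones))]
    dst = zeros[np.argmax(cost(zeros))]
    matrix[tuple(src)] = 0
    matrix[tuple(dst)] = 1


def gen_noisy_nested(
    n: int, m: int, e: int, n_swaps: int, seed: int = 0
) -> BipartiteNetwork:
    """Nested reference degraded by ``n_swaps`` checkerboard swap attempts.

    ``n_swaps = 0`` returns the canonical nested matrix itself.  For
    ``n_swaps > 0`` a single deterministic defect link is planted first
    (see :func:`_plant_defect`) — without it no swap could ever fire —
    and then ``n_swaps`` seeded swap attempts are applied; a failed
    attempt (the sampled row pair is nested) is skipped.  All noisy
    levels of a given (n, m, E) therefore share one degree sequence,
    which is what lets the noise level vary nestedness while the
    degree-sequence null model's fit target stays constant.
    """
    if n < 2 or m < 2:
        raise ValidationError("checkerboard swaps need at least a 2x2 matrix")
    matrix = np.array(canonical_nested(n, m, e).matrix)
    if n_swaps > 0 and 0 < e < n * m:
        _plant_defect(matrix)
        rng = np.random.default_rng(seed)
        for _ in range(n_swaps):
            _attempt_swap(matrix, rng)
    return BipartiteNetwork(matrix)


_BATTERY_SIZES = (20, 40, 80, 120, 200)
_BATTERY_ECCENTRICITIES = (0.0, 0.3, 0.6)
_BATTERY_FILLS = (0.05, 0.15, 0.3, 0.5)
# noise levels as checkerboard-swap attempts relative to E: pristine,
# moderately degraded, heavily randomized
_BATTERY_SWAP_FACTORS = (0.0, 0.5, 5.0)


def fixture_battery(seed: int = 0) -> tuple[dict[str, BipartiteNetwork], pd.DataFrame]:
    """A reproducible spread of 60 networks for survey-style analyses.

    Crosses sizes 20-200 nodes, matrix fills 0.05-0.5 and
    eccentricities 0-0.6; the three checkerboard-noise levels cycle
    through the grid so each (size, eccentricity, fill) cell appears at
    one nestedness level.  Returns the networks keyed by name and a
    descriptor table (one row per network).
    """
    rng = np.random.default_rng(seed)
    networks: dict[str, BipartiteNetwork] = {}
    records = []
    k = 0
    for s in _BATTERY_SIZES:
        for ecc in _BATTERY_ECCENTRICITIES:
            for fill in _BATTERY_FILLS:
                n = round(s * (1 + ecc) / 2)
                m = s - n
                e = max(1, round(fill * n * m))
                factor = _BATTERY_SWAP_FACTORS[k % len(_BATTERY_SWAP_FACTORS)]
                n_swaps = round(factor * e)
                sub_seed = int(rng.integers(0, 2**31 - 1))
                net = gen_noisy_nested(n, m, e, n_swaps=n_swaps, seed=sub_seed)
                name = f"net{k:03d}_s{s}_e{ecc:.1f}_f{fill:.2f}_w{n_swaps}"
                networks[name] = net
                desc = descriptors(net)
                records.append(
                    {
                        "name": name,
                        "n": n,
                        "m": m,
                        "E": net.n_links,
                        "n_swaps": n_swaps,
                        "size_s": desc.size_s,
                        "fill_matrix": desc.fill_matrix,
                        "links_per_node": desc.links_per_node,
                        "eccentricity": desc.eccentricity,
                        "degeneracy_g": desc.degeneracy_g,
                    }
                )
                k += 1
    table = pd.DataFrame.from_records(records).set_index("name")
    # the design must not confound the descriptors: no pair may be in
    # perfect rank lockstep
    for a, b in (("size_s", "links_per_node"), ("size_s", "eccentricity"),
                 ("links_per_node", "eccentricity")):
        rho = table[a].corr(table[b], method="spearman")
        if abs(rho) >= 1.0:
            raise RuntimeError(f"degenerate battery: {a} and {b} are rank-identical")
    return networks, table


def export_battery(
    networks: dict[str, BipartiteNetwork],
    table: pd.DataFrame,
    out_dir: str | Path,
) -> None:
    """Write a battery as a directory of matrix CSVs plus descriptors.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, net in networks.items():
        write_matrix(net, out / f"{name}.csv")
    table.to_csv(out / "descriptors.csv")
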