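# Methods

`bipnest` measures nestedness in binary bipartite networks and tests its
significance against a maximum-entropy null ensemble that preserves both
degree sequences on average. This note records the models, the numerical
choices, and what the synthetic test bed does and does not establish.

## Data model

A network is an `n x m` biadjacency matrix `B` with `b_ij = 1` iff
row-node `i` (one guild, e.g. plants) interacts with column-node `j`
(the other guild, e.g. pollinators). Inputs may carry weights; any
positive value is read as presence. Zero-degree rows and columns are
retained: null-ensemble samples routinely disconnect nodes, and every
index must tolerate them.

Four structural descriptors feed the dependency analyses: size
`s = n + m`; two fill conventions kept under distinct names —
`fill_matrix = E/(n·m)` (the density of contacts used by the indices,
e.g. in the NIR normalization, where it is the only convention for
which the perfect-nested identity holds) and `links_per_node = E/(n+m)`
(the regression covariate); eccentricity `ε = |n − m|/(n + m)` (the
magnitude, since the quantity measures deviation from squareness); and
degree degeneracy `g` = the fraction of nodes whose degree value is
shared with at least one other node *of the same guild* — cross-guild
coincidences are not counted, a convention that is monotone in
repetition and bounded in [0, 1].

## Packing and the nested reference

Most indices are defined on the *maximally packed* matrix: rows and
columns reordered by non-increasing degree. Packing is deterministic:
sort by decreasing degree, break ties by decreasing sum of the packed
ranks of a node's partners, then by original index, alternating guilds
until stable (capped at 100 passes). No stochastic packing search is
used; the discrepancy index in particular is reported for this single
packing, never averaged over alternatives.

The *perfectly nested reference* for `(n, m, E)` maps cell centers into
the unit square, `x_j = (j − 1/2)/m`, `y_i = (i − 1/2)/n`, and fills
the `E` cells of smallest Manhattan cost `x_j + y_i` (ties: smaller row,
then smaller column, decided in exact integer arithmetic). The result
is always a staircase: each row's support is a prefix, with
non-increasing lengths `c_i`, `Σ c_i = E`.

The isocline of perfect nestedness (IPN) is defined *discretely* as
that staircase boundary. An analytic isocline family exists in the
literature but pins down a geometry we would otherwise have to guess
at; the discrete construction is parameter-free and guarantees that a
perfectly nested matrix has an empty unexpectedness set, hence
temperature exactly zero — the property the temperature's designers
intended. Published temperatures from packing-optimizing
implementations will therefore not be matched digit for digit.

## The eight indices

* **Temperature** `T_AP`: after packing, every unexpected presence
  (1 outside the staircase) or absence (0 inside it) contributes
  `(d/D)²`, where `d` is the distance from the cell center to the
  nearest crossing of the slope-+1 diagonal through the cell with the
  staircase, and `D` the full chord of that diagonal inside the unit
  square. If the diagonal never meets the staircase the far chord end
  is used (maximal displacement). `T_AP = 100/(U_max·n·m)·Σ(d/D)²`
  with `U_max = 0.04145`, the constant of the original implementation;
  it only rescales the index. Reported alongside `T = 100 − T_AP`,
  clamped to [0, 100] (tiny matrices can push `T_AP` past 100).
* **Manhattan-distance index** `τ = (d − d_nest)/(d_rand − d_nest)`,
  with `d` the Manhattan-cost sum of the packed matrix's links,
  `d_nest` that of the nested reference, and `d_rand = E` — the *exact*
  expectation under uniform placement of `E` links, since the mean cell
  cost over the whole unit square is 1. Using the closed form rather
  than Monte-Carlo removes sampling noise from a normalization
  constant; a sampling cross-check lives in the tests. Undefined at
  complete fill, where nested and random references coincide.
  Reported with `NMD = 100(1 − τ)`.
* **NODF**: for each ordered pair (higher-degree, lower-degree) of rows
  the shared-partner fraction `overlap/d_lower`, zeroed when the two
  degrees are equal (the "decreasing fill" condition — equal degrees
  annihilate the pair, which is what makes NODF penalize degree
  repetition) or when the lower degree is 0; same for columns;
  normalized by `K = [n(n−1) + m(m−1)]/200`.
* **stable-NODF**: identical but without the equal-degree suppression.
* **Discrepancy** `Δ`: after packing, the number of 1s falling outside
  each row's `d_i` leftmost cells; `Δ' = 100(1 − Δ/E)` normalizes away
  the gross fill dependence.
* **NIR** (robustness-based): nodes of one guild are removed one at a
  time in increasing (IDR) or decreasing (DDR) degree order; the attack
  tolerance curve records the fraction of opposite-guild nodes still
  holding a link before each removal, and its left-Riemann area gives
  `R_IDR`, `R_DDR`. Per guild, `NIR = (R_IDR − R_DDR)/(1 − φ)`;
  the index is the mean over both guilds, with degree ties averaged
  over seeded orderings (default 100). Two conventions matter:
  * The standalone attack-tolerance curve counts *all* opposite-guild
    nodes, so initially isolated nodes are dead from the start.
  * NIR itself first drops isolated nodes and uses the trimmed fill:
    the robustness analysis concerns the interacting community, and
    this preserves the exact identities `R_IDR = 1`, `R_DDR = φ`,
    `NIR = 1` for *any* perfectly nested input — including sparse
    triangular references, whose staircase necessarily leaves empty
    rows. The left-Riemann evaluation (survival measured before each
    removal) is what makes `R_IDR = 1` exact at any size.
  Undefined at complete fill, where the two curves coincide.
* **Spectral radius** `ρ`: the largest singular value of `B` (equal to
  the spectral radius of the full two-guild adjacency). Needs no
  packing and is permutation-invariant. Its normalized companion
  `ρ_norm = 100·ρ/ρ_max` divides by the spectral radius of the nested
  reference of the same `(n, m, E)`. That reference is not the exact
  maximizer for every shape: `ρ_norm` can exceed 100 by a fraction of a
  percent, in which case it is reported unclamped with a warning rather
  than silently truncated.

Indices that are mathematically undefined for an input (`E = 0`;
complete fill for τ and NIR) are explicit flagged states in the report,
never NaN propagation or silent zeros. For an edgeless network NODF,
stable-NODF and ρ are genuinely 0 and reported as such.

## The null ensemble

The null model is the bipartite configuration model obtained by
maximizing Shannon entropy subject to both degree sequences holding *on
average*, equivalently maximizing the likelihood of the observed
degrees in the exponential random-graph family. Links are independent
with `p_ij = x_i y_j/(1 + x_i y_j)`; the multipliers solve the moment
equations `Σ_j p_ij = d_i`, `Σ_i p_ij = e_j`.

Numerics, in order:

1. **Per-node clamps, cascaded.** Degree-0 nodes force `p = 0`; nodes
   connected to the entire (remaining) opposite guild force `p = 1`;
   each clamp updates residual degrees and can trigger further clamps.
2. **Polytope faces.** Even after clamping, a degree sequence can lie
   on a face of the margin polytope: whenever a Gale–Ryser prefix bound
   `Σ_{i≤k} r_i ≤ Σ_j min(c_j, k)` is tight, every realization makes
   the top-`k` rows fill all columns of degree ≥ `k` and starves the
   rest. No finite multipliers exist there, so the solver forces those
   blocks analytically and recurses on the two independent subsystems.
   (After the cascade the minimal tight `k` provably falls on a strict
   degree step, so the split is unambiguous.) Nested and near-nested
   degree sequences live exactly in this regime — a perfectly nested
   sequence is uniquely realizable and its "ensemble" correctly
   collapses to a point mass with zero entropy.
3. **Interior solve.** Duplicate degrees share a multiplier (the
   reduced degree-class system); a Newton root search on the
   log-multipliers with analytic Jacobian does the work, warm-started
   and backed by a damped likelihood fixed point. Tolerance: maximum
   absolute degree residual ≤ `1e-8·max(n, m)` by default.
4. **Multi-start.** The solve is repeated from 8 starting points (one
   heuristic, the rest seeded log-normal perturbations); converged
   starts must agree on the expected degrees within `10·tol`, else a
   solver error reports the residuals. The interior problem is
   strictly concave on the reduced system, so this is a convergence
   safeguard, not an identifiability one.

Sampling draws each cell as an independent Bernoulli; a master seed
spawns one substream per sample, so sample `k` is reproducible
regardless of how many samples are drawn. The default ensemble size is
10⁴ (overridable; the self-consistency tests use a few hundred, which
already pins ensemble means to well within the spreads they measure).
Z-scores use the sample standard deviation (`n − 1`); a zero spread or
an undefined observed value flags the z-score undefined. Samples for
which an index is undefined are excluded from that index's statistics
and counted.

## Dependency analyses

Spearman correlations between each index and each descriptor use
average ranks (tie-corrected) with the two-sided t-approximation
p-value; an exact permutation p-value is available for n ≤ 10. The
multilinear model `ν = β₀ + β₁s + β₂φ + β₃ε + error` is ordinary least
squares with `links_per_node` as the fill covariate and absolute-value
eccentricity; degree degeneracy is deliberately excluded, since its
connection with nestedness is expected rather than spurious. t-ratios,
p-values and adjusted R² come from the standard OLS machinery;
significance is flagged at p < .01 with *no* multiple-testing
correction across the index × descriptor grid — the flags are
screening-table descriptives, and the calibration tests verify the
nominal type-I rate. A constant response (e.g. identically-zero
z-scores) yields zero coefficients and a flagged-undefined R²;
z-score regressions drop undefined entries pairwise, report the count,
and refuse to fit fewer than 6 networks.

## Synthetic test bed

Three generators replace any external survey data:

* `gen_perfect_nested` — the staircase reference;
* `gen_bernoulli` — i.i.d. fill, the unstructured baseline;
* `gen_noisy_nested` — the reference degraded by degree-preserving
  checkerboard swaps. One structural fact shapes this generator: a
  perfectly nested matrix contains *no* checkerboard (its row supports
  are totally ordered by inclusion), so its degree sequence admits
  exactly one matrix and swaps alone can never leave it. For
  `n_swaps > 0` a single deterministic defect is planted first (the
  outermost staircase link moves to the far empty corner); all noisy
  levels of a given `(n, m, E)` then share one degree sequence, so the
  noise level varies nestedness at a constant null-model fit target.
  `n_swaps = 0` returns the exact reference. A corollary worth
  stating: with near-staircase degrees held fixed, heavy swapping
  relaxes the matrix toward an equilibrium that is still highly nested
  — degree sequences, not fine structure, carry most of the nestedness
  signal. The honest monotonicity statement, and the one the tests
  assert, is that heavily noised matrices are at most as nested (in
  stable-NODF and ρ, in expectation over seeds) as the pristine
  reference; intermediate noise levels need not be ordered.

`fixture_battery` crosses sizes 20–200 nodes, matrix fills 0.05–0.5,
eccentricities 0–0.6 and three noise levels into 60 reproducible
networks (all ≥ 20 nodes) whose descriptors are verified not to be in
rank lockstep. It emulates the descriptor spread of a survey of real
mutualistic webs but none of their biology — no phylogenetic signal,
no spatial structure, no sampling effort gradient — so passing tests
demonstrate correctness of the machinery, not ecological conclusions.

Problem sizes in the test suite (ensembles of 250–1000 samples,
networks up to ~200 nodes, 50 self-consistency replicates, 500
calibration regressions at n = 200) were chosen so the full suite
documents the statistical claims at comfortable margins while running
in well under a minute.

## Known limitations

* Temperature depends on the discrete-isocline convention; values are
  internally consistent but not interchangeable with packing-optimizing
  implementations.
* `ρ_max` uses the Manhattan staircase, which is not always the exact
  spectral-radius maximizer; `ρ_norm` may slightly exceed 100.
* Discrepancy inherits the ambiguity of the packed configuration; only
  the one deterministic packing is used.
* The exact-degree (fixed-fixed) null model, weighted networks and
  unipartite projections are out of scope.
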