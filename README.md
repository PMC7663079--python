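# bipnest

Nestedness metrics and maximum-entropy null models for binary bipartite
networks.

Mutualistic communities — plants and their pollinators, hosts and their
parasites, buyers and sellers — are bipartite networks whose
interactions are typically *nested*: the partners of a specialist form
a subset of the partners of every more generalist member of its guild.
Many indices claim to measure this pattern, they disagree, and several
depend strongly on incidental network properties. `bipnest` implements
the principal indices side by side, a degree-preserving maximum-entropy
null ensemble to judge their significance, and the statistical analyses
that expose each index's dependence on size, fill and shape. It is
aimed at ecologists and network scientists who need comparable,
reproducible nestedness numbers.

## What it computes

For an `n × m` biadjacency matrix `B` with `E` links:

* **Temperature** `T_AP` (and `T = 100 − T_AP`): squared relative
  distances `(d/D)²` of misplaced presences/absences from the isocline
  of perfect nestedness, summed and scaled by `100/(U_max·n·m)`.
* **Manhattan-distance index** `τ = (d − d_nest)/(d_rand − d_nest)`
  (and `NMD = 100(1 − τ)`), from unit-square Manhattan distances of the
  packed matrix against its perfectly nested reference.
* **NODF** and **stable-NODF**: mean pairwise overlap fractions
  `Σ_a b_ia b_ja / d_j` over decreasing-degree pairs of rows and of
  columns, normalized by `K = [n(n−1)+m(m−1)]/200`; NODF additionally
  zeroes equal-degree pairs.
* **Discrepancy** `Δ` (and `Δ' = 100(1 − Δ/E)`): misplaced links
  relative to each packed row's leftmost-filled template.
* **NIR**: `(R_IDR − R_DDR)/(1 − φ)` from the areas under attack
  tolerance curves for increasing-/decreasing-degree node removal.
* **Spectral radius** `ρ` (largest singular value of `B`) and
  `ρ_norm = 100·ρ/ρ_max` against the nested reference of equal size
  and fill.
* **Null ensemble**: the bipartite configuration model
  `p_ij = x_i y_j/(1 + x_i y_j)` with multipliers fitted so both degree
  sequences are preserved on average; ensemble sampling and z-scores
  `z = (ν − ⟨ν⟩)/σ` per index.
* **Dependency analyses**: tie-corrected Spearman correlations of each
  index against size, fill, eccentricity and degree degeneracy, and
  multilinear regressions `ν = β₀ + β₁s + β₂φ + β₃ε + error` with
  t-ratios, adjusted R² and p < .01 flags.

See `docs/methods.md` for conventions, numerics and limitations.

## Worked example

```python
import bipnest as bn

# a 15x20 network: nested backbone, degraded by degree-preserving noise
net = bn.gen_noisy_nested(15, 20, 90, n_swaps=400, seed=7)

report = bn.compute_all(net, bn.MetricConfig(nir_orderings=50, seed=0))
for name in bn.METRIC_NAMES:
    e = report[name]
    print(name, e.raw_value, e.transformed_value)

mult, P = bn.fit_bicm(net, seed=0)          # null ensemble
summary = bn.ensemble_metrics(
    net, P, ["nodf", "stable_nodf", "spectral_radius", "rho_norm"],
    n_samples=2000, seed=1,
)
for k, s in summary.metrics.items():
    print(k, s.real_value, s.mean, s.std, s.z_score)
```

prints (formatted):

```
temperature      raw=    0.6102  transformed=   99.3898
nmd              raw=    0.0176  transformed=   98.2355
nodf             raw=   58.8378  transformed=   58.8378
stable_nodf      raw=   60.0436  transformed=   60.0436
discrepancy      raw=    7.0000  transformed=   92.2222
nir              raw=    0.8983  transformed=   89.8333
spectral_radius  raw=    8.4340  transformed=         —
rho_norm         raw=   98.4935  transformed=   98.4935

nodf             real=  58.838 mean=  53.429 std= 4.084 z=+1.32
stable_nodf      real=  60.044 mean=  56.556 std= 4.123 z=+0.85
spectral_radius  real=   8.434 mean=   8.522 std= 0.163 z=-0.54
rho_norm         real=  98.494 mean=  99.560 std= 0.839 z=-1.27
```

Reading: the transformed values all live on a 0–100, larger-is-more-
nested scale; this noisy matrix is still strongly nested (temperature
near 0, discrepancy Δ' ≈ 92). Every |z| < 2: given its degree
sequences, the observed nestedness is statistically indistinguishable
from the maximum-entropy expectation — the degree sequences alone
account for it.

## Command line

```sh
bipnest synth --kind noisy --rows 15 --cols 20 --links 90 --swaps 400 -o net.csv
bipnest compute net.csv -o reports/           # JSON + CSV index reports
bipnest nullmodel net.csv -o reports/         # p_ij matrix + multipliers
bipnest zscore net.csv --n-samples 10000 -o reports/
bipnest analyze batch_dir/ -o reports/        # correlations + regressions
```

Batch `compute` continues past malformed files and distinguishes
all-ok / partial / failed runs by exit code. Inputs are dense CSV/TSV
matrices (optional header row and label column; any positive weight is
a link) or two-column edge lists.

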