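"""Dependency analyses: rank correlations and multilinear regressions.

Two complementary views of how an index depends on network structure:

* tie-corrected Spearman rank correlation between each index and each
  descriptor (size s, links-per-node phi, eccentricity eps, degree
  degeneracy g), flagged significant at p < .01;
* ordinary least squares of the index (or of its null-model z-score) on
  s, phi and eps jointly,

      nu = beta0 + beta1 * s + beta2 * phi + beta3 * eps + error,

  reporting per-coefficient t-ratios, p-values and the adjusted R^2.
  The regression deliberately excludes degree degeneracy, whose
  connection with nestedness is expected rather than spurious.

Raw p < .01 flags are reported without multiple-testing correction
across the index x descriptor grid, mirroring common practice for these
screening tables; treat them as descriptive.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "RegressionResult",
    "spearman",
    "correlation_table",
    "fit_multilinear",
    "zscore_regression",
]

SIGNIFICANCE_LEVEL = 0.01

#: Descriptor columns expected by the regression, in model order.
REGRESSION_COVARIATES = ("size_s", "links_per_node", "eccentricity")


@dataclass(frozen=True)
class CorrelationResult:
    rho: float | None
    p_value: float | None
    significant: bool
    n: int
    note: str = ""


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of one response on (s, phi, eps) with an intercept."""

    intercept: float
    coefficients: dict[str, float]
    t_ratios: dict[str, float]
    p_values: dict[str, float]
    significant: dict[str, bool]
    adjusted_r2: float | None
    n_obs: int
    n_dropped: int = 0


def spearman(
    x: np.ndarray | list[float],
    y: np.ndarray | list[float],
    method: str = "t-approx",
) -> CorrelationResult:
    """Tie-corrected Spearman rank correlation with two-sided p-value.

    ``method='t-approx'`` uses the Student-t approximation;
    ``method='exact'`` enumerates all pairings (only for n <= 10, and
    practical well below that).  Constant inputs have no rank ordering
    and are flagged undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return CorrelationResult(None, None, False, n, note="constant input sequence")
    if method == "t-approx":
        rho, p = sps.spearmanr(x, y)
        rho = float(rho)
        p = float(p)
    elif method == "exact":
        if n > 10:
            raise ValueError("exact permutation p-value limited to n <= 10")
        rho = float(sps.spearmanr(x, y).statistic)
        rx = sps.rankdata(x)
        ry = sps.rankdata(y)
        observed = abs(np.corrcoef(rx, ry)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            r = abs(np.corrcoef(rx, ry[list(perm)])[0, 1])
            count += r >= observed - 1e-12
            total += 1
        p = count / total
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(rho, p, bool(p < SIGNIFICANCE_LEVEL), n)


def correlation_table(
    metric_values: pd.DataFrame,
    descriptor_values: pd.DataFrame,
    method: str = "t-approx",
) -> pd.DataFrame:
    """Spearman correlations for every (index, descriptor) pair.

    Inputs are aligned on their index (one row per network).  Returns a
    tidy frame with columns metric, descriptor, rho, p_value,
    significant, n.
    """
    joined = metric_values.join(descriptor_values, how="inner", lsuffix="", rsuffix="_desc")
    records = []
    for metric in metric_values.columns:
        for descriptor in descriptor_values.columns:
            pair = joined[[metric, descriptor]].dropna()
            if len(pair) < 3:
                records.append(
                    {
                        "metric": metric,
                        "descriptor": descriptor,
                        "rho": None,
                        "p_value": None,
                        "significant": False,
                        "n": len(pair),
                    }
                )
                continue
            res = spearman(pair[metric].to_numpy(), pair[descriptor].to_numpy(), method)
            records.append(
                {
                    "metric": metric,
                    "descriptor": descriptor,
                    "rho": res.rho,
                    "p_value": res.p_value,
                    "significant": res.significant,
                    "n": res.n,
                }
            )
    return pd.DataFrame.from_records(records)


def _check_collinearity(design: pd.DataFrame) -> None:
    mat = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        # name the offender: the first column whose removal restores full rank
        for col in design.columns:
            reduced = design.drop(columns=[col]).to_numpy(dtype=float)
            if np.linalg.matrix_rank(reduced) == rank:
                raise ValueError(f"design is rank-deficient: column {col!r} is collinear")
        raise ValueError("design is rank-deficient")


def fit_multilinear(
    response: np.ndarray | list[float],
    s: np.ndarray | list[float],
    phi: np.ndarray | list[float],
    eps: np.ndarray | list[float],
) -> RegressionResult:
    """OLS of a response on size, links-per-node and eccentricity.

    t-ratios are coefficient / standard error; the adjusted R^2 applies
    the usual degrees-of-freedom correction and is flagged ``None`` for
    a constant response (no variance to explain).
    """
    y = np.asarray(response, dtype=float)
    design = pd.DataFrame(
        {
            "size_s": np.asarray(s, dtype=float),
            "links_per_node": np.asarray(phi, dtype=float),
            "eccentricity": np.asarray(eps, dtype=float),
        }
    )
    if len(design) != y.size:
        raise ValueError("response and covariates differ in length")
    if y.size < 6:
        raise ValueError("need at least 6 observations for the 3-covariate model")
    _check_collinearity(sm.add_constant(design, has_constant="add"))
    model = sm.OLS(y, sm.add_constant(design, has_constant="add"))
    fit = model.fit()
    names = list(design.columns)
    adjusted = float(fit.rsquared_adj)
    if not math.isfinite(adjusted):
        adjusted = None
    coefficients = {name: float(fit.params[name]) for name in names}
    t_ratios = {}
    p_values = {}
    significant = {}
    for name in names:
        t = float(fit.tvalues[name])
        p = float(fit.pvalues[name])
        t_ratios[name] = t if math.isfinite(t) else 0.0
        p_values[name] = p if math.isfinite(p) else 1.0
        significant[name] = bool(math.isfinite(p) and p < SIGNIFICANCE_LEVEL)
    return RegressionResult(
        intercept=float(fit.params["const"]),
        coefficients=coefficients,
        t_ratios=t_ratios,
        p_values=p_values,
        significant=significant,
        adjusted_r2=adjusted,
        n_obs=int(y.size),
    )


def zscore_regression(
    zscores: pd.DataFrame,
    descriptors: pd.DataFrame,
) -> dict[str, RegressionResult | None]:
    """Per-index regression of null-model z-scores on (s, phi, eps).

    ``zscores`` has one row per network and one column per index;
    ``descriptors`` must provide the :data:`REGRESSION_COVARIATES`
    columns with a matching index.  Undefined z-scores are dropped
    pairwise and counted; an index left with fewer than 6 usable
    networks is reported as ``None`` rather than fitted.
    """
    missing = [c for c in REGRESSION_COVARIATES if c not in descriptors.columns]
    if missing:
        raise ValueError(f"descriptors lack columns {missing}")
    results: dict[str, RegressionResult | None] = {}
    for metric in zscores.columns:
        joined = pd.concat(
            [zscores[metric], descriptors[list(REGRESSION_COVARIATES)]], axis=1, join="inner"
        ).dropna()
        n_dropped = len(zscores[metric]) - len(joined)
        if len(joined) < 6:
            results[metric] = None
            continue
        res = fit_multilinear(
            joined[metric].to_numpy(),
            joined["size_s"].to_numpy(),
            joined["links_per_node"].to_numpy(),
            joined["eccentricity"].to_numpy(),
        )
        results[metric] = RegressionResult(
            intercept=res.intercept,
            coefficients=res.coefficients,
            t_ratios=res.t_ratios,
            p_values=res.p_values,
            significant=res.significant,
            adjusted_r2=res.adjusted_r2,
            n_obs=res.n_obs,
            n_dropped=n_dropped,
        )
    return results
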