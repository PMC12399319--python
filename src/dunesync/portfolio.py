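"""Spatial synchrony and portfolio-effect statistics.

Given per-zone yearly series (abundances, vital-rate cell predictions, or
growth rates), this module quantifies how asynchronously the zones
fluctuate and how much that asynchrony damps whole-population variability:

* the synchrony index ``phi = Var(sum_i N_i) / (sum_i sqrt(Var(N_i)))**2``,
  1 for perfectly synchronous and 0 for perfectly compensating zones;
* Taylor's-law mean-variance scaling ``log Var(N_i) = beta0 + z log E(N_i)``
  fit across zones by ordinary least squares on natural logs;
* the portfolio effect ``PE = Var_pred(N_total) / Var_obs(N_total)``, where
  the predicted variance extrapolates the fitted scaling law to the mean
  total abundance — PE above 1 is evidence that asynchrony stabilizes the
  total;
* pairwise Pearson correlation matrices between zones with two-sided
  p-values, the per-pair test (no multiple-testing correction by default).

All variances use the sample (n-1) denominator; the choice cancels in phi
(a ratio) but not in the scaling regression, so it is fixed here rather
than configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PortfolioStats",
    "zone_abundance",
    "synchrony_phi",
    "taylor_fit",
    "portfolio_effect",
    "correlation_matrix",
]


@dataclass
class PortfolioStats:
    phi: float
    beta0: float               # Taylor intercept (natural-log scale)
    z: float                   # Taylor slope
    var_pred_total: float
    var_obs_total: float
    pe: float

    def __post_init__(self) -> None:
        if not np.isclose(self.pe * self.var_obs_total, self.var_pred_total,
                          rtol=1e-9):
            raise ValueError("inconsistent PortfolioStats: PE * Var_obs != Var_pred")


def _as_matrix(mat) -> pd.DataFrame:
    """Coerce to a zones-by-years DataFrame and check shape requirements."""
    df = pd.DataFrame(mat)
    if df.shape[0] < 2 or df.shape[1] < 3:
        raise ValueError("need at least 2 zones and 3 years")
    if df.isna().any().any():
        raise ValueError("zone-by-year matrix contains missing values")
    return df.astype(float)


def zone_abundance(census: pd.DataFrame) -> pd.DataFrame:
    """Plants per (zone, year) over all three stages, zones x years.

    Every live tagged plant counts: seedlings, vegetative plants and
    flowering adults alike.  Zone-year combinations with no plants are 0.
    """
    counts = census.groupby(["zone", "year"]).size().unstack(fill_value=0)
    counts = counts.reindex(
        index=np.sort(census["zone"].unique()),
        columns=np.sort(census["year"].unique()), fill_value=0)
    counts.index.name = "zone"
    counts.columns.name = "year"
    return counts


def synchrony_phi(mat) -> float:
    """Loreau & de Mazancourt synchrony index of a zones-by-years matrix."""
    df = _as_matrix(mat)
    sds = df.std(axis=1, ddof=1)
    if (sds == 0).any():
        bad = list(df.index[sds == 0])
        raise ValueError(f"zones {bad} have zero temporal variance")
    var_total = float(df.sum(axis=0).var(ddof=1))
    return var_total / float(sds.sum()) ** 2


def taylor_fit(mat) -> tuple[float, float]:
    """OLS fit of log temporal variance on log temporal mean across zones.

    Returns (beta0, z) on the natural-log scale.  Requires >= 3 zones (the
    slope needs residual degrees of freedom) with positive means and
    variances, and non-constant log means.
    """
    df = _as_matrix(mat)
    if df.shape[0] < 3:
        raise ValueError("Taylor fit needs >= 3 zones")
    means = df.mean(axis=1).to_numpy()
    variances = df.var(axis=1, ddof=1).to_numpy()
    if np.any(means <= 0) or np.any(variances <= 0):
        raise ValueError("all zone means and variances must be positive")
    x = np.log(means)
    y = np.log(variances)
    if np.ptp(x) == 0:
        raise ValueError("degenerate regression: all zone means equal")
    slope, intercept = np.polyfit(x, y, 1)
    return float(intercept), float(slope)


def portfolio_effect(mat) -> PortfolioStats:
    """Two-step mean-variance portfolio effect of a zones-by-years matrix."""
    df = _as_matrix(mat)
    beta0, z = taylor_fit(df)
    total = df.sum(axis=0)
    var_obs = float(total.var(ddof=1))
    var_pred = float(np.exp(beta0 + z * np.log(total.mean())))
    return PortfolioStats(
        phi=synchrony_phi(df), beta0=beta0, z=z,
        var_pred_total=var_pred, var_obs_total=var_obs,
        pe=var_pred / var_obs)


def correlation_matrix(mat, adjust: str | None = None) -> pd.DataFrame:
    """Pairwise Pearson correlations between zone series with p-values.

    Returns a long table (zone_a, zone_b, r, p, n) for all unordered pairs;
    p is the two-sided t-test with n-2 degrees of freedom.  ``adjust`` may
    name a multiple-testing correction understood by
    ``statsmodels.stats.multitest.multipletests`` (off by default, matching
    per-pair reporting conventions).
    """
    df = pd.DataFrame(mat).astype(float)
    rows = []
    for za, zb in combinations(df.index, 2):
        a, b = df.loc[za], df.loc[zb]
        ok = a.notna() & b.notna()
        if ok.sum() < 3:
            raise ValueError(f"pair ({za}, {zb}) has fewer than 3 shared years")
        av, bv = a[ok].to_numpy(), b[ok].to_numpy()
        if np.ptp(av) == 0 or np.ptp(bv) == 0:
            raise ValueError(f"constant series in pair ({za}, {zb})")
        r, p = stats.pearsonr(av, bv)
        rows.append({"zone_a": za, "zone_b": zb, "r": float(r),
                     "p": float(p), "n": int(ok.sum())})
    out = pd.DataFrame(rows)
    if adjust is not None:
        from statsmodels.stats.multitest import multipletests
        out["p_adj"] = multipletests(out["p"], method=adjust)[1]
    return out
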