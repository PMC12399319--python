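"""Does the climate-by-zone interaction explain asynchrony?

If zones desynchronize because they respond to the same climate signal
with different slopes, then a zone's climate coefficient (from the best
sliding-window model) should covary with how strongly that zone's yearly
vital-rate series correlates with the reference zone's (zone 1, the
foredune).  This module assembles those (coefficient, correlation) points
per rate and fits the least-squares line through them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .window_scan import WindowFitResult

__all__ = [
    "zone1_correlations",
    "attribution_points",
    "coef_vs_corr_regression",
]


def zone1_correlations(pred_matrix: pd.DataFrame,
                       reference_zone: int | None = None) -> pd.Series:
    """Pearson correlation of each zone's yearly series with the reference.

    ``pred_matrix`` is zones x years (cell predictions or growth rates);
    the reference zone defaults to the smallest zone label.  The reference
    zone's own entry is 1 by definition.
    """
    df = pd.DataFrame(pred_matrix).astype(float)
    if reference_zone is None:
        reference_zone = df.index.min()
    if reference_zone not in df.index:
        raise KeyError(f"reference zone {reference_zone} not in matrix")
    ref = df.loc[reference_zone]
    out = {}
    for z in df.index:
        a, b = ref, df.loc[z]
        ok = a.notna() & b.notna()
        if ok.sum() < 3:
            raise ValueError(f"zone {z}: fewer than 3 shared years with reference")
        av, bv = a[ok].to_numpy(), b[ok].to_numpy()
        if np.ptp(av) == 0 or np.ptp(bv) == 0:
            raise ValueError(f"constant series involving zone {z}")
        out[z] = 1.0 if z == reference_zone else float(stats.pearsonr(av, bv)[0])
    s = pd.Series(out, name="r_zone1")
    s.index.name = "zone"
    return s


def attribution_points(best: WindowFitResult, pred_matrix: pd.DataFrame,
                       reference_zone: int | None = None,
                       include_reference: bool = True) -> pd.DataFrame:
    """Pair each zone's climate slope with its correlation to the reference.

    Climate slopes follow the scan's per-zone parameterization (the effect
    of climate in that zone, not a contrast against zone 1).  The reference
    zone's own point (its coefficient, r = 1) is included by default.
    """
    corr = zone1_correlations(pred_matrix, reference_zone)
    ref = corr.index.min() if reference_zone is None else reference_zone
    rows = []
    for z, coef in best.climate_slopes.items():
        if z == ref and not include_reference:
            continue
        rows.append({"rate": best.rate, "zone": z, "coef": float(coef),
                     "r_zone1": float(corr.loc[z])})
    return pd.DataFrame(rows)


def coef_vs_corr_regression(points: pd.DataFrame
                            ) -> tuple[float, float, float]:
    """Least squares of climate coefficient on correlation-with-zone-1.

    Returns (slope, intercept, two-sided p for the slope).  Requires >= 3
    points with non-degenerate correlation spread.
    """
    df = pd.DataFrame(points)
    x = df["r_zone1"].to_numpy(float)
    y = df["coef"].to_numpy(float)
    if len(df) < 3:
        raise ValueError("regression needs >= 3 zones")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x-variance: all correlations equal")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.pvalue)
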