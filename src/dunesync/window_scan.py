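"""Sliding-window climate-driver selection with a randomization null.

For one vital rate, every candidate model regresses the rate on a climate
covariate — the mean monthly anomaly of one variable over one window of
months before the census — with zone-specific slopes:

    response ~ zone + size + climate:zone + (1 | year_t0)

(size only for the size-dependent rates).  The per-zone climate slopes span
the same space as a main effect plus interaction contrasts, so the
climate-by-zone interaction that drives asynchrony is read directly off the
slope differences.  Candidates are all (variable, window) pairs, one
variable at a time; with windows up to 36 months before the census there
are 703 windows per variable.  The winner is the lowest AICc
(``AIC + 2k(k+1)/(n-k-1)``, k counting every estimated parameter including
variance components) across the baseline (no-climate) model and all
candidates.

Because hundreds of windows are tried, strong-looking support can be
spurious.  The randomization test permutes the biological years as whole
blocks against the climate years — preserving within-year dependence,
which the year random intercept models — reruns the scan per permutation,
and reports the add-one exceedance probability of the observed best
improvement over baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._glmm import fit_binomial_mixed, fit_gaussian_mixed
from ._scanfit import batched_binomial_ri, batched_gaussian_ri
from .climate import AnomalySeries, WindowSpec, offset_to_month
from .demography import rate_observations

__all__ = [
    "WindowFitResult",
    "ScanResult",
    "RandomizationResult",
    "enumerate_windows",
    "fit_window_model",
    "baseline_model",
    "scan",
    "randomization_test",
]

logger = logging.getLogger(__name__)

_GAUSSIAN_RATES = {"G", "D"}
_SIZE_RATES = {"S2", "G", "A"}
_TIE_TOL = 1e-9


def enumerate_windows(max_offset: int = 36) -> list[WindowSpec]:
    """All candidate windows over offsets 0..max_offset.

    Count is ``(max_offset + 1)(max_offset + 2) / 2``; for the default
    37-month range that is 703.  Deterministic order: by open, then close.
    """
    if max_offset < 0:
        raise ValueError("max_offset must be >= 0")
    return [WindowSpec(open=o, close=c)
            for o in range(max_offset + 1) for c in range(o + 1)]


@dataclass
class WindowFitResult:
    rate: str
    variable: str | None           # None for the baseline model
    window: WindowSpec | None
    aicc: float
    delta_aicc: float | None       # vs baseline; negative = better
    zone_intercepts: dict[int, float]
    climate_slopes: dict[int, float]
    size_slope: float | None
    re_sd: float
    n: int
    k: int
    converged: bool
    loglik: float = np.nan
    beta_se: np.ndarray | None = field(default=None, repr=False)


@dataclass
class ScanResult:
    rate: str
    table: pd.DataFrame
    best: WindowFitResult
    baseline_aicc: float
    n_candidates: int
    n_failed: int
    n_ties: int


@dataclass
class RandomizationResult:
    rate: str
    n_perm: int
    observed_best_delta: float
    null_best_delta: np.ndarray
    p: float


class _RateData:
    """Rows, base design and grouping for one rate, reused across candidates.

    The size-independent Bernoulli rate (S1) is aggregated to per-(year,
    zone) binomial counts: every fixed covariate is cell-constant, so the
    Bernoulli log-likelihood is reproduced exactly at a fraction of the
    rows.
    """

    def __init__(self, transitions: pd.DataFrame, rate: str):
        obs = rate_observations(transitions, rate)
        if not len(obs):
            raise ValueError(f"no observations for rate {rate}")
        self.rate = rate
        self.family = "gaussian" if rate in _GAUSSIAN_RATES else "binomial"
        self.has_size = rate in _SIZE_RATES
        self.zones = sorted(obs["zone"].unique())
        self.years = np.sort(obs["year_t0"].unique())
        aggregate = self.family == "binomial" and not self.has_size
        if aggregate:
            agg = obs.groupby(["year_t0", "zone"]).agg(
                s=("y", "sum"), m=("y", "size")).reset_index()
            self.succ = agg["s"].to_numpy(float)
            self.trials = agg["m"].to_numpy(float)
            self.y = None
            src = agg
        else:
            src = obs
            if self.family == "binomial":
                self.succ = obs["y"].to_numpy(float)
                self.trials = np.ones(len(obs))
                self.y = None
            else:
                self.y = obs["y"].to_numpy(float)
        self.year_idx = np.searchsorted(self.years, src["year_t0"].to_numpy())
        self.zone_dummies = np.column_stack(
            [(src["zone"] == z).to_numpy(float) for z in self.zones])
        cols = [f"zone_{z}" for z in self.zones]
        parts = [self.zone_dummies]
        if self.has_size:
            self.size_center = float(obs["size"].mean())
            parts.append((src["size"] - self.size_center).to_numpy(float)[:, None])
            cols.append("size")
        else:
            self.size_center = None
        self.X0 = np.column_stack(parts)
        self.col_names = cols
        self.n_rows = self.X0.shape[0]
        self.n_eff = int(self.trials.sum()) if self.family == "binomial" \
            else self.n_rows

    def designs(self, x_by_year: np.ndarray) -> np.ndarray:
        """Stack designs for candidate climate year-covariates (W, ny)."""
        x_by_year = np.atleast_2d(x_by_year)
        x_rows = x_by_year[:, self.year_idx]                   # (W, n)
        clim = self.zone_dummies[None, :, :] * x_rows[:, :, None]
        W = x_by_year.shape[0]
        X0 = np.broadcast_to(self.X0, (W,) + self.X0.shape)
        return np.concatenate([X0, clim], axis=2)


def _aicc(loglik, k, n):
    aic = -2.0 * np.asarray(loglik) + 2.0 * k
    denom = n - k - 1
    if denom <= 0:
        return np.full_like(aic, np.inf)
    return aic + 2.0 * k * (k + 1) / denom


def _batch_fit(data: _RateData, X3: np.ndarray) -> dict:
    ny = len(data.years)
    if data.family == "binomial":
        out = batched_binomial_ri(X3, data.succ, data.trials,
                                  data.year_idx, ny)
    else:
        out = batched_gaussian_ri(X3, data.y, data.year_idx, ny)
    out["aicc"] = _aicc(out["loglik"], out["k"], data.n_eff)
    return out


def _offset_anomaly_matrix(anoms: AnomalySeries, years_t0: np.ndarray,
                           max_offset: int, anchor_month: int) -> np.ndarray:
    """z[i, k] = anomaly at offset k before the census of year years_t0[i]+1."""
    Z = np.empty((len(years_t0), max_offset + 1))
    for i, t0 in enumerate(years_t0):
        for k in range(max_offset + 1):
            Z[i, k] = anoms.z(*offset_to_month(int(t0) + 1, k, anchor_month))
    return Z


def _window_x(Z: np.ndarray, windows: list[WindowSpec]) -> np.ndarray:
    """(W, ny) window-mean anomalies from the per-offset matrix via cumsums."""
    C = np.concatenate([np.zeros((Z.shape[0], 1)), np.cumsum(Z, axis=1)], axis=1)
    out = np.empty((len(windows), Z.shape[0]))
    for i, w in enumerate(windows):
        out[i] = (C[:, w.open + 1] - C[:, w.close]) / w.n_months
    return out


def baseline_model(transitions: pd.DataFrame, rate: str) -> float:
    """AICc of the no-climate model (zone + size + random year intercept)."""
    data = _RateData(transitions, rate)
    out = _batch_fit(data, data.X0[None, :, :])
    return float(out["aicc"][0])


def fit_window_model(transitions: pd.DataFrame, anoms: AnomalySeries,
                     rate: str, window: WindowSpec,
                     anchor_month: int = 6,
                     baseline_aicc: float | None = None) -> WindowFitResult:
    """Fit a single candidate model, with standard errors.

    This is the scalar reference path; :func:`scan` uses an equivalent
    batched fitter whose AICc values agree to well below selection-relevant
    differences.  A window whose covariate is constant across years makes
    the design singular and returns a flagged (non-converged) result.
    """
    data = _RateData(transitions, rate)
    Z = _offset_anomaly_matrix(anoms, data.years, window.open, anchor_month)
    x_by_year = _window_x(Z, [window])[0]
    nz = len(data.zones)
    if np.ptp(x_by_year) < 1e-12:
        logger.warning("window (%d, %d) of %s has a constant covariate; flagged",
                       window.open, window.close, anoms.variable)
        return WindowFitResult(
            rate=rate, variable=anoms.variable, window=window, aicc=np.nan,
            delta_aicc=None, zone_intercepts={}, climate_slopes={},
            size_slope=None, re_sd=np.nan, n=data.n_eff, k=0, converged=False)
    X3 = data.designs(x_by_year)
    X = X3[0]
    if data.family == "binomial":
        fit = fit_binomial_mixed(X, data.succ, data.trials,
                                 data.years[data.year_idx])
        re_sd = fit.vcomp["re_sd"]
    else:
        fit = fit_gaussian_mixed(X, data.y, data.years[data.year_idx])
        re_sd = fit.vcomp["re_sd"]
    beta = fit.beta
    p0 = nz + (1 if data.has_size else 0)
    aicc = float(_aicc(fit.loglik, fit.k, data.n_eff))
    return WindowFitResult(
        rate=rate, variable=anoms.variable, window=window, aicc=aicc,
        delta_aicc=None if baseline_aicc is None else aicc - baseline_aicc,
        zone_intercepts=dict(zip(data.zones, beta[:nz])),
        climate_slopes=dict(zip(data.zones, beta[p0:])),
        size_slope=float(beta[nz]) if data.has_size else None,
        re_sd=float(re_sd), n=data.n_eff, k=fit.k, converged=fit.converged,
        loglik=fit.loglik, beta_se=fit.beta_se)


def _scan_rows(data: _RateData, zmats: dict[str, np.ndarray],
               windows: list[WindowSpec], baseline_aicc: float,
               year_perm: np.ndarray | None = None,
               chunk_elems: float = 6e6) -> list[dict]:
    """Fit every (variable, window) candidate; one result dict per candidate."""
    nz = len(data.zones)
    p0 = nz + (1 if data.has_size else 0)
    p = p0 + nz
    chunk = max(1, int(chunk_elems // max(data.n_rows * p, 1)))
    rows = []
    for var_order, (var, Z) in enumerate(zmats.items()):
        if year_perm is not None:
            Z = Z[year_perm]
        xmat = _window_x(Z, windows)
        degenerate = np.ptp(xmat, axis=1) < 1e-12
        for lo in range(0, len(windows), chunk):
            hi = min(lo + chunk, len(windows))
            idx = [i for i in range(lo, hi) if not degenerate[i]]
            if idx:
                out = _batch_fit(data, data.designs(xmat[idx]))
            for j, i in enumerate(idx):
                w = windows[i]
                beta = out["beta"][j]
                row = {"variable": var, "var_order": var_order,
                       "open": w.open, "close": w.close,
                       "n_months": w.n_months,
                       "aicc": float(out["aicc"][j]),
                       "delta_aicc": float(out["aicc"][j] - baseline_aicc),
                       "re_sd": float(out["re_sd"][j]), "converged": True}
                for zi, z in enumerate(data.zones):
                    row[f"intercept_zone_{z}"] = float(beta[zi])
                    row[f"slope_zone_{z}"] = float(beta[p0 + zi])
                if data.has_size:
                    row["size_slope"] = float(beta[nz])
                rows.append(row)
            for i in range(lo, hi):
                if degenerate[i]:
                    w = windows[i]
                    logger.warning(
                        "scan %s/%s window (%d, %d): constant covariate, "
                        "excluded", data.rate, var, w.open, w.close)
                    rows.append({"variable": var, "var_order": var_order,
                                 "open": w.open, "close": w.close,
                                 "n_months": w.n_months, "aicc": np.nan,
                                 "delta_aicc": np.nan, "re_sd": np.nan,
                                 "converged": False})
    return rows


def _best_delta(data: _RateData, zmats: dict[str, np.ndarray],
                windows: list[WindowSpec], baseline_aicc: float,
                year_perm: np.ndarray,
                chunk_elems: float = 6e6) -> float:
    """Best candidate delta-AICc only (the randomization test's hot path)."""
    nz = len(data.zones)
    p = 2 * nz + (1 if data.has_size else 0)
    chunk = max(1, int(chunk_elems // max(data.n_rows * p, 1)))
    best = np.inf
    for var, Z in zmats.items():
        xmat = _window_x(Z[year_perm], windows)
        keep = np.ptp(xmat, axis=1) >= 1e-12
        xs = xmat[keep]
        for lo in range(0, len(xs), chunk):
            out = _batch_fit(data, data.designs(xs[lo:lo + chunk]))
            best = min(best, float(np.min(out["aicc"])))
    if not np.isfinite(best):
        raise RuntimeError(f"scan of rate {data.rate}: all candidates failed")
    return best - baseline_aicc


def scan(transitions: pd.DataFrame, anoms: dict[str, AnomalySeries],
         rate: str, max_offset: int = 36, anchor_month: int = 6,
         baseline_aicc: float | None = None,
         year_perm: np.ndarray | None = None,
         chunk_elems: float = 6e6) -> ScanResult:
    """Evaluate every (variable, window) candidate and select by AICc.

    ``anoms`` maps variable names to anomaly series; variables are scanned
    one at a time.  ``year_perm`` (used by the randomization test) remaps
    biological years to climate years as whole blocks: entry i gives the
    index of the climate year assigned to biological year i.  Exact AICc
    ties are broken deterministically — shorter window, then more recent,
    then variable order — and counted in the result.
    """
    if isinstance(anoms, AnomalySeries):
        anoms = {anoms.variable: anoms}
    data = _RateData(transitions, rate)
    windows = enumerate_windows(max_offset)
    if baseline_aicc is None:
        baseline_aicc = float(_batch_fit(data, data.X0[None, :, :])["aicc"][0])
    zmats = {var: _offset_anomaly_matrix(series, data.years, max_offset,
                                         anchor_month)
             for var, series in anoms.items()}
    nz = len(data.zones)
    p0 = nz + (1 if data.has_size else 0)
    p = p0 + nz
    table = pd.DataFrame(_scan_rows(data, zmats, windows, baseline_aicc,
                                    year_perm, chunk_elems))
    ok = table[table["converged"]]
    if not len(ok):
        raise RuntimeError(f"scan of rate {rate}: all candidates failed")
    amin = ok["aicc"].min()
    tied = ok[ok["aicc"] <= amin + _TIE_TOL]
    n_ties = len(tied) - 1
    if n_ties:
        logger.info("scan %s: %d AICc ties at the minimum", rate, n_ties)
    best_row = tied.sort_values(
        ["n_months", "close", "var_order"]).iloc[0]
    bw = WindowSpec(open=int(best_row["open"]), close=int(best_row["close"]))
    best = WindowFitResult(
        rate=rate, variable=str(best_row["variable"]), window=bw,
        aicc=float(best_row["aicc"]),
        delta_aicc=float(best_row["delta_aicc"]),
        zone_intercepts={z: best_row[f"intercept_zone_{z}"]
                         for z in data.zones},
        climate_slopes={z: best_row[f"slope_zone_{z}"] for z in data.zones},
        size_slope=float(best_row["size_slope"]) if data.has_size else None,
        re_sd=float(best_row["re_sd"]), n=data.n_eff,
        k=p + (1 if data.family == "binomial" else 2), converged=True)
    table = table.drop(columns=["var_order"])
    return ScanResult(rate=rate, table=table, best=best,
                      baseline_aicc=baseline_aicc,
                      n_candidates=len(table), n_failed=int((~table["converged"]).sum()),
                      n_ties=n_ties)


def randomization_test(transitions: pd.DataFrame,
                       anoms: dict[str, AnomalySeries], rate: str,
                       n_perm: int = 1000, seed: int = 0,
                       max_offset: int = 36,
                       anchor_month: int = 6) -> RandomizationResult:
    """Year-block randomization of the scan's best model support.

    Biological years are shuffled against climate years ``n_perm`` times
    (whole blocks, preserving within-year dependence); the full scan is
    rerun per permutation and the best improvement over baseline recorded.
    The baseline contains no climate term, so it is invariant under the
    permutation and computed once.  ``p = (1 + #{null <= observed}) /
    (n_perm + 1)`` estimates the probability that support as strong as the
    observed one arises with climate decoupled from demography.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if isinstance(anoms, AnomalySeries):
        anoms = {anoms.variable: anoms}
    data = _RateData(transitions, rate)
    if len(data.years) < 2:
        raise ValueError("randomization needs >= 2 distinct years")
    baseline = float(_batch_fit(data, data.X0[None, :, :])["aicc"][0])
    windows = enumerate_windows(max_offset)
    zmats = {var: _offset_anomaly_matrix(series, data.years, max_offset,
                                         anchor_month)
             for var, series in anoms.items()}
    ny = len(data.years)
    identity = np.arange(ny)
    obs_delta = _best_delta(data, zmats, windows, baseline, identity)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        null[i] = _best_delta(data, zmats, windows, baseline,
                              rng.permutation(ny))
    p = (1.0 + np.sum(null <= obs_delta)) / (n_perm + 1.0)
    return RandomizationResult(rate=rate, n_perm=n_perm,
                               observed_best_delta=obs_delta,
                               null_best_delta=null, p=float(p))
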