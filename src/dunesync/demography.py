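"""Plant-year transitions and vital-rate mixed models.

The census table records every tagged plant once per year with its stage
(seedling, vegetative, flowering) and, for vegetative plants, ln taproot
diameter.  :func:`build_transitions` turns that into one row per plant per
year t0 describing its fate at t1, applying the field scoring rules:

* a plant never seen again is scored dead in the first year it went missing
  (in the field the three-missing-year criterion builds confidence in that
  call; censoring terminal absences instead would bias survival upward);
* a plant re-found after a gap is credited with survival through the gap,
  but gap years carry no size (nothing is fabricated);
* a flowering plant dies after reproduction and yields no transition.

Five vital rates are then fit as generalized linear mixed models whose only
random term is the year-by-zone interaction — deliberately not separate year
and zone effects, which would shrink zones fluctuating in opposite
directions within a year toward a common mean and mask asynchrony:

====  ==========================  =============================================
rate  response                    model
====  ==========================  =============================================
S1    seedling survival           logit, intercept + (1 | year:zone)
S2    vegetative survival         logit, size + (1 + size | year:zone)
G     ln-size at t1               Gaussian, size + (1 + size | year:zone)
A     flowering at t1 (survivors) logit, size + (1 + size | year:zone)
D     first ln-size after         Gaussian, intercept + (1 | year:zone)
      the seedling year
====  ==========================  =============================================

Size enters centered on the fitted data's mean for numerical stability; the
centering constant is stored on the fit and undone in reporting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from ._glmm import fit_binomial_mixed, fit_gaussian_mixed
from .synthetic import STAGE_FLOWERING, STAGE_SEEDLING, STAGE_VEGETATIVE

__all__ = [
    "RATES",
    "VitalRateFit",
    "build_transitions",
    "rate_observations",
    "fit_vital_rate",
    "predict_cell",
    "cell_prediction_series",
    "recruitment",
]

RATES = ("S1", "S2", "G", "A", "D")
_BERNOULLI = {"S1", "S2", "A"}
_SIZE_DEPENDENT = {"S2", "G", "A"}


def build_transitions(census: pd.DataFrame) -> pd.DataFrame:
    """Construct year t0 -> t1 fate records from a long-format census table.

    Returns columns: plant_id, zone, year_t0, stage_t0, size_t0,
    survived_t1, flowered_t1, size_t1, gap (True for interpolated gap-year
    rows of re-found plants).  Raises on duplicate (plant_id, year) rows and
    on any record following a flowering record (monocarpy violation).
    """
    req = {"plant_id", "zone", "year", "stage", "size"}
    if not req.issubset(census.columns):
        raise ValueError(f"census table needs columns {sorted(req)}")
    if census.duplicated(subset=["plant_id", "year"]).any():
        dups = census[census.duplicated(subset=["plant_id", "year"], keep=False)]
        raise ValueError(
            f"duplicate (plant_id, year) rows, e.g. {dups.iloc[0].to_dict()}")
    df = census.sort_values(["plant_id", "year"]).reset_index(drop=True)
    last_year = int(df["year"].max())

    grp = df.groupby("plant_id", sort=False)
    nxt_year = grp["year"].shift(-1)
    nxt_stage = grp["stage"].shift(-1)
    nxt_size = grp["size"].shift(-1)

    flowering_with_later = (df["stage"] == STAGE_FLOWERING) & nxt_year.notna()
    if flowering_with_later.any():
        bad = df.loc[flowering_with_later, "plant_id"].iloc[0]
        raise ValueError(
            f"plant {bad!r} has a record after flowering (monocarpy violated)")

    year = df["year"].to_numpy(int)
    active = df["stage"] != STAGE_FLOWERING
    has_next = nxt_year.notna()
    gap_len = np.where(has_next, nxt_year.fillna(0).to_numpy(int) - year, 0)

    rows: dict[str, list] = {c: [] for c in (
        "plant_id", "zone", "year_t0", "stage_t0", "size_t0",
        "survived_t1", "flowered_t1", "size_t1", "gap")}

    def emit(pid, zone, t0, stage0, size0, surv, flow, size1, gap):
        rows["plant_id"].append(pid)
        rows["zone"].append(zone)
        rows["year_t0"].append(t0)
        rows["stage_t0"].append(stage0)
        rows["size_t0"].append(size0)
        rows["survived_t1"].append(surv)
        rows["flowered_t1"].append(flow)
        rows["size_t1"].append(size1)
        rows["gap"].append(gap)

    pid_arr = df["plant_id"].to_numpy()
    zone_arr = df["zone"].to_numpy()
    stage_arr = df["stage"].to_numpy()
    size_arr = df["size"].to_numpy(float)
    nxt_stage_arr = nxt_stage.to_numpy()
    nxt_size_arr = nxt_size.to_numpy(float)

    for i in np.flatnonzero(active.to_numpy()):
        t0 = year[i]
        if has_next.iloc[i]:
            g = gap_len[i]
            n_stage = nxt_stage_arr[i]
            n_size = nxt_size_arr[i] if n_stage == STAGE_VEGETATIVE else np.nan
            if g == 1:
                emit(pid_arr[i], zone_arr[i], t0, stage_arr[i], size_arr[i],
                     1, int(n_stage == STAGE_FLOWERING), n_size, False)
            else:
                # alive through the gap; sizes unknown in gap years
                emit(pid_arr[i], zone_arr[i], t0, stage_arr[i], size_arr[i],
                     1, 0, np.nan, False)
                for yy in range(t0 + 1, t0 + g):
                    final = yy == t0 + g - 1
                    emit(pid_arr[i], zone_arr[i], yy, STAGE_VEGETATIVE, np.nan,
                         1, int(final and n_stage == STAGE_FLOWERING),
                         n_size if final else np.nan, True)
        else:
            missing = last_year - t0
            if missing >= 1:
                # Never seen again: dead in the first year it went missing.
                # Scoring shorter terminal absences as deaths too avoids the
                # survivorship bias of censoring them (their survivors would
                # stay in the data while their deaths vanished).
                emit(pid_arr[i], zone_arr[i], t0, stage_arr[i], size_arr[i],
                     0, 0, np.nan, False)

    out = pd.DataFrame(rows)
    if len(out):
        out = out.astype({"zone": int, "year_t0": int,
                          "survived_t1": int, "flowered_t1": int})
    return out


def rate_observations(transitions: pd.DataFrame, rate: str) -> pd.DataFrame:
    """Extract the response (and size covariate) for one vital rate.

    Rows lacking a required size are dropped: gap-year transitions carry
    survival credit but no measurements, so they inform S1 only through the
    observed seedling year and never contribute growth observations.
    """
    t = transitions
    if rate == "S1":
        sub = t[t["stage_t0"] == STAGE_SEEDLING]
        return pd.DataFrame({"year_t0": sub["year_t0"], "zone": sub["zone"],
                             "y": sub["survived_t1"].astype(float)})
    if rate == "S2":
        sub = t[(t["stage_t0"] == STAGE_VEGETATIVE) & t["size_t0"].notna()]
        return pd.DataFrame({"year_t0": sub["year_t0"], "zone": sub["zone"],
                             "y": sub["survived_t1"].astype(float),
                             "size": sub["size_t0"]})
    if rate == "A":
        sub = t[(t["stage_t0"] == STAGE_VEGETATIVE) & (t["survived_t1"] == 1)
                & t["size_t0"].notna()]
        return pd.DataFrame({"year_t0": sub["year_t0"], "zone": sub["zone"],
                             "y": sub["flowered_t1"].astype(float),
                             "size": sub["size_t0"]})
    if rate == "G":
        sub = t[(t["stage_t0"] == STAGE_VEGETATIVE) & (t["survived_t1"] == 1)
                & (t["flowered_t1"] == 0) & t["size_t0"].notna()
                & t["size_t1"].notna()]
        return pd.DataFrame({"year_t0": sub["year_t0"], "zone": sub["zone"],
                             "y": sub["size_t1"], "size": sub["size_t0"]})
    if rate == "D":
        sub = t[(t["stage_t0"] == STAGE_SEEDLING) & (t["survived_t1"] == 1)
                & t["size_t1"].notna()]
        return pd.DataFrame({"year_t0": sub["year_t0"], "zone": sub["zone"],
                             "y": sub["size_t1"]})
    raise ValueError(f"unknown rate {rate!r}; expected one of {RATES}")


@dataclass
class VitalRateFit:
    """One fitted vital-rate model with its year-by-zone random effects."""

    rate: str
    family: str                    # "bernoulli-logit" or "gaussian-identity"
    intercept: float
    size_slope: float | None       # None for size-independent rates
    size_center: float | None      # centering constant (ln mm), undone on request
    size_sd: float | None
    ranef: pd.DataFrame            # year_t0, zone, b_intercept[, b_size]
    resid_sd: float | None
    vcomp: dict[str, float]
    loglik: float
    n: int
    converged: bool
    beta_se: np.ndarray | None = None

    def cells(self) -> list[tuple[int, int]]:
        return list(zip(self.ranef["year_t0"], self.ranef["zone"]))

    def _cell_effects(self, year: int, zone: int) -> tuple[float, float]:
        sel = self.ranef[(self.ranef["year_t0"] == year)
                         & (self.ranef["zone"] == zone)]
        if not len(sel):
            raise KeyError(f"no (year={year}, zone={zone}) cell in {self.rate} fit")
        b0 = float(sel["b_intercept"].iloc[0])
        b1 = float(sel["b_size"].iloc[0]) if "b_size" in sel.columns else 0.0
        return b0, b1


def _cell_codes(year: np.ndarray, zone: np.ndarray) -> np.ndarray:
    return year.astype(np.int64) * 1000 + zone.astype(np.int64)


def fit_vital_rate(transitions: pd.DataFrame, rate: str) -> VitalRateFit:
    """Fit one of the five vital-rate mixed models.

    Bernoulli rates use the package's Laplace GLMM; Gaussian rates with a
    random size slope (G) use statsmodels ``MixedLM``; the size-independent
    Gaussian rate (D) uses the fast profiled random-intercept LMM.
    """
    obs = rate_observations(transitions, rate)
    cells = _cell_codes(obs["year_t0"].to_numpy(), obs["zone"].to_numpy())
    if len(np.unique(cells)) < 2:
        raise ValueError(f"rate {rate}: need >=2 (year, zone) cells with data")
    size_dependent = rate in _SIZE_DEPENDENT
    if size_dependent:
        center = float(obs["size"].mean())
        size_sd = float(obs["size"].std(ddof=1))
        size_c = obs["size"].to_numpy() - center
        X = np.column_stack([np.ones(len(obs)), size_c])
    else:
        center = size_sd = None
        size_c = None
        X = np.ones((len(obs), 1))

    if rate in _BERNOULLI:
        y = obs["y"].to_numpy()
        fit = fit_binomial_mixed(X, y, np.ones(len(y)), cells,
                                 slope_covariate=size_c)
        family = "bernoulli-logit"
        resid_sd = None
        ran = np.atleast_2d(fit.ranef.T).T if fit.ranef.ndim == 1 else fit.ranef
        labels = fit.group_labels
        loglik, n, conv = fit.loglik, fit.n, fit.converged
        beta, se, vcomp = fit.beta, fit.beta_se, fit.vcomp
    elif rate == "G":
        import statsmodels.formula.api as smf
        dat = obs.assign(size_c=size_c, cell=cells)
        md = smf.mixedlm("y ~ size_c", dat, groups="cell",
                         re_formula="~size_c")
        res = md.fit(reml=True, method=["lbfgs", "bfgs"])
        family = "gaussian-identity"
        resid_sd = float(np.sqrt(res.scale))
        labels = np.array(sorted(dat["cell"].unique()))
        ran = np.zeros((len(labels), 2))
        re = res.random_effects
        for i, lab in enumerate(labels):
            v = re[lab]
            ran[i, 0] = v.iloc[0]
            ran[i, 1] = v.iloc[1] if len(v) > 1 else 0.0
        cov_re = np.asarray(res.cov_re)
        vcomp = {"re_sd_intercept": float(np.sqrt(max(cov_re[0, 0], 0.0))),
                 "re_sd_slope": float(np.sqrt(max(cov_re[1, 1], 0.0))),
                 "re_corr": float(cov_re[0, 1]
                                  / max(np.sqrt(cov_re[0, 0] * cov_re[1, 1]),
                                        1e-12))}
        beta = np.asarray(res.fe_params)
        se = np.asarray(res.bse_fe)
        loglik, n, conv = float(res.llf), len(dat), bool(res.converged)
    else:  # D
        fit = fit_gaussian_mixed(X, obs["y"].to_numpy(), cells)
        family = "gaussian-identity"
        resid_sd = fit.resid_sd
        ran = fit.ranef[:, None]
        labels = fit.group_labels
        loglik, n, conv = fit.loglik, fit.n, fit.converged
        beta, se, vcomp = fit.beta, fit.beta_se, fit.vcomp

    ranef = pd.DataFrame({
        "year_t0": (labels // 1000).astype(int),
        "zone": (labels % 1000).astype(int),
        "b_intercept": ran[:, 0],
    })
    if size_dependent and ran.shape[1] > 1:
        ranef["b_size"] = ran[:, 1]
    return VitalRateFit(
        rate=rate, family=family,
        intercept=float(beta[0]),
        size_slope=float(beta[1]) if size_dependent else None,
        size_center=center, size_sd=size_sd,
        ranef=ranef, resid_sd=resid_sd, vcomp=vcomp,
        loglik=loglik, n=n, converged=conv, beta_se=np.asarray(se))


def predict_cell(fit: VitalRateFit, year: int, zone: int,
                 size: float | None = None) -> float:
    """Mean response-scale prediction for one (year, zone) cell.

    ``size`` is ln taproot diameter on the raw (uncentered) scale; it is
    required for size-dependent rates and ignored otherwise.
    """
    b0, b1 = fit._cell_effects(year, zone)
    eta = fit.intercept + b0
    if fit.size_slope is not None:
        if size is None:
            raise ValueError(f"rate {fit.rate} prediction requires a size")
        eta += (fit.size_slope + b1) * (size - fit.size_center)
    return float(expit(eta)) if fit.family == "bernoulli-logit" else float(eta)


def cell_prediction_series(fit: VitalRateFit,
                           at: str = "mean") -> pd.DataFrame:
    """Zone-by-year matrix of cell predictions at a reference size.

    ``at`` is ``"mean"`` (dataset mean size; the convention for survival and
    growth) or ``"mean+sd"`` (one SD above the mean; the convention for
    flowering probability, which is uniformly low at small sizes).  Rows are
    zones, columns years; cells absent from the fit are NaN.
    """
    if fit.size_slope is None:
        size = None
    elif at == "mean":
        size = fit.size_center
    elif at == "mean+sd":
        size = fit.size_center + fit.size_sd
    else:
        raise ValueError("at must be 'mean' or 'mean+sd'")
    years = sorted(fit.ranef["year_t0"].unique())
    zones = sorted(fit.ranef["zone"].unique())
    mat = pd.DataFrame(np.nan, index=zones, columns=years)
    for (y, z) in fit.cells():
        mat.loc[z, y] = predict_cell(fit, y, z, size)
    mat.index.name = "zone"
    mat.columns.name = "year_t0"
    return mat


def recruitment(census: pd.DataFrame) -> pd.Series:
    """Zone-specific recruitment: seedlings per reproductive adult, pooled.

    ``r_zone = sum_t seedlings(zone, t+1) / sum_t flowering(zone, t)`` with
    both sums over all transition years — pooling avoids dividing by zero in
    years with no flowering plants.  A zone with no flowering plants in any
    year has undefined recruitment and raises ``ValueError``.
    """
    years = np.sort(census["year"].unique())
    zones = np.sort(census["zone"].unique())
    seedlings = census[(census["stage"] == STAGE_SEEDLING)
                       & (census["year"] >= years[0] + 1)]
    adults = census[(census["stage"] == STAGE_FLOWERING)
                    & (census["year"] <= years[-1] - 1)]
    n_seed = seedlings.groupby("zone").size().reindex(zones, fill_value=0)
    n_adult = adults.groupby("zone").size().reindex(zones, fill_value=0)
    if (n_adult == 0).any():
        bad = list(n_adult.index[n_adult == 0])
        raise ValueError(
            f"zones {bad} have no flowering adults in any year; "
            "recruitment is undefined")
    r = (n_seed / n_adult).astype(float)
    r.name = "r"
    return r
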