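"""Individual-based synthetic census and climate generator.

The generator emulates the study design the analysis pipeline assumes: a
multi-year, multi-zone annual census of a monocarpic perennial.  Seedlings
are tagged but not measured; vegetative plants carry a size (natural log of
taproot diameter in mm); a plant flowers at most once and dies after
flowering.  Five vital rates drive the dynamics:

* ``S1`` — seedling survival to the vegetative stage (Bernoulli, logit),
* ``S2`` — vegetative survival (Bernoulli, logit, size-dependent),
* ``G``  — growth of surviving non-flowering plants (Gaussian in ln-size),
* ``A``  — probability a surviving vegetative plant flowers next year
  (Bernoulli, logit, size-dependent),
* ``D``  — size of a new vegetative plant the year after it was a seedling
  (Gaussian in ln-size),

plus zone-specific recruitment ``r`` (seedlings per flowering adult, Poisson).

Climate enters each rate's linear predictor as the mean monthly anomaly of a
chosen variable over a chosen window of months before the census, multiplied
by a zone-specific slope.  The default slopes increase monotonically from
negative in zone 1 (foredune) to positive in zone 5 (backdune), so zones
respond to the same climate signal in opposite directions — the structure
that creates demographic asynchrony.  A year-level Gaussian deviate shared
across zones adds temporal variation that climate does not explain.

All true parameters, realized per-(year, zone) rates, yearly climate
covariates and year deviates are returned alongside the census table so that
recovery tests can compare estimates against truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import truncnorm

from .climate import AnomalySeries, WindowSpec, monthly_anomalies, window_mean

__all__ = [
    "ClimateGenParams",
    "GeneratorParams",
    "Truth",
    "generate_climate",
    "generate_population",
    "apply_detection_noise",
    "default_params",
]

RATES = ("S1", "S2", "G", "A", "D")

STAGE_SEEDLING = "seedling"
STAGE_VEGETATIVE = "vegetative"
STAGE_FLOWERING = "flowering"

# Seasonal climatology loosely shaped like a northern Great Lakes station:
# monthly total precipitation (mm) and air temperatures (deg C), Jan..Dec.
_PRCP_MEAN = (45.0, 38.0, 52.0, 68.0, 74.0, 82.0, 78.0, 88.0, 95.0, 84.0, 72.0, 56.0)
_TMEAN_MEAN = (-6.0, -5.0, 0.0, 7.0, 13.0, 18.0, 21.0, 20.0, 16.0, 9.0, 2.0, -3.0)


@dataclass(frozen=True)
class ClimateGenParams:
    """Seasonal means and SDs per variable for the monthly climate generator."""

    prcp_mean: tuple[float, ...] = _PRCP_MEAN
    prcp_sd: tuple[float, ...] = tuple(0.35 * m for m in _PRCP_MEAN)
    tmean_mean: tuple[float, ...] = _TMEAN_MEAN
    tmean_sd: tuple[float, ...] = (2.2,) * 12
    tmin_offset: float = -5.5
    tmax_offset: float = 6.0
    temp_extreme_sd: float = 1.2  # extra independent noise on tmin/tmax

    def validate(self) -> None:
        for name in ("prcp_sd", "tmean_sd"):
            if any(s <= 0 for s in getattr(self, name)):
                raise ValueError(f"{name} must be strictly positive")
        if self.temp_extreme_sd <= 0:
            raise ValueError("temp_extreme_sd must be strictly positive")
        for name in ("prcp_mean", "prcp_sd", "tmean_mean", "tmean_sd"):
            if len(getattr(self, name)) != 12:
                raise ValueError(f"{name} must have 12 monthly entries")


def generate_climate(start_year: int, n_years: int,
                     params: ClimateGenParams | None = None,
                     seed: int = 0,
                     include_drought_index: bool = True) -> pd.DataFrame:
    """Simulate a monthly station table: year, month, prcp, tmin, tmean, tmax.

    Values are seasonal means plus independent Gaussian noise; precipitation
    is floored at zero.  When ``include_drought_index`` is set, a synthetic
    SPI-3-like column ``drought_index`` is added: the 3-month running mean of
    per-calendar-month precipitation z-scores, restandardized per calendar
    month.  Deterministic given ``seed``.
    """
    params = params or ClimateGenParams()
    params.validate()
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(seed)
    years = np.repeat(np.arange(start_year, start_year + n_years), 12)
    months = np.tile(np.arange(1, 13), n_years)
    n = len(years)
    pm = np.asarray(params.prcp_mean)[months - 1]
    ps = np.asarray(params.prcp_sd)[months - 1]
    tm = np.asarray(params.tmean_mean)[months - 1]
    ts = np.asarray(params.tmean_sd)[months - 1]
    prcp = np.maximum(rng.normal(pm, ps), 0.0)
    tmean = rng.normal(tm, ts)
    tmin = tmean + params.tmin_offset + rng.normal(0, params.temp_extreme_sd, n)
    tmax = tmean + params.tmax_offset + rng.normal(0, params.temp_extreme_sd, n)
    out = pd.DataFrame({
        "year": years, "month": months,
        "prcp": prcp, "tmin": tmin, "tmean": tmean, "tmax": tmax,
    })
    if include_drought_index:
        # water balance: precipitation supply minus temperature-driven
        # demand, 3-month running mean, restandardized per calendar month
        def colz(col):
            g = out.groupby("month")[col]
            return (out[col] - g.transform("mean")) \
                / g.transform(lambda s: s.std(ddof=1))
        bal = (colz("prcp") - colz("tmean")) / np.sqrt(2.0)
        b3 = bal.rolling(3, min_periods=1).mean()
        g3 = b3.groupby(out["month"])
        out["drought_index"] = (b3 - g3.transform("mean")) / g3.transform(
            lambda s: s.std(ddof=1))
    return out


def _per_zone(values, n_zones: int, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 0:
        arr = np.full(n_zones, float(arr))
    if arr.shape != (n_zones,):
        raise ValueError(f"{name} must be scalar or length {n_zones}")
    return arr


def _graded_slopes(scale: float, n_zones: int) -> tuple[float, ...]:
    """Slopes increasing monotonically from -scale (zone 1) to +scale (zone n)."""
    return tuple(np.linspace(-scale, scale, n_zones))


@dataclass(frozen=True)
class GeneratorParams:
    """True parameters of the synthetic census generator.

    Linear predictors are on the logit scale for S1/S2/A and the ln-mm scale
    for G/D; size covariates use raw ln taproot diameter (mm).  Climate
    slopes are per anomaly unit (the window-mean z-score of
    ``true_variable`` over ``true_window``, anchored at the June census of
    the second year of each transition).
    """

    n_zones: int = 5
    n_years: int = 17
    start_year: int = 2006
    init_per_zone: int = 60
    true_window: WindowSpec = WindowSpec(open=8, close=4)
    true_variable: str = "prcp"
    s1_intercepts: tuple[float, ...] | float = -0.2
    s1_climate_slopes: tuple[float, ...] = _graded_slopes(1.0, 5)
    s2_intercepts: tuple[float, ...] | float = -0.2
    s2_size_slope: float = 0.9
    s2_climate_slopes: tuple[float, ...] = _graded_slopes(0.8, 5)
    growth_intercept: float = 0.55
    growth_size_slope: float = 0.82
    growth_climate_slopes: tuple[float, ...] = _graded_slopes(0.2, 5)
    growth_resid_sd: float = 0.25
    flower_intercept: float = -6.5
    flower_size_slope: float = 2.4
    newsize_mean: float = 1.2
    newsize_sd: float = 0.35
    recruit_rate: tuple[float, ...] | float = 7.0
    year_noise_sd: dict[str, float] = field(default_factory=lambda: {
        "S1": 0.3, "S2": 0.3, "G": 0.08, "A": 0.3, "D": 0.08})
    seed: int = 0

    def validate(self) -> None:
        if self.n_zones < 2 or self.n_years < 3:
            raise ValueError("need at least 2 zones and 3 years")
        if self.init_per_zone < 1:
            raise ValueError("init_per_zone must be >= 1")
        if self.growth_resid_sd <= 0 or self.newsize_sd <= 0:
            raise ValueError("residual SDs must be strictly positive")
        if np.any(_per_zone(self.recruit_rate, self.n_zones, "recruit_rate") < 0):
            raise ValueError("recruit_rate must be >= 0")
        for sd in self.year_noise_sd.values():
            if sd < 0:
                raise ValueError("year_noise_sd entries must be >= 0")


def default_params(**overrides) -> GeneratorParams:
    """Default study conditions, optionally overridden field-by-field."""
    return replace(GeneratorParams(), **overrides)


@dataclass
class Truth:
    """Everything a recovery test needs to compare estimates to the truth."""

    params: GeneratorParams
    climate_x: pd.DataFrame        # year_t0, x (window-mean anomaly of true variable)
    year_effects: pd.DataFrame     # year_t0, rate, eps
    rates: pd.DataFrame            # year_t0, zone, rate, n, realized, expected
    anomalies: AnomalySeries

    def linear_predictor(self, rate: str, zone: int, year_t0: int,
                         size: float | None = None) -> float:
        """True latent linear predictor for a cell (before individual noise)."""
        p = self.params
        zi = zone - 1
        x = float(self.climate_x.set_index("year_t0").loc[year_t0, "x"])
        eps = float(self.year_effects.query(
            "year_t0 == @year_t0 and rate == @rate")["eps"].iloc[0])
        if rate == "S1":
            eta = _per_zone(p.s1_intercepts, p.n_zones, "s1")[zi] \
                + p.s1_climate_slopes[zi] * x
        elif rate == "S2":
            eta = _per_zone(p.s2_intercepts, p.n_zones, "s2")[zi] \
                + p.s2_size_slope * size + p.s2_climate_slopes[zi] * x
        elif rate == "G":
            eta = p.growth_intercept + p.growth_size_slope * size \
                + p.growth_climate_slopes[zi] * x
        elif rate == "A":
            eta = p.flower_intercept + p.flower_size_slope * size
        elif rate == "D":
            eta = p.newsize_mean
        else:
            raise ValueError(f"unknown rate {rate!r}")
        return eta + eps


def generate_population(params: GeneratorParams, climate: pd.DataFrame,
                        seed: int | None = None
                        ) -> tuple[pd.DataFrame, Truth]:
    """Simulate the tagged-plant census forward through all study years.

    Each transition year t0 -> t1 proceeds as: flowering plants at t0 seed
    Poisson(recruit_rate * A_zone) new seedlings at t1 and die; each
    vegetative plant survives with the S2 probability, then either flowers
    at t1 (probability A) or grows to a new size (G); each seedling survives
    with the S1 probability and receives a first measured size (D).  Climate
    covariates are standardized with the same machinery the analysis uses,
    so the sliding-window scan sees the generating scale.

    Returns the long-format census table and a :class:`Truth` record.
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    p = params
    years = np.arange(p.start_year, p.start_year + p.n_years)
    cl_years = climate["year"].unique()
    if cl_years.min() > years[0] - 3 or cl_years.max() < years[-1]:
        raise ValueError(
            f"climate must cover [{years[0] - 3}, {years[-1]}]; "
            f"got [{cl_years.min()}, {cl_years.max()}]")
    ref = (int(cl_years.min()), int(cl_years.max()))
    anoms = monthly_anomalies(climate, p.true_variable, ref)
    # Window-mean anomaly for each transition year t0, anchored at the June
    # census of year t1 = t0 + 1.
    x_by_year = {int(t0): window_mean(anoms, int(t0) + 1, p.true_window)
                 for t0 in years[:-1]}

    s1_int = _per_zone(p.s1_intercepts, p.n_zones, "s1_intercepts")
    s2_int = _per_zone(p.s2_intercepts, p.n_zones, "s2_intercepts")
    s1_sl = _per_zone(p.s1_climate_slopes, p.n_zones, "s1_climate_slopes")
    s2_sl = _per_zone(p.s2_climate_slopes, p.n_zones, "s2_climate_slopes")
    g_sl = _per_zone(p.growth_climate_slopes, p.n_zones, "growth_climate_slopes")
    r_zone = _per_zone(p.recruit_rate, p.n_zones, "recruit_rate")

    # Live-plant state arrays.
    if p.init_per_zone * p.n_zones == 0:
        raise ValueError("empty initial population")
    n0 = p.init_per_zone * p.n_zones
    zone = np.repeat(np.arange(1, p.n_zones + 1), p.init_per_zone)
    lo = (0.0 - p.newsize_mean) / p.newsize_sd  # positive ln-size support
    size = truncnorm.rvs(lo, np.inf, loc=p.newsize_mean, scale=p.newsize_sd,
                         size=n0, random_state=rng)
    stage = np.full(n0, STAGE_VEGETATIVE, dtype=object)
    pid = np.arange(n0)
    next_id = n0

    census_rows: list[pd.DataFrame] = []
    rate_rows: list[dict] = []
    eps_rows: list[dict] = []

    def record_census(year: int) -> None:
        sizes = np.where(stage == STAGE_VEGETATIVE, size, np.nan)
        census_rows.append(pd.DataFrame({
            "plant_id": pid, "zone": zone, "year": year,
            "stage": stage, "size": sizes,
        }))

    for t0 in years:
        record_census(int(t0))
        if t0 == years[-1]:
            break
        x = x_by_year[int(t0)]
        eps = {r: rng.normal(0.0, p.year_noise_sd.get(r, 0.0)) for r in RATES}
        for r in RATES:
            eps_rows.append({"year_t0": int(t0), "rate": r, "eps": eps[r]})

        zi = zone - 1
        is_flower = stage == STAGE_FLOWERING
        is_veg = stage == STAGE_VEGETATIVE
        is_seed = stage == STAGE_SEEDLING

        # Recruitment: flowering adults at t0 seed year t1, then die.
        a_counts = np.bincount(zi[is_flower], minlength=p.n_zones)
        n_recruits = rng.poisson(r_zone * a_counts)

        # Vegetative survival, flowering, growth.
        eta_s2 = s2_int[zi] + p.s2_size_slope * size + s2_sl[zi] * x + eps["S2"]
        surv_v = np.zeros(len(pid), dtype=bool)
        surv_v[is_veg] = rng.random(is_veg.sum()) < expit(eta_s2[is_veg])
        eta_a = p.flower_intercept + p.flower_size_slope * size + eps["A"]
        flowers = np.zeros(len(pid), dtype=bool)
        vs = is_veg & surv_v
        flowers[vs] = rng.random(vs.sum()) < expit(eta_a[vs])
        grows = vs & ~flowers
        new_size = np.where(
            grows,
            p.growth_intercept + p.growth_size_slope * size + g_sl[zi] * x
            + eps["G"] + rng.normal(0.0, p.growth_resid_sd, len(pid)),
            size)

        # Seedling survival and first size.
        eta_s1 = s1_int[zi] + s1_sl[zi] * x + eps["S1"]
        surv_s = np.zeros(len(pid), dtype=bool)
        surv_s[is_seed] = rng.random(is_seed.sum()) < expit(eta_s1[is_seed])
        d_draw = rng.normal(p.newsize_mean + eps["D"], p.newsize_sd, len(pid))
        new_size = np.where(is_seed & surv_s, d_draw, new_size)

        # Realized-rate bookkeeping per (year, zone).
        for z in range(1, p.n_zones + 1):
            inz = zone == z
            m = is_seed & inz
            if m.any():
                rate_rows.append({
                    "year_t0": int(t0), "zone": z, "rate": "S1",
                    "n": int(m.sum()), "realized": float(surv_s[m].mean()),
                    "expected": float(expit(eta_s1[m]).mean())})
            m = is_veg & inz
            if m.any():
                rate_rows.append({
                    "year_t0": int(t0), "zone": z, "rate": "S2",
                    "n": int(m.sum()), "realized": float(surv_v[m].mean()),
                    "expected": float(expit(eta_s2[m]).mean())})
            m = vs & inz
            if m.any():
                rate_rows.append({
                    "year_t0": int(t0), "zone": z, "rate": "A",
                    "n": int(m.sum()), "realized": float(flowers[m].mean()),
                    "expected": float(expit(eta_a[m]).mean())})
            m = grows & inz
            if m.any():
                rate_rows.append({
                    "year_t0": int(t0), "zone": z, "rate": "G",
                    "n": int(m.sum()), "realized": float(new_size[m].mean()),
                    "expected": float((p.growth_intercept
                                       + p.growth_size_slope * size[m]
                                       + g_sl[z - 1] * x + eps["G"]).mean())})
            m = is_seed & surv_s & inz
            if m.any():
                rate_rows.append({
                    "year_t0": int(t0), "zone": z, "rate": "D",
                    "n": int(m.sum()), "realized": float(new_size[m].mean()),
                    "expected": p.newsize_mean + eps["D"]})

        # Assemble the t1 state: survivors plus fresh recruits.
        keep = surv_v | surv_s
        n_stage = np.where(flowers, STAGE_FLOWERING, STAGE_VEGETATIVE)
        pid = pid[keep]
        zone = zone[keep]
        size = new_size[keep]
        stage = n_stage[keep].astype(object)

        total_new = int(n_recruits.sum())
        if total_new:
            rec_zone = np.repeat(np.arange(1, p.n_zones + 1), n_recruits)
            rec_id = np.arange(next_id, next_id + total_new)
            next_id += total_new
            pid = np.concatenate([pid, rec_id])
            zone = np.concatenate([zone, rec_zone])
            size = np.concatenate([size, np.full(total_new, np.nan)])
            stage = np.concatenate(
                [stage, np.full(total_new, STAGE_SEEDLING, dtype=object)])

    census = pd.concat(census_rows, ignore_index=True)
    census = census.astype({"plant_id": int, "zone": int, "year": int})
    truth = Truth(
        params=p,
        climate_x=pd.DataFrame(
            {"year_t0": list(x_by_year), "x": list(x_by_year.values())}),
        year_effects=pd.DataFrame(eps_rows),
        rates=pd.DataFrame(rate_rows),
        anomalies=anoms,
    )
    return census, truth


def apply_detection_noise(census: pd.DataFrame, miss_prob: float,
                          seed: int = 0) -> pd.DataFrame:
    """Delete each vegetative record independently with ``miss_prob``.

    Emulates field non-detection (a tag missed in one sweep, found again
    later); the underlying fates are unchanged, so the transition builder's
    gap-handling rules can be tested against the intact table.
    """
    if not (0.0 <= miss_prob < 1.0):
        raise ValueError("miss_prob must be in [0, 1)")
    if miss_prob == 0.0:
        return census.copy()
    rng = np.random.default_rng(seed)
    veg = (census["stage"] == STAGE_VEGETATIVE).to_numpy()
    drop = veg & (rng.random(len(census)) < miss_prob)
    return census.loc[~drop].reset_index(drop=True)
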