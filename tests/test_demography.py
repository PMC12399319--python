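"""Transition building, vital-rate model fits, recruitment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import expit, logit

from dunesync import synthetic as syn
from dunesync.demography import (
    build_transitions,
    cell_prediction_series,
    fit_vital_rate,
    predict_cell,
    rate_observations,
    recruitment,
)


def _census(rows):
    return pd.DataFrame(rows,
                        columns=["plant_id", "zone", "year", "stage", "size"])


class TestBuildTransitions:
    def test_vegetative_to_flowering(self):
        cen = _census([(1, 1, 2010, "vegetative", 2.0),
                       (1, 1, 2011, "flowering", np.nan),
                       (2, 1, 2010, "vegetative", 1.5),
                       (2, 1, 2011, "vegetative", 1.7)])
        tr = build_transitions(cen)
        row = tr[tr["plant_id"] == 1].iloc[0]
        assert (row["survived_t1"], row["flowered_t1"]) == (1, 1)
        assert np.isnan(row["size_t1"])

    def test_long_absence_scored_dead_at_first_missing_year(self):
        rows = [(1, 2, y, "vegetative", 2.0) for y in range(2010, 2013)]
        rows += [(2, 2, y, "vegetative", 2.2) for y in range(2010, 2023)]
        tr = build_transitions(_census(rows))
        p1 = tr[tr["plant_id"] == 1].sort_values("year_t0")
        assert list(p1["survived_t1"]) == [1, 1, 0]
        assert p1["year_t0"].iloc[-1] == 2012  # dead in the 2012->2013 step

    def test_seedling_to_vegetative_yields_s1_and_d(self):
        cen = _census([(1, 3, 2010, "seedling", np.nan),
                       (1, 3, 2011, "vegetative", 1.1),
                       (2, 3, 2010, "vegetative", 2.0),
                       (2, 3, 2011, "vegetative", 2.1)])
        tr = build_transitions(cen)
        s1 = rate_observations(tr, "S1")
        d = rate_observations(tr, "D")
        assert len(s1) == 1 and s1["y"].iloc[0] == 1.0
        assert len(d) == 1 and d["y"].iloc[0] == pytest.approx(1.1)

    def test_refound_after_gap_is_alive_through_gap(self):
        cen = _census([(1, 1, 2010, "vegetative", 2.0),
                       (1, 1, 2012, "vegetative", 2.4),
                       (2, 1, 2010, "vegetative", 1.0),
                       (2, 1, 2011, "vegetative", 1.1),
                       (2, 1, 2012, "vegetative", 1.2)])
        tr = build_transitions(cen)
        p1 = tr[tr["plant_id"] == 1].sort_values("year_t0")
        assert list(p1["year_t0"]) == [2010, 2011]
        assert list(p1["survived_t1"]) == [1, 1]
        assert p1["gap"].tolist() == [False, True]
        # the gap year carries no sizes: no growth observation is fabricated
        assert np.isnan(p1.iloc[0]["size_t1"])
        assert np.isnan(p1.iloc[1]["size_t0"])
        assert p1.iloc[1]["size_t1"] == pytest.approx(2.4)

    def test_duplicate_year_rejected(self):
        cen = _census([(1, 1, 2010, "vegetative", 2.0),
                       (1, 1, 2010, "vegetative", 2.1)])
        with pytest.raises(ValueError, match="duplicate"):
            build_transitions(cen)

    def test_record_after_flowering_rejected(self):
        cen = _census([(1, 1, 2010, "flowering", np.nan),
                       (1, 1, 2011, "vegetative", 2.0)])
        with pytest.raises(ValueError, match="monocarpy"):
            build_transitions(cen)

    def test_detection_noise_gap_relinked(self, census):
        """Records hidden by detection noise re-link across the gap."""
        noisy = syn.apply_detection_noise(census, 0.08, seed=5)
        tr = build_transitions(noisy)
        assert tr["gap"].any()
        gap_rows = tr[tr["gap"]]
        assert (gap_rows["survived_t1"] == 1).all()
        assert gap_rows["size_t0"].isna().all()

    def test_seedling_survivors_equal_newsize_observations(self, transitions):
        """Bookkeeping: surviving seedlings are exactly the D observations."""
        s1 = rate_observations(transitions, "S1")
        d = rate_observations(transitions, "D")
        per_year_s1 = s1[s1["y"] == 1].groupby("year_t0").size()
        per_year_d = d.groupby("year_t0").size()
        pd.testing.assert_series_equal(per_year_s1, per_year_d)


def _bernoulli_cells(rng, p, n_per_cell=65, n_years=16, n_zones=5):
    rows = []
    for y in range(2006, 2006 + n_years):
        for z in range(1, n_zones + 1):
            surv = rng.random(n_per_cell) < p
            for s in surv:
                rows.append((len(rows), z, y, "seedling", np.nan, int(s)))
    df = pd.DataFrame(rows, columns=["plant_id", "zone", "year_t0",
                                     "stage_t0", "size_t0", "survived_t1"])
    df["flowered_t1"] = 0
    df["size_t1"] = np.where(df["survived_t1"] == 1, 1.2, np.nan)
    df["gap"] = False
    return df


class TestFitVitalRate:
    def test_s1_intercept_recovery_flat_world(self, rng):
        tr = _bernoulli_cells(rng, p=0.5)  # ~5200 Bernoulli trials
        fit = fit_vital_rate(tr, "S1")
        assert abs(fit.intercept - 0.0) < 2 * fit.beta_se[0]
        assert fit.vcomp["re_sd"] < 0.15

    def test_all_successes_is_separation_error(self, rng):
        tr = _bernoulli_cells(rng, p=1.1)  # every trial succeeds
        with pytest.raises(ValueError, match="separation"):
            fit_vital_rate(tr, "S1")

    def test_gaussian_growth_recovery(self, rng):
        n = 4000
        size0 = rng.normal(2.0, 0.5, n)
        size1 = 0.3 + 0.9 * size0 + rng.normal(0, 0.1, n)
        tr = pd.DataFrame({
            "plant_id": np.arange(n),
            "zone": rng.integers(1, 6, n),
            "year_t0": rng.integers(2006, 2022, n),
            "stage_t0": "vegetative", "size_t0": size0,
            "survived_t1": 1, "flowered_t1": 0, "size_t1": size1,
            "gap": False})
        fit = fit_vital_rate(tr, "G")
        assert abs(fit.size_slope - 0.9) < 2 * fit.beta_se[1]
        assert abs(fit.resid_sd - 0.1) / 0.1 < 0.10

    def test_bernoulli_predictions_match_raw_fraction(self, vital_fits,
                                                      transitions):
        """Cell predictions, weighted by cell n, reproduce the raw rate."""
        for rate in ("S1", "S2"):
            fit = vital_fits[rate]
            obs = rate_observations(transitions, rate)
            raw = obs["y"].mean()
            weights, preds = [], []
            for (y, z), cell in obs.groupby(["year_t0", "zone"]):
                size = None if rate == "S1" else cell["size"].mean()
                preds.append(predict_cell(fit, y, z, size))
                weights.append(len(cell))
            model_rate = np.average(preds, weights=weights)
            assert abs(model_rate - raw) < 0.05

    def test_prediction_matches_manual_linear_predictor(self, vital_fits):
        fit = vital_fits["S2"]
        y, z = fit.ranef["year_t0"].iloc[3], fit.ranef["zone"].iloc[3]
        b0, b1 = fit._cell_effects(y, z)
        size = fit.size_center + 0.7
        eta = fit.intercept + b0 + (fit.size_slope + b1) * 0.7
        assert predict_cell(fit, y, z, size) == pytest.approx(expit(eta),
                                                              abs=1e-12)

    def test_gaussian_prediction_is_intercept_plus_cell_effect(self,
                                                               vital_fits):
        fit = vital_fits["D"]
        y, z = fit.ranef["year_t0"].iloc[0], fit.ranef["zone"].iloc[0]
        expected = fit.intercept + fit.ranef["b_intercept"].iloc[0]
        assert predict_cell(fit, y, z) == pytest.approx(expected, abs=1e-12)

    def test_unknown_cell_rejected(self, vital_fits):
        with pytest.raises(KeyError):
            predict_cell(vital_fits["S1"], 1899, 1)

    def test_prediction_series_shape(self, vital_fits):
        mat = cell_prediction_series(vital_fits["A"], at="mean+sd")
        assert set(mat.index) == {1, 2, 3, 4, 5}
        assert ((mat.stack() > 0) & (mat.stack() < 1)).all()


class TestRecruitment:
    def test_pooled_ratio_example(self):
        rows = []
        # zone 1: 5 flowering in 2010, 10 seedlings in 2011, none later
        rows += [(i, 1, 2010, "flowering", np.nan) for i in range(5)]
        rows += [(10 + i, 1, 2011, "seedling", np.nan) for i in range(10)]
        rows += [(100, 1, 2012, "vegetative", 2.0)]
        tr = _census(rows)
        assert recruitment(tr).loc[1] == pytest.approx(2.0)

    def test_no_seedlings_gives_zero(self):
        rows = [(i, 1, 2010, "flowering", np.nan) for i in range(4)]
        rows += [(50, 1, 2011, "vegetative", 2.0)]
        assert recruitment(_census(rows)).loc[1] == 0.0

    def test_zone_without_flowering_adults_errors(self):
        rows = [(1, 1, 2010, "flowering", np.nan),
                (2, 1, 2011, "seedling", np.nan),
                (3, 2, 2010, "vegetative", 2.0),
                (4, 2, 2011, "vegetative", 2.1)]
        with pytest.raises(ValueError, match="no flowering adults"):
            recruitment(_census(rows))

    def test_estimate_within_poisson_bounds_of_truth(self, climate_table):
        true_r = 5.0
        p = syn.default_params(recruit_rate=true_r, n_years=10,
                               init_per_zone=80)
        census, _ = syn.generate_population(p, climate_table, seed=13)
        est = recruitment(census)
        adults = census[(census["stage"] == "flowering")
                        & (census["year"] < census["year"].max())]
        for z, r_hat in est.items():
            n_adults = (adults["zone"] == z).sum()
            lo, hi = stats.poisson.interval(0.95, true_r * n_adults)
            assert lo / n_adults <= r_hat <= hi / n_adults
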