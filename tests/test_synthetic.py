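"""Generator contracts: determinism, life-cycle invariants, truth recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dunesync import synthetic as syn
from dunesync.climate import monthly_anomalies


class TestGenerateClimate:
    def test_deterministic_given_seed(self):
        a = syn.generate_climate(1990, 20, seed=5)
        b = syn.generate_climate(1990, 20, seed=5)
        pd.testing.assert_frame_equal(a, b)
        c = syn.generate_climate(1990, 20, seed=6)
        assert not a["prcp"].equals(c["prcp"])

    def test_near_degenerate_noise_reproduces_seasonal_means(self):
        params = syn.ClimateGenParams(
            prcp_sd=(1e-9,) * 12, tmean_sd=(1e-9,) * 12,
            temp_extreme_sd=1e-9)
        cl = syn.generate_climate(2000, 5, params=params, seed=0,
                                  include_drought_index=False)
        jan = cl[cl["month"] == 1]
        assert np.allclose(jan["prcp"], params.prcp_mean[0], atol=1e-6)
        assert np.allclose(jan["tmean"], params.tmean_mean[0], atol=1e-6)

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            syn.generate_climate(2000, 5,
                                 params=syn.ClimateGenParams(prcp_sd=(0.0,) * 12))

    def test_monthly_means_within_clt_bound(self):
        n_years = 40
        cl = syn.generate_climate(1980, n_years, seed=3)
        params = syn.ClimateGenParams()
        for m in range(1, 13):
            vals = cl.loc[cl["month"] == m, "tmean"]
            bound = 4 * params.tmean_sd[m - 1] / np.sqrt(n_years)
            assert abs(vals.mean() - params.tmean_mean[m - 1]) < bound

    def test_drought_index_standardized_per_month(self):
        cl = syn.generate_climate(1980, 40, seed=3)
        for m in (1, 6, 12):
            z = cl.loc[cl["month"] == m, "drought_index"]
            assert z.mean() == pytest.approx(0.0, abs=1e-10)
            assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-10)


class TestGeneratePopulation:
    def test_deterministic_given_seed(self, climate_table):
        p = syn.default_params(n_years=6, init_per_zone=20)
        a, _ = syn.generate_population(p, climate_table, seed=9)
        b, _ = syn.generate_population(p, climate_table, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_monocarpy_no_record_after_flowering(self, census):
        flowering_year = census[census["stage"] == "flowering"] \
            .set_index("plant_id")["year"]
        merged = census.join(flowering_year.rename("fl_year"), on="plant_id")
        after = merged[merged["fl_year"].notna()
                       & (merged["year"] > merged["fl_year"])]
        assert len(after) == 0

    def test_plant_id_unique_per_year(self, census):
        assert not census.duplicated(subset=["plant_id", "year"]).any()

    def test_stage_progression(self, census):
        order = {"seedling": 0, "vegetative": 1, "flowering": 2}
        ranks = census.assign(rank=census["stage"].map(order)) \
            .sort_values(["plant_id", "year"])
        # stages never move backwards and never skip seedling -> flowering
        for _, g in ranks.groupby("plant_id"):
            r = g["rank"].to_numpy()
            assert (np.diff(r) >= 0).all()
            assert not np.any((r[:-1] == 0) & (r[1:] == 2))

    def test_size_present_iff_vegetative(self, census):
        veg = census["stage"] == "vegetative"
        assert census.loc[veg, "size"].notna().all()
        assert census.loc[~veg, "size"].isna().all()

    def test_conservation_vegetative_inflows(self, census):
        """Every vegetative plant was a seedling or vegetative the year before."""
        years = np.sort(census["year"].unique())
        by_year = {y: g.set_index("plant_id") for y, g in census.groupby("year")}
        for t0, t1 in zip(years[:-1], years[1:]):
            veg_t1 = by_year[t1][by_year[t1]["stage"] == "vegetative"]
            prev = by_year[t0].reindex(veg_t1.index)
            assert prev["stage"].isin(["seedling", "vegetative"]).all()

    def test_realized_rates_match_census_frequencies(self, census, truth):
        """The generator's returned realized S1 equals the census recount."""
        years = np.sort(census["year"].unique())
        by_year = {y: g.set_index("plant_id") for y, g in census.groupby("year")}
        s1 = truth.rates.query("rate == 'S1'")
        for _, row in s1.sample(25, random_state=0).iterrows():
            t0, z = int(row["year_t0"]), int(row["zone"])
            g0 = by_year[t0]
            seedlings = g0[(g0["stage"] == "seedling") & (g0["zone"] == z)]
            survivors = seedlings.index.intersection(by_year[t0 + 1].index)
            assert len(seedlings) == row["n"]
            assert len(survivors) / len(seedlings) == pytest.approx(
                row["realized"])

    def test_invlogit_zero_gives_half_survival(self, climate_table):
        p = syn.default_params(
            s1_intercepts=0.0, s1_climate_slopes=(0.0,) * 5,
            year_noise_sd={"S1": 0.0, "S2": 0.3, "G": 0.08, "A": 0.3,
                           "D": 0.08},
            init_per_zone=200, n_years=8)
        _, truth = syn.generate_population(p, climate_table, seed=1)
        s1 = truth.rates.query("rate == 'S1'")
        n = s1["n"].sum()
        successes = (s1["realized"] * s1["n"]).sum()
        lo, hi = stats.binom.interval(0.999, n, 0.5)
        assert lo <= successes <= hi

    def test_zero_recruitment_extinguishes_seedlings(self, climate_table):
        p = syn.default_params(recruit_rate=0.0, n_years=6, init_per_zone=30)
        census, _ = syn.generate_population(p, climate_table, seed=2)
        later = census[census["year"] > census["year"].min()]
        assert (later["stage"] != "seedling").all()

    def test_empty_initial_population_rejected(self, climate_table):
        with pytest.raises(ValueError):
            syn.generate_population(
                syn.default_params(init_per_zone=0), climate_table, seed=0)

    def test_climate_coverage_gap_rejected(self):
        short = syn.generate_climate(2005, 10, seed=0)
        with pytest.raises(ValueError, match="climate must cover"):
            syn.generate_population(syn.default_params(start_year=2006),
                                    short, seed=0)

    def test_opposite_slopes_make_zone15_rates_anticorrelated(
            self, climate_table):
        """Across replicates, realized S1 of zones 1 and 5 mostly disagree."""
        p = syn.default_params(
            n_years=12, init_per_zone=80,
            s1_climate_slopes=(-1.0, -0.5, 0.0, 0.5, 1.0),
            year_noise_sd={"S1": 0.1, "S2": 0.3, "G": 0.08, "A": 0.3,
                           "D": 0.08})
        neg = 0
        n_rep = 200
        for seed in range(n_rep):
            _, truth = syn.generate_population(p, climate_table, seed=seed)
            s1 = truth.rates.query("rate == 'S1'")
            piv = s1.pivot(index="year_t0", columns="zone",
                           values="realized")
            if piv[[1, 5]].dropna().shape[0] >= 5:
                r = piv[1].corr(piv[5])
                neg += r < 0
        assert neg > 0.6 * n_rep


class TestDetectionNoise:
    def test_zero_miss_prob_is_identity(self, census):
        out = syn.apply_detection_noise(census, 0.0, seed=1)
        pd.testing.assert_frame_equal(out, census)

    def test_deleted_fraction_within_binomial_bounds(self, census):
        miss = 0.1
        out = syn.apply_detection_noise(census, miss, seed=0)
        n_veg = (census["stage"] == "vegetative").sum()
        removed = n_veg - (out["stage"] == "vegetative").sum()
        lo, hi = stats.binom.interval(0.99, n_veg, miss)
        assert lo <= removed <= hi
        # non-vegetative records untouched
        assert (out["stage"] != "vegetative").sum() \
            == (census["stage"] != "vegetative").sum()

    def test_invalid_probability_rejected(self, census):
        with pytest.raises(ValueError):
            syn.apply_detection_noise(census, 1.0)
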