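"""Synthetic study-system generators: demography, climate, landscape,
space use, foraging and model-generated dyadic outcomes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sympatry import environment as env
from sympatry.synth import (
    ForagingConfig,
    LandscapeConfig,
    gen_climate,
    gen_demography,
    gen_foraging,
    gen_landscape,
    gen_mm_data,
    gen_space_use,
    gen_srm_data,
)
from sympatry.synth.movement import mixture_product_integral, simulate_ou
from sympatry.truth import GenerativeTruth, SRMTruth


class TestDemography:
    def test_census_structure_matches_study_population(self, truth):
        dem = gen_demography(12, range(1991, 2024), truth, seed=1)
        assert set(dem["season"]) == {"dry", "wet"}
        assert dem["size"].between(5, 40).all()
        assert 15 <= dem["size"].mean() <= 23
        # one record per group x year x season
        assert not dem.duplicated(["group_id", "year", "season"]).any()

    def test_zero_variance_walk_keeps_sizes_constant(self):
        truth = GenerativeTruth(size_walk_sd=0.0)
        dem = gen_demography(2, range(2000, 2010), truth, seed=3)
        assert (dem.groupby("group_id")["size"].nunique() == 1).all()

    def test_identical_seed_gives_byte_identical_tables(self, truth):
        a = gen_demography(5, range(2000, 2010), truth, seed=7)
        b = gen_demography(5, range(2000, 2010), truth, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_fission_creates_daughter_groups(self):
        truth = GenerativeTruth(fission_rate=0.1)
        dem = gen_demography(4, range(2000, 2020), truth, seed=5)
        assert dem["group_id"].nunique() > 4

    @pytest.mark.parametrize("bad", [([], 4), (range(2000, 2005), 1)])
    def test_rejects_degenerate_inputs(self, truth, bad):
        years, n_groups = bad
        with pytest.raises(ValueError):
            gen_demography(n_groups, years, truth, seed=0)


class TestClimate:
    def test_standardization_within_season(self, climate):
        for _, grp in climate.groupby("season"):
            assert abs(grp["spei_z"].mean()) < 1e-9
            assert abs(grp["spei_z"].std(ddof=1) - 1) < 1e-9

    def test_single_year_rejected(self, truth):
        with pytest.raises(ValueError):
            gen_climate([2000], truth, seed=0)

    def test_ar1_autocorrelation_recovered(self):
        truth = GenerativeTruth(spei_ar=0.6)
        clim = gen_climate(range(1000, 2000), truth, seed=11)
        x = clim["spei_raw"].to_numpy()
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r1 - 0.6) < 0.05

    def test_deterministic(self, truth):
        a = gen_climate(range(2000, 2010), truth, seed=9)
        b = gen_climate(range(2000, 2010), truth, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestLandscape:
    def test_dry_greenness_tracks_riparian_gradient(self, landscape):
        comp = env.seasonal_composite(landscape.scenes, 2010, "dry")
        ok = ~np.isnan(comp.values)
        rho = stats.spearmanr(
            comp.values[ok], landscape.riparian_distance.values[ok]
        ).statistic
        assert rho < -0.3

    def test_wet_season_flatter_than_dry(self, landscape):
        dry = env.seasonal_composite(landscape.scenes, 2010, "dry")
        wet = env.seasonal_composite(landscape.scenes, 2010, "wet")
        assert np.nanstd(wet.values) < np.nanstd(dry.values)

    def test_zero_qa_fraction_flags_nothing(self):
        cfg = LandscapeConfig(nx=60, ny=60, years=[2015], qa_fraction=0.0)
        stack = gen_landscape(cfg, seed=2)
        assert all(not s.qa.values.any() for s in stack.scenes)

    def test_reflectances_bounded_and_geometry_shared(self, landscape):
        for s in landscape.scenes[:4]:
            assert s.red.grid == landscape.grid
            assert 0 <= s.red.values.min() and s.red.values.max() <= 1
            assert 0 <= s.nir.values.min() and s.nir.values.max() <= 1

    @pytest.mark.parametrize(
        "kwargs", [{"cell": 0.0}, {"cell": -3.0}, {"nx": 30, "ny": 30}]
    )
    def test_rejects_bad_grid(self, kwargs):
        with pytest.raises(ValueError):
            gen_landscape(LandscapeConfig(**kwargs), seed=0)


class TestSpaceUse:
    def test_area_slope_encoded_in_true_areas(self, landscape, truth):
        # >= 200 group-seasons so OLS pins the generative slope
        dem = gen_demography(10, range(2000, 2012), truth, seed=8)
        clim = gen_climate(range(2000, 2012), truth, seed=8)
        su = gen_space_use(dem, landscape, clim, truth, seed=8)
        tab = su.ud_table()
        assert len(tab) >= 200
        wet = (tab["season"] == "wet").astype(float)
        X = np.column_stack([np.ones(len(tab)), tab["size_z"], wet])
        beta = np.linalg.lstsq(X, np.log(tab["area95_true"]), rcond=None)[0]
        assert abs(beta[1] - truth.beta_size_hra) < 0.05

    def test_null_area_slope_recovered_near_zero(self, landscape):
        truth = GenerativeTruth(beta_size_hra=0.0)
        dem = gen_demography(10, range(2000, 2012), truth, seed=8)
        clim = gen_climate(range(2000, 2012), truth, seed=8)
        tab = gen_space_use(dem, landscape, clim, truth, seed=8).ud_table()
        wet = (tab["season"] == "wet").astype(float)
        X = np.column_stack([np.ones(len(tab)), tab["size_z"], wet])
        beta = np.linalg.lstsq(X, np.log(tab["area95_true"]), rcond=None)[0]
        assert abs(beta[1]) < 0.05

    def test_ou_stationary_sd(self, rng):
        pts = simulate_ou(np.zeros(2), sd=120.0, tau=600.0, dt_s=30.0,
                          n_steps=100_000, rng=rng)
        assert abs(pts[:, 0].std() - 120.0) / 120.0 < 0.05
        assert abs(pts[:, 1].std() - 120.0) / 120.0 < 0.05

    def test_trajectories_time_ordered_with_sleep_sites(self, space_use):
        for _, day in space_use.trajectories.groupby(["group_id", "date"]):
            assert (np.diff(day["t"]) > 0).all()
        assert len(space_use.sleep_sites) > 0

    def test_mixture_product_integral_matches_quadrature(self, space_use):
        a, b = space_use.ud_specs[0], space_use.ud_specs[1]
        closed = mixture_product_integral(a, b)
        grid = np.linspace(-6000, 12000, 901)
        X, Y = np.meshgrid(grid, grid)
        pts = np.column_stack([X.ravel(), Y.ravel()])
        cell = (grid[1] - grid[0]) ** 2
        numeric = float((a.density_at(pts) * b.density_at(pts)).sum() * cell)
        assert closed == pytest.approx(numeric, rel=1e-3)

    def test_deterministic(self, demography, landscape, climate, truth):
        a = gen_space_use(demography, landscape, climate, truth, seed=5)
        b = gen_space_use(demography, landscape, climate, truth, seed=5)
        pd.testing.assert_frame_equal(a.ud_table(), b.ud_table())
        pd.testing.assert_frame_equal(a.trajectories, b.trajectories)


class TestForaging:
    def test_intake_slope_recovered_by_offset_regression(self, truth):
        dem = gen_demography(12, range(2000, 2010), truth, seed=4)
        clim = gen_climate(range(2000, 2010), truth, seed=4)
        f = gen_foraging(dem, clim, truth, seed=4,
                         config=ForagingConfig(individuals_per_group=15,
                                               follows_per_individual_season=2))
        assert len(f) >= 5000
        # quasi-likelihood oracle: log-rate regression with offset
        d = f[f["season"] == "dry"]
        y = np.log((d["bites"] + 0.5) / d["seconds_in_view"])
        X = np.column_stack(
            [np.ones(len(d)), d["size_z"], d["spei_z"], d["size_z"] * d["spei_z"]]
        )
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert abs(beta[1] - truth.beta_size_intake) < 0.05

    def test_poisson_limit_of_dispersion(self, rng):
        # gamma-Poisson mixture converges to Poisson as dispersion grows
        r, mu = 1e9, 7.0
        lam = rng.gamma(shape=r, scale=mu / r, size=100_000)
        draws = rng.poisson(lam)
        assert abs(draws.var() / draws.mean() - 1.0) < 0.1

    def test_offset_scales_expected_bites(self, truth, rng):
        # the generative mean is rate x seconds: doubling exposure doubles it
        base = np.exp(truth.intake_log_rate)
        assert base * 2400.0 == pytest.approx(2 * base * 1200.0)

    def test_records_have_positive_exposure(self, demography, climate, truth):
        f = gen_foraging(demography, climate, truth, seed=1,
                         config=ForagingConfig(individuals_per_group=3,
                                               follows_per_individual_season=1))
        assert (f["seconds_in_view"] > 0).all()
        assert (f["bites"] >= 0).all()


class TestSRMGenerator:
    def test_hurdle_rate_under_flat_truth(self, demography):
        srm = SRMTruth(
            hurdle_intercept=-1.0, hurdle_focal=0, hurdle_neighbour=0,
            hurdle_fn=0, hurdle_dry=0, beta_focal=0, beta_neighbour=0,
            beta_fn=0, beta_dry=0, beta_neighbour_dry=0,
            sd_focal=1e-6, sd_neighbour=1e-6, sd_dyad=1e-6,
        )
        truth = GenerativeTruth(srm=srm)
        big = gen_demography(12, range(2000, 2040), truth, seed=6)
        df = gen_srm_data(truth, big, seed=6, seasonal=False)
        n = len(df)
        assert n > 4000
        p0 = 1 / (1 + np.exp(1.0))  # expit(-1): truth zero probability
        se = np.sqrt(p0 * (1 - p0) / n)
        assert abs((df["po"] == 0).mean() - p0) < 2.5 * se

    def test_within_dyad_effect_correlation(self):
        truth = GenerativeTruth()
        truth.srm.rho_dd = 0.9
        dem = gen_demography(65, range(2010, 2012), truth, seed=9)
        _, eff = gen_srm_data(truth, dem, seed=9, return_effects=True)
        pairs = sorted({tuple(sorted(k)) for k in eff["d"]})
        assert len(pairs) >= 2000
        d01 = np.array([[eff["d"][(a, b)], eff["d"][(b, a)]] for a, b in pairs])
        r = np.corrcoef(d01[:, 0], d01[:, 1])[0, 1]
        assert 0.85 < r < 0.95

    def test_neighbour_slope_recovered_on_logit_scale(self):
        truth = GenerativeTruth()
        truth.srm.beta_neighbour = 0.5
        truth.srm.beta_fn = 0.0
        truth.srm.hurdle_intercept = -4.0  # almost no zeros
        dem = gen_demography(15, range(2000, 2020), truth, seed=10)
        df = gen_srm_data(truth, dem, seed=10, seasonal=False)
        d = df[df["po"] > 0]
        y = np.log(d["po"] / (1 - d["po"]))
        X = np.column_stack([np.ones(len(d)), d["focal_size_z"], d["neighbour_size_z"]])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        assert abs(beta[2] - 0.5) < 0.1

    def test_double_entry_and_bounds(self, truth, demography):
        df = gen_srm_data(truth, demography, seed=2)
        assert ((df["po"] >= 0) & (df["po"] < 1)).all()
        keyed = set(zip(df["focal_id"], df["neighbour_id"], df["period"]))
        assert all((n, f, t) in keyed for f, n, t in keyed)

    def test_invalid_correlation_rejected(self, demography):
        truth = GenerativeTruth()
        truth.srm.rho_dd = 1.0
        with pytest.raises(ValueError):
            gen_srm_data(truth, demography, seed=0)


class TestMMGenerator:
    def test_rows_are_symmetric_pair_periods(self, truth, demography):
        df = gen_mm_data(truth, demography, seed=3)
        assert (df["er"] > 0).all()
        assert (df["log_er_se"] > 0).all()
        assert not df.duplicated(["dyad_id", "period"]).any()

    def test_area_slope_present_in_generated_response(self, truth):
        dem = gen_demography(15, range(2000, 2015), truth, seed=12)
        df = gen_mm_data(truth, dem, seed=12, seasonal=True)
        wet = df[df["season"] == "wet"]
        X = np.column_stack([np.ones(len(wet)), wet["overlap_area_z"],
                             wet["overlap_ndvi_z"], wet["size_diff_z"]])
        beta = np.linalg.lstsq(X, wet["log_er"], rcond=None)[0]
        assert abs(beta[1] - truth.mm.b_area) < 0.1


class TestTruthConfig:
    def test_yaml_round_trip(self, truth, tmp_path):
        path = tmp_path / "truth.yaml"
        truth.to_yaml(path)
        again = GenerativeTruth.from_yaml(path)
        assert again == truth

    def test_validation_rejects_bad_values(self):
        bad = GenerativeTruth()
        bad.srm.sd_dyad = -1.0
        with pytest.raises(ValueError):
            bad.validate()
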