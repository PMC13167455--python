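"""Posterior machinery: HPDI, hurdle-beta density, model fits."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from sympatry.bayes import (
    GroupModelSpec,
    MMSpec,
    SRMSpec,
    fit_encounter_mm,
    fit_group_glmm,
    fit_srm,
    hpdi,
    hurdle_beta_loglik,
    marginal_slope,
    seasonal_contrast,
    summarize,
)
from sympatry.bayes.engine import PosteriorSummary
from sympatry.bayes.glmm import coef_draws, size_slope_draws
from sympatry.bayes.mm import mm_coef_draws, season_slope_contrast
from sympatry.bayes.srm import neighbour_slope_draws
from sympatry.synth import ForagingConfig, gen_foraging, gen_mm_data, gen_srm_data
from sympatry.truth import GenerativeTruth


class TestHPDI:
    def test_uniform_interval_width(self, rng):
        x = rng.uniform(0, 1, 100_000)
        lo, hi = hpdi(x, 0.89)
        assert abs((hi - lo) - 0.89) < 0.02

    def test_symmetric_unimodal_close_to_equal_tailed(self, rng):
        x = rng.normal(0, 1, 100_000)
        lo, hi = hpdi(x, 0.89)
        qlo, qhi = np.quantile(x, [0.055, 0.945])
        assert abs(lo - qlo) < 0.05 and abs(hi - qhi) < 0.05

    def test_point_mass_zero_width(self):
        lo, hi = hpdi(np.full(1000, 3.7), 0.89)
        assert lo == hi == 3.7

    def test_summary_invariants(self, rng):
        s = summarize(rng.normal(0.5, 0.1, 4000), "x")
        assert s.hpdi89[0] <= s.median <= s.hpdi89[1]
        assert 0 <= s.pp_gt0 <= 1

    def test_inconsistent_summary_rejected(self):
        with pytest.raises(ValueError):
            PosteriorSummary("bad", 5.0, (0.0, 1.0), 0.5)


class TestHurdleBetaDensity:
    def test_zero_branch(self):
        assert hurdle_beta_loglik(0.0, 0.3, 0.5, 4.0) == pytest.approx(
            np.log(0.3), abs=1e-12
        )

    def test_positive_branch_beta22(self):
        # Beta(2,2) density at 0.5 is 1.5
        got = hurdle_beta_loglik(0.5, 0.3, 0.5, 4.0)
        assert got == pytest.approx(np.log(0.7) + np.log(1.5), abs=1e-12)

    def test_total_mass_is_one(self):
        theta, mu, phi = 0.3, 0.6, 9.0
        dens = lambda x: np.exp(hurdle_beta_loglik(x, theta, mu, phi))
        cont, _ = integrate.quad(dens, 1e-12, 1 - 1e-12, limit=200)
        assert theta + cont == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"po": -0.1, "theta": 0.5, "mu": 0.5, "phi": 2.0},
            {"po": 0.5, "theta": 1.5, "mu": 0.5, "phi": 2.0},
            {"po": 0.5, "theta": 0.5, "mu": 0.0, "phi": 2.0},
            {"po": 0.5, "theta": 0.5, "mu": 0.5, "phi": -1.0},
        ],
    )
    def test_domain_violations_rejected(self, kwargs):
        with pytest.raises(ValueError):
            hurdle_beta_loglik(**kwargs)

    def test_permutation_invariance_of_joint_loglik(self, rng):
        pos = rng.beta(2, 3, 50)
        pos[rng.random(50) < 0.3] = 0.0
        ll = [hurdle_beta_loglik(float(x), 0.3, 0.4, 6.0) for x in pos]
        assert sum(ll) == pytest.approx(sum(reversed(ll)), abs=1e-12)


@pytest.fixture(scope="module")
def glmm_fit(demography_mod, climate_mod, truth_mod):
    f = gen_foraging(
        demography_mod, climate_mod, truth_mod, seed=21,
        config=ForagingConfig(individuals_per_group=8, follows_per_individual_season=1),
    )
    spec = GroupModelSpec(
        response="bites", family="negative_binomial", offset="seconds_in_view",
        seasonal=True, spei=True, extra_varying="individual_id",
    )
    return fit_group_glmm(spec, f, seed=21)


@pytest.fixture(scope="module")
def truth_mod():
    return GenerativeTruth()


@pytest.fixture(scope="module")
def demography_mod(truth_mod):
    from sympatry.synth import gen_demography

    return gen_demography(10, range(2008, 2016), truth_mod, seed=21)


@pytest.fixture(scope="module")
def climate_mod(truth_mod):
    from sympatry.synth import gen_climate

    return gen_climate(range(2008, 2016), truth_mod, seed=21)


class TestGroupGLMM:
    def test_size_slope_recovered(self, glmm_fit, truth_mod):
        lo, hi = hpdi(coef_draws(glmm_fit, "b_size"))
        # generous window around the generative slope
        assert lo - 0.15 < truth_mod.beta_size_intake < hi + 0.15
        assert np.median(coef_draws(glmm_fit, "b_size")) < 0

    def test_marginal_slope_linearity_per_draw(self, glmm_fit):
        s_lo = size_slope_draws(glmm_fit, "dry", -1.5)
        s_mid = size_slope_draws(glmm_fit, "dry", 0.0)
        s_hi = size_slope_draws(glmm_fit, "dry", 1.5)
        np.testing.assert_allclose(s_mid, 0.5 * (s_lo + s_hi), atol=1e-12)

    def test_seasonal_contrast_antisymmetry(self, glmm_fit):
        wet_minus_dry = size_slope_draws(glmm_fit, "wet", 0.0) - size_slope_draws(
            glmm_fit, "dry", 0.0
        )
        c = seasonal_contrast(glmm_fit)
        assert c.median == pytest.approx(float(np.median(wet_minus_dry)))
        np.testing.assert_allclose(wet_minus_dry, -(-wet_minus_dry))

    def test_no_interaction_model_slope_constant_in_spei(
        self, demography_mod, climate_mod, truth_mod
    ):
        f = gen_foraging(
            demography_mod, climate_mod, truth_mod, seed=22,
            config=ForagingConfig(individuals_per_group=4,
                                  follows_per_individual_season=1),
        )
        spec = GroupModelSpec(
            response="bites", family="negative_binomial", offset="seconds_in_view",
            seasonal=True, spei=False, extra_varying="individual_id",
        )
        fit = fit_group_glmm(spec, f, seed=22)
        np.testing.assert_array_equal(
            size_slope_draws(fit, "dry", 0.0), size_slope_draws(fit, "dry", 1.5)
        )

    def test_beta_family_nudges_boundary_values(self, demography_mod):
        n = len(demography_mod)
        data = demography_mod.copy()
        rng = np.random.default_rng(5)
        data["resp"] = rng.beta(5, 5, n)
        data.loc[data.index[:3], "resp"] = 0.0
        data.loc[data.index[3:5], "resp"] = 1.0
        fit = fit_group_glmm(
            GroupModelSpec(response="resp", family="beta", seasonal=True), data, seed=1
        )
        assert fit.meta["n_nudged"] == 5

    def test_gamma_measurement_error_limit(self, demography_mod, rng):
        data = demography_mod.copy()
        mu = np.exp(14.0 + 0.3 * data["size_z"])
        data["resp"] = rng.gamma(25.0, mu / 25.0)
        data["tiny_se"] = 1e-4
        spec_me = GroupModelSpec(response="resp", family="gamma", me_se="tiny_se")
        spec_plain = GroupModelSpec(response="resp", family="gamma")
        b_me = np.median(coef_draws(fit_group_glmm(spec_me, data, seed=2), "b_size"))
        b_plain = np.median(
            coef_draws(fit_group_glmm(spec_plain, data, seed=2), "b_size")
        )
        assert b_me == pytest.approx(b_plain, abs=0.02)

    def test_bad_spec_rejected(self):
        with pytest.raises(ValueError):
            GroupModelSpec(response="y", family="poisson")
        with pytest.raises(ValueError):
            GroupModelSpec(response="y", family="gamma", seasonal=False, spei=True)


class TestSRMFit:
    def test_double_entry_violation_detected(self, truth_mod, demography_mod):
        df = gen_srm_data(truth_mod, demography_mod, seed=30, seasonal=True)
        broken = df.drop(df.index[0])
        with pytest.raises(ValueError, match="double-entry"):
            fit_srm(SRMSpec(seasonal=True), broken, seed=0)

    def test_all_zero_po_reverts_beta_branch_to_prior(self, truth_mod, demography_mod):
        df = gen_srm_data(truth_mod, demography_mod, seed=31, seasonal=False)
        df = df.assign(po=0.0)
        fit = fit_srm(SRMSpec(), df, seed=31, refine_hypers=False)
        names = fit.meta["coef_names"]
        for name in ("b_focal", "b_neighbour", "b_fn"):
            draws = fit["beta"][:, names.index(name)]
            m, s = float(draws.mean()), float(draws.std())
            # overlap coefficient between fitted N(m, s) and the N(0,1) prior
            grid_x = np.linspace(-5, 5, 2001)
            ovl = np.trapezoid(
                np.minimum(stats.norm.pdf(grid_x, m, s), stats.norm.pdf(grid_x)),
                grid_x,
            )
            assert ovl > 0.8

    def test_conditional_slope_monotone_when_interaction_negative(
        self, truth_mod, demography_mod
    ):
        df = gen_srm_data(truth_mod, demography_mod, seed=32, seasonal=True)
        fit = fit_srm(SRMSpec(seasonal=True), df, seed=32, refine_hypers=False)
        s8 = neighbour_slope_draws(fit, 8.0)
        s35 = neighbour_slope_draws(fit, 35.0)
        # per-draw: s8 - s35 = (z8 - z35) b_fn and z8 < z35, so the sign of
        # the difference is opposite to the interaction's sign (up to
        # floating-point cancellation for draws with b_fn ~ 0)
        b_fn = fit["beta"][:, fit.meta["coef_names"].index("b_fn")]
        mask = np.abs(b_fn) > 1e-8
        np.testing.assert_array_equal(np.sign((s8 - s35))[mask], -np.sign(b_fn)[mask])


class TestMMFit:
    def test_label_swap_posterior_identical(self, truth_mod, demography_mod):
        df = gen_mm_data(truth_mod, demography_mod, seed=40, seasonal=True)
        swapped = df.rename(columns={"group_1": "group_2", "group_2": "group_1"})
        fit_a = fit_encounter_mm(MMSpec(seasonal=True), df, seed=7)
        fit_b = fit_encounter_mm(MMSpec(seasonal=True), swapped, seed=7)
        np.testing.assert_array_equal(fit_a["beta"], fit_b["beta"])

    def test_inflated_ses_widen_posteriors(self, truth_mod, demography_mod):
        df = gen_mm_data(truth_mod, demography_mod, seed=41, seasonal=True)
        fit_tight = fit_encounter_mm(MMSpec(seasonal=True), df, seed=8)
        df_wide = df.assign(log_er_se=df["log_er_se"] * 100.0)
        fit_wide = fit_encounter_mm(MMSpec(seasonal=True), df_wide, seed=8)
        for name in ("b_area", "b_ndvi", "b_size_diff"):
            lo1, hi1 = hpdi(mm_coef_draws(fit_tight, name))
            lo2, hi2 = hpdi(mm_coef_draws(fit_wide, name))
            assert (hi2 - lo2) > (hi1 - lo1)

    def test_season_contrast_is_negated_dry_modifier(self, truth_mod, demography_mod):
        df = gen_mm_data(truth_mod, demography_mod, seed=42, seasonal=True)
        fit = fit_encounter_mm(MMSpec(seasonal=True), df, seed=9)
        c = season_slope_contrast(fit, "area")
        np.testing.assert_allclose(
            -mm_coef_draws(fit, "b_area_dry"),
            mm_coef_draws(fit, "b_area_dry") * -1,
        )
        assert c.median == pytest.approx(
            float(np.median(-mm_coef_draws(fit, "b_area_dry")))
        )

    def test_nonpositive_se_rejected(self, truth_mod, demography_mod):
        df = gen_mm_data(truth_mod, demography_mod, seed=43)
        df.loc[df.index[0], "log_er_se"] = 0.0
        with pytest.raises(ValueError):
            fit_encounter_mm(MMSpec(), df, seed=0)
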