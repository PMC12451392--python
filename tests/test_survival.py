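"""Exponential survival fits: conjugate oracles, imputation, derived TT."""

import math

import numpy as np
import pytest

import cullwelfare as cw
from cullwelfare.mcmc import GammaPrior, SamplerSettings
from cullwelfare.survival import (
    compare_models,
    derive_tt,
    fit_exponential,
    percentile,
    survival_curve,
)

FAST = SamplerSettings(n_chains=4, n_draws=2000, n_burn=600, seed=17)


def censor_independently(rng, t, frac):
    """Independent out-of-view times calibrated to censor ``frac`` of rows."""
    lam_hat = 1.0 / t.mean()
    c_time = rng.exponential((1 - frac) / (lam_hat * frac), size=t.size)
    cens = c_time < t
    return np.where(cens, c_time, t), cens


class TestUncensoredConjugacy:
    def test_pooled_posterior_matches_gamma_closed_form(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(1 / 0.07, size=200)
        prior = GammaPrior(shape=2.0, rate=10.0)
        fit = fit_exponential(t, covariate_mode="pooled", priors=prior, settings=FAST)
        lam = fit.rate_draws()
        closed_mean = (prior.shape + t.size) / (prior.rate + t.sum())
        closed_sd = math.sqrt(prior.shape + t.size) / (prior.rate + t.sum())
        se = closed_sd / math.sqrt(lam.size)  # draws are iid conjugate Gibbs
        assert lam.mean() == pytest.approx(closed_mean, abs=5 * se)
        assert lam.std() == pytest.approx(closed_sd, rel=0.05)

    def test_zero_censoring_bypasses_imputation(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10.0, size=50)
        fit = fit_exponential(t, covariate_mode="pooled", settings=FAST)
        assert fit.imputed.size == 0
        assert fit.censored_index.size == 0

    def test_single_observation_order_of_magnitude(self):
        fit = fit_exponential([20.0], covariate_mode="pooled", settings=FAST)
        assert 1 / 200 < fit.rate_draws().mean() < 10 / 20


class TestCensoredImputation:
    def test_imputed_values_respect_interval_bounds(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(1 / 0.0697, size=200)
        obs, cens = censor_independently(rng, t, 0.25)
        fit = fit_exponential(obs, cens, covariate_mode="pooled", settings=FAST)
        minima = obs[fit.censored_index]
        assert fit.imputed.shape[1] == fit.censored_index.size
        assert np.all(fit.imputed >= minima[None, :] - 1e-9)
        assert np.all(fit.imputed <= fit.t_max + 1e-9)

    def test_uniform_imputation_mode_runs_and_differs(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(1 / 0.07, size=150)
        obs, cens = censor_independently(rng, t, 0.3)
        f_model = fit_exponential(obs, cens, covariate_mode="pooled", settings=FAST)
        f_unif = fit_exponential(obs, cens, covariate_mode="pooled", settings=FAST,
                                 imputation="uniform")
        # uniform imputation inflates the latent times, lowering the rate
        assert f_unif.rate_draws().mean() < f_model.rate_draws().mean()

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="censored"):
            fit_exponential([5.0, 6.0], [True, True], covariate_mode="pooled",
                            settings=FAST)

    def test_non_positive_time_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            fit_exponential([5.0, 0.0], covariate_mode="pooled", settings=FAST)


class TestCovariateFit:
    def test_recovers_per_arm_rates(self):
        rng = np.random.default_rng(4)
        rates = {"RIFLE_308": 0.10, "BUCK_00": 0.05, "BUCK_1": 0.05, "BUCK_4": 0.05}
        ammo = np.repeat(list(rates), 150)
        t = np.concatenate([rng.exponential(1 / rates[a], 150) for a in rates])
        fit = fit_exponential(t, None, ammo, covariate_mode="by_ammo", settings=FAST)
        assert fit.worst_rhat() < 1.02
        for arm, lam in rates.items():
            lo, hi = cw.hpdi(fit.rate_draws(arm), 0.99)
            assert lo < lam < hi

    def test_covariate_model_wins_with_threefold_rate_difference(self):
        rng = np.random.default_rng(5)
        ammo = np.repeat([a.value for a in cw.Ammo], 100)
        rates = np.repeat([0.3, 0.1, 0.1, 0.1], 100)
        t = rng.exponential(1 / rates)
        by = fit_exponential(t, None, ammo, covariate_mode="by_ammo", settings=FAST)
        pooled = fit_exponential(t, covariate_mode="pooled", settings=FAST)
        assert compare_models(by, pooled).preferred == "by_ammo"


class TestPercentile:
    def test_95th_percentile_identity(self):
        assert percentile(math.log(20.0) / 43.0, 0.95) == pytest.approx(43.0)

    def test_median_closed_form(self):
        assert percentile(0.1, 0.5) == pytest.approx(math.log(2) / 0.1)

    def test_doubling_rate_halves_percentile(self):
        assert percentile(0.2, 0.9) == pytest.approx(percentile(0.1, 0.9) / 2)

    def test_invalid_quantile(self):
        with pytest.raises(ValueError):
            percentile(0.1, 1.0)


class TestSurvivalCurve:
    def test_degenerate_posterior_gives_exact_exponential(self):
        fit = fit_exponential(
            np.full(30, 10.0), covariate_mode="pooled",
            priors=GammaPrior(shape=1e9, rate=1e10),  # pins the rate at 0.1
            settings=FAST,
        )
        grid = np.array([0.0, 5.0, 10.0, 30.0])
        curve = survival_curve(fit, grid)
        assert np.allclose(curve.mean[0], np.exp(-0.1 * grid), atol=1e-3)
        assert curve.mean[0, 0] == 1.0

    def test_monotone_non_increasing_and_starts_at_one(self):
        rng = np.random.default_rng(6)
        fit = fit_exponential(rng.exponential(12.0, 100), covariate_mode="pooled",
                              settings=FAST)
        curve = survival_curve(fit, np.linspace(0, 60, 40))
        assert curve.mean[0, 0] == pytest.approx(1.0)
        assert np.all(np.diff(curve.mean[0]) <= 1e-12)

    def test_wider_posterior_gives_wider_band(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(12.0, size=400)
        big = fit_exponential(t, covariate_mode="pooled", settings=FAST)
        small = fit_exponential(t[:25], covariate_mode="pooled", settings=FAST)
        grid = np.array([5.0, 12.0, 30.0])
        band_big = survival_curve(big, grid)
        band_small = survival_curve(small, grid)
        assert np.all(
            band_small.hi - band_small.lo > band_big.hi - band_big.lo
        )


class TestDeriveTT:
    def test_zero_chase_time_reproduces_tti_fit(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(1 / 0.07, size=200)
        obs, cens = censor_independently(rng, t, 0.2)
        tti = fit_exponential(obs, cens, covariate_mode="pooled", settings=FAST)
        tt = derive_tt(tti, np.zeros(obs.size), settings=FAST)
        assert tt.rate_draws().mean() == pytest.approx(
            tti.rate_draws().mean(), rel=0.03
        )

    def test_constant_chase_time_shifts_empirical_percentiles(self):
        rng = np.random.default_rng(9)
        obs = rng.exponential(1 / 0.07, size=300)
        tti = fit_exponential(obs, covariate_mode="pooled", settings=FAST)
        tt = derive_tt(tti, np.full(obs.size, 30.0), settings=FAST)
        assert np.median(tt.times) == pytest.approx(np.median(obs) + 30.0)

    def test_trial_fixture_tt_ordering(self, trial_encounters):
        recs = [r for r in trial_encounters if r.tti_s is not None]
        tti = fit_exponential(
            [r.tti_s for r in recs], [r.tti_censored for r in recs],
            covariate_mode="pooled", settings=FAST,
        )
        ct = np.array([r.ct_s for r in recs])
        tt = derive_tt(tti, ct, settings=FAST)
        median_tt = percentile(tt.rate_draws().mean(), 0.5)
        median_ct = np.median(ct)
        assert median_ct < median_tt < median_ct + max(r.tti_s for r in recs)

    def test_misaligned_chase_times_rejected(self):
        fit = fit_exponential([5.0, 6.0, 7.0] * 5, covariate_mode="pooled",
                              settings=FAST)
        with pytest.raises(ValueError, match="entries"):
            derive_tt(fit, np.zeros(7), settings=FAST)


class TestCompareModels:
    def test_identical_fits_tie(self):
        rng = np.random.default_rng(10)
        t = rng.exponential(10.0, 50)
        fit = fit_exponential(t, covariate_mode="pooled", settings=FAST)
        comp = compare_models(fit, fit)
        assert comp.preferred == "tie"
        assert comp.dic_by_ammo == comp.dic_pooled

    def test_different_data_rejected(self):
        rng = np.random.default_rng(11)
        f1 = fit_exponential(rng.exponential(10.0, 50), covariate_mode="pooled",
                             settings=FAST)
        f2 = fit_exponential(rng.exponential(10.0, 50), covariate_mode="pooled",
                             settings=FAST)
        with pytest.raises(ValueError, match="identical data"):
            compare_models(f1, f2)
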