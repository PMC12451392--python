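"""Wound-tract, pellet-zone and missing-pellet models."""

import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

import cullwelfare as cw
from cullwelfare.mcmc import GammaPrior, NormalPrior, SamplerSettings
from cullwelfare.wounds import (
    fit_missing_pellets,
    fit_wound_tracts,
    fit_zone_proportions,
)

FAST = SamplerSettings(n_chains=4, n_draws=2000, n_burn=800, seed=31)


def pm_record(animal_id, tracts, zone_counts, expected):
    return cw.PostMortemRecord(
        animal_id=animal_id,
        wound_tracts=tracts,
        pellets_by_zone={z: c for z, c in zip(cw.Zone, zone_counts)},
        pellets_expected=expected,
        body_mass_kg=60.0,
        mass_censored=False,
        exam=cw.Exam.EX_SITU,
    )


def uniform_records(counts_per_arm: dict):
    """One post-mortem record per count, all arms represented."""
    recs, amap = [], {}
    i = 0
    for ammo, counts in counts_per_arm.items():
        for c in counts:
            i += 1
            aid = f"W{i:04d}"
            amap[aid] = ammo
            expected = 0 if ammo is cw.Ammo.RIFLE_308 else max(3 * c, 9)
            zone = [0, 0, c, 0, 0] if expected else [0] * 5
            recs.append(pm_record(aid, c, zone, expected))
    return recs, amap


class TestWoundTracts:
    def test_constant_counts_recovered(self):
        recs, amap = uniform_records({a: [4] * 25 for a in cw.Ammo})
        fit = fit_wound_tracts(recs, amap, settings=FAST)
        for a in cw.Ammo:
            assert fit.mean_draws(a.value).mean() == pytest.approx(4.0, abs=0.35)

    def test_single_arm_matches_quadrature_oracle(self):
        # Poisson mean with a normal prior on the log scale, one arm isolated
        counts = [3, 5, 2, 4, 6, 3, 4, 5, 2, 4]
        recs, amap = uniform_records(
            {a: (counts if a is cw.Ammo.RIFLE_308 else [4] * 10) for a in cw.Ammo}
        )
        fit = fit_wound_tracts(recs, amap, settings=FAST)
        eta = np.linspace(-6, 6, 20001)
        log_w = sum(counts) * eta - len(counts) * np.exp(eta) - 0.5 * (eta / 10.0) ** 2
        w = np.exp(log_w - log_w.max())
        oracle = float(np.trapezoid(w * np.exp(eta), eta) / np.trapezoid(w, eta))
        assert fit.mean_draws("RIFLE_308").mean() == pytest.approx(oracle, rel=0.02)

    def test_trial_fixture_ordering_follows_pellets_per_cartridge(
        self, trial_data
    ):
        enc, pm = trial_data
        fit = fit_wound_tracts(pm, cw.ammo_by_animal(enc), settings=FAST)
        means = [fit.mean_draws(a.value).mean()
                 for a in (cw.Ammo.BUCK_00, cw.Ammo.BUCK_1, cw.Ammo.BUCK_4)]
        assert means == sorted(means)

    def test_empty_arm_rejected(self):
        recs, amap = uniform_records(
            {a: [3] * 5 for a in cw.Ammo if a is not cw.Ammo.BUCK_4}
        )
        with pytest.raises(ValueError, match="BUCK_4"):
            fit_wound_tracts(recs, amap, settings=FAST)


class TestZoneProportions:
    def test_all_thorax_collapses_to_unit_vector(self):
        recs, amap = uniform_records(
            {a: [5] * 10 for a in cw.SHOTGUN_AMMO}
        )
        fit = fit_zone_proportions(recs, amap, settings=FAST)
        # the Gamma(0.5) prior leaves half a pseudo-pellet per zone, so the
        # posterior thorax share is (50 + 0.5) / (50 + 2.5), not exactly 1
        for arm in fit.arms:
            means = fit.prop_draws[arm].mean(axis=0)
            thorax = means[list(cw.Zone).index(cw.Zone.THORAX)]
            assert thorax == pytest.approx(50.5 / 52.5, abs=0.01)
            assert all(m < 0.02 for i, m in enumerate(means)
                       if i != list(cw.Zone).index(cw.Zone.THORAX))

    def test_equal_zone_totals_give_uniform_proportions(self):
        recs, amap = [], {}
        for i in range(12):
            aid = f"Z{i:03d}"
            amap[aid] = cw.SHOTGUN_AMMO[i % 3]
            recs.append(pm_record(aid, 10, [2, 2, 2, 2, 2], 45))
        fit = fit_zone_proportions(recs, amap, settings=FAST)
        for arm in fit.arms:
            assert np.allclose(fit.prop_draws[arm].mean(axis=0), 0.2, atol=0.03)

    def test_draws_stay_on_simplex(self, trial_data):
        enc, pm = trial_data
        fit = fit_zone_proportions(pm, cw.ammo_by_animal(enc), settings=FAST)
        for arm in fit.arms:
            assert np.allclose(fit.prop_draws[arm].sum(axis=1), 1.0)

    def test_matches_dirichlet_closed_form(self):
        # shared Gamma rate -> proportions are Dirichlet(shape + totals)
        recs, amap = [], {}
        totals = np.array([1, 4, 20, 6, 2], dtype=float)
        for i in range(2):
            aid = f"D{i:03d}"
            amap[aid] = cw.Ammo.BUCK_00
            half = (totals // 2) if i else (totals - totals // 2)
            recs.append(pm_record(aid, int(half.sum()), half.astype(int), 54))
        prior = GammaPrior(shape=0.5, rate=1e-9)
        fit = fit_zone_proportions(recs, amap, priors=prior, settings=FAST)
        alpha = prior.shape + totals
        expected = alpha / alpha.sum()
        got = fit.prop_draws["BUCK_00"].mean(axis=0)
        assert np.allclose(got, expected, atol=0.01)

    def test_armwise_zero_pellets_rejected(self):
        recs, amap = uniform_records({a: [0] * 5 for a in cw.Ammo})
        with pytest.raises(ValueError):
            fit_zone_proportions(recs, amap, settings=FAST)


class TestMissingPellets:
    def test_full_detection_drives_proportion_to_zero(self):
        recs, amap = [], {}
        for i, ammo in enumerate(cw.SHOTGUN_AMMO):
            for j in range(10):
                aid = f"F{i}{j:02d}"
                amap[aid] = ammo
                recs.append(pm_record(aid, 18, [0, 0, 18, 0, 0], 18))
        fit = fit_missing_pellets(recs, amap, settings=FAST)
        assert fit.pooled_draws.mean() < 0.02

    def test_trial_fixture_recovers_undetected_fraction(self, trial_data):
        enc, pm = trial_data
        fit = fit_missing_pellets(pm, cw.ammo_by_animal(enc), settings=FAST)
        # the generator loses 78% of fired pellets
        assert fit.pooled_draws.mean() == pytest.approx(0.78, abs=0.03)

    def test_single_arm_matches_beta_quadrature_oracle(self):
        recs, amap = [], {}
        miss, tot = 0, 0
        for j, (detected, expected) in enumerate([(4, 18), (2, 18), (5, 27)]):
            for ammo in cw.SHOTGUN_AMMO:
                aid = f"B{j}{ammo.value}"
                amap[aid] = ammo
                recs.append(pm_record(aid, detected, [0, 0, detected, 0, 0], expected))
            miss += expected - detected
            tot += expected
        fit = fit_missing_pellets(recs, amap, settings=FAST)
        from cullwelfare.outcomes import _binomial_logit_logpost  # oracle below
        eta = np.linspace(-8, 8, 20001)
        p = 1 / (1 + np.exp(-eta))
        log_w = miss * np.log(p) + (tot - miss) * np.log1p(-p) - 0.5 * (eta / 1.6) ** 2
        w = np.exp(log_w - log_w.max())
        oracle = float(np.trapezoid(w * p, eta) / np.trapezoid(w, eta))
        assert fit.prop_draws("BUCK_00").mean() == pytest.approx(oracle, abs=0.01)

    def test_invariant_to_aggregating_within_arm(self):
        split, amap1 = [], {}
        merged, amap2 = [], {}
        for i, ammo in enumerate(cw.SHOTGUN_AMMO):
            for j in range(4):
                aid = f"S{i}{j}"
                amap1[aid] = ammo
                split.append(pm_record(aid, 3, [0, 0, 3, 0, 0], 18))
            aid = f"M{i}"
            amap2[aid] = ammo
            merged.append(pm_record(aid, 12, [0, 0, 12, 0, 0], 72))
        f1 = fit_missing_pellets(split, amap1, settings=FAST)
        f2 = fit_missing_pellets(merged, amap2, settings=FAST)
        assert np.array_equal(f1.prop_chains, f2.prop_chains)

    def test_detected_exceeding_expected_rejected(self):
        rec = pm_record("X1", 20, [0, 0, 20, 0, 0], 20)
        rec.pellets_expected = 10  # corrupt after construction
        with pytest.raises(ValueError, match="exceed"):
            fit_missing_pellets([rec], {"X1": cw.Ammo.BUCK_00}, settings=FAST)
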