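"""Ballistic-injury models: wound tracts, pellet zones, missing pellets.

Three post-mortem models:

* wound tracts per carcase — Poisson regression with ammunition type as a
  reference-coded categorical covariate on the log mean;
* pellet distribution across the five anatomical zones — independent
  per-zone Poisson means, normalised to proportions draw by draw (equivalent
  to a Dirichlet posterior on the zone proportions conditional on totals);
* proportion of fired pellets not detected on radiographs — binomial-logit
  model on (missing, fired) totals per arm, plus a pooled fit.

The rifle arm is excluded from the two pellet models: a bullet fragments
rather than scattering countable pellets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_model import (
    Ammo,
    PostMortemRecord,
    SHOTGUN_AMMO,
    Zone,
)
from .mcmc import (
    GammaPrior,
    NormalPrior,
    SamplerSettings,
    sample,
    summarize,
)
from .outcomes import _binomial_logit_logpost, _eta_from_draws

__all__ = [
    "WoundTractFit",
    "ZoneProportionFit",
    "MissingPelletFit",
    "fit_wound_tracts",
    "fit_zone_proportions",
    "fit_missing_pellets",
]


def _arm_of(rec: PostMortemRecord, ammo: Mapping[str, Ammo]) -> Ammo:
    try:
        return ammo[rec.animal_id]
    except KeyError:
        raise ValueError(
            f"post-mortem record {rec.animal_id} has no ammunition assignment"
        ) from None


def _summary_frame(named: dict[str, np.ndarray], mass: float = 0.90) -> pd.DataFrame:
    summ = summarize(named, mass)
    return pd.DataFrame(
        {
            "arm": list(summ),
            "mean": [s.mean for s in summ.values()],
            "hpdi_lo": [s.hpdi_lo for s in summ.values()],
            "hpdi_hi": [s.hpdi_hi for s in summ.values()],
            "rhat": [s.rhat for s in summ.values()],
        }
    )


@dataclass
class WoundTractFit:
    """Posterior expected wound tracts per carcase, by ammunition arm."""

    arms: tuple[str, ...]
    mean_chains: np.ndarray  # (chain, iteration, arm), expected tracts

    def mean_draws(self, arm: str) -> np.ndarray:
        return self.mean_chains[:, :, self.arms.index(arm)].reshape(-1)

    def summary(self, mass: float = 0.90) -> pd.DataFrame:
        return _summary_frame(
            {a: self.mean_chains[:, :, k] for k, a in enumerate(self.arms)}, mass
        )

    def worst_rhat(self) -> float:
        return float(self.summary()["rhat"].max())


def fit_wound_tracts(
    postmortem: Sequence[PostMortemRecord],
    ammo: Mapping[str, Ammo],
    priors: NormalPrior | None = None,
    settings: SamplerSettings | None = None,
) -> WoundTractFit:
    """Poisson regression of wound-tract counts on ammunition type.

    ``ammo`` maps animal_id to its arm (see
    :func:`cullwelfare.data_model.ammo_by_animal`).  Every arm must have at
    least one examined carcase.
    """
    if not postmortem:
        raise ValueError("no post-mortem records")
    prior = priors or NormalPrior(sd=10.0)
    s = settings or SamplerSettings()
    arms = [a.value for a in Ammo]
    ysum = np.zeros(len(arms))
    n = np.zeros(len(arms))
    for rec in postmortem:
        k = arms.index(_arm_of(rec, ammo).value)
        ysum[k] += rec.wound_tracts
        n[k] += 1
    empty = [a for a, c in zip(arms, n) if c == 0]
    if empty:
        raise ValueError(f"no post-mortem records for arm(s): {', '.join(empty)}")

    def logpost(beta: np.ndarray) -> np.ndarray:
        beta = np.atleast_2d(beta)
        eta = beta[:, :1] + np.concatenate(
            [np.zeros((beta.shape[0], 1)), beta[:, 1:]], axis=1
        )
        ll = (ysum * eta - n * np.exp(eta)).sum(axis=1)
        return ll - 0.5 * (beta ** 2).sum(axis=1) / prior.sd ** 2

    init = np.zeros(len(arms))
    init[0] = np.log(max(ysum.sum() / n.sum(), 0.1))
    chains = sample(logpost, init, s)
    mean_chains = np.exp(_eta_from_draws(chains.draws))
    return WoundTractFit(arms=tuple(arms), mean_chains=mean_chains)


@dataclass
class ZoneProportionFit:
    """Posterior pellet proportions per anatomical zone, by shotgun arm."""

    arms: tuple[str, ...]
    zones: tuple[str, ...]
    prop_draws: dict[str, np.ndarray]  # arm -> (draw, zone), rows on the simplex

    def summary(self, mass: float = 0.90) -> pd.DataFrame:
        frames = []
        for arm in self.arms:
            named = {
                z: self.prop_draws[arm][:, j][None, :]
                for j, z in enumerate(self.zones)
            }
            f = _summary_frame(named, mass).rename(columns={"arm": "zone"})
            f.insert(0, "arm", arm)
            frames.append(f.drop(columns=["rhat"]))
        return pd.concat(frames, ignore_index=True)


def fit_zone_proportions(
    postmortem: Sequence[PostMortemRecord],
    ammo: Mapping[str, Ammo],
    priors: GammaPrior | None = None,
    settings: SamplerSettings | None = None,
) -> ZoneProportionFit:
    """Zone proportions of detected pellets per shotgun arm.

    Independent Gamma posteriors for the per-zone Poisson means (shape
    ``prior.shape + total count``, rate ``prior.rate + n carcases``) are
    normalised per draw; with a shared rate this is exactly a Dirichlet
    posterior on the proportions.
    """
    prior = priors or GammaPrior(shape=0.5, rate=1e-9)
    s = settings or SamplerSettings()
    rng = np.random.default_rng(s.seed + 2)
    shotgun = {a.value for a in SHOTGUN_AMMO}
    totals: dict[str, np.ndarray] = {a: np.zeros(len(Zone)) for a in shotgun}
    counts = {a: 0 for a in shotgun}
    for rec in postmortem:
        arm = _arm_of(rec, ammo).value
        if arm not in shotgun or rec.pellets_expected == 0:
            continue
        totals[arm] += np.array([rec.pellets_by_zone[z] for z in Zone], dtype=float)
        counts[arm] += 1
    arms = [a.value for a in SHOTGUN_AMMO if counts[a.value] > 0]
    if not arms:
        raise ValueError("no examined shotgun carcases with pellet data")
    prop_draws: dict[str, np.ndarray] = {}
    n_total = s.n_chains * s.n_draws
    for arm in arms:
        if totals[arm].sum() == 0:
            raise ValueError(f"arm {arm}: zero pellets detected in every zone")
        g = rng.gamma(prior.shape + totals[arm],
                      1.0 / (prior.rate + counts[arm]),
                      size=(n_total, len(Zone)))
        props = g / g.sum(axis=1, keepdims=True)
        assert np.allclose(props.sum(axis=1), 1.0)
        prop_draws[arm] = props
    return ZoneProportionFit(
        arms=tuple(arms),
        zones=tuple(z.value for z in Zone),
        prop_draws=prop_draws,
    )


@dataclass
class MissingPelletFit:
    """Posterior proportion of fired pellets not detected, by arm and pooled."""

    arms: tuple[str, ...]
    prop_chains: np.ndarray  # (chain, iteration, arm)
    pooled_chains: np.ndarray  # (chain, iteration)
    totals: pd.DataFrame

    def prop_draws(self, arm: str) -> np.ndarray:
        return self.prop_chains[:, :, self.arms.index(arm)].reshape(-1)

    @property
    def pooled_draws(self) -> np.ndarray:
        return self.pooled_chains.reshape(-1)

    def summary(self, mass: float = 0.90) -> pd.DataFrame:
        named = {a: self.prop_chains[:, :, k] for k, a in enumerate(self.arms)}
        named["pooled"] = self.pooled_chains
        return _summary_frame(named, mass)

    def worst_rhat(self) -> float:
        return float(self.summary()["rhat"].max())


def fit_missing_pellets(
    postmortem: Sequence[PostMortemRecord],
    ammo: Mapping[str, Ammo],
    priors: NormalPrior | None = None,
    settings: SamplerSettings | None = None,
) -> MissingPelletFit:
    """Binomial-logit model for the proportion of fired pellets not detected.

    The response per carcase is (expected pellets - detected pellets) out of
    expected pellets, with expected = shots fired x pellets per cartridge.
    The binomial likelihood depends on the data only through per-arm totals,
    so aggregating carcases within an arm leaves the fit unchanged.
    """
    prior = priors or NormalPrior(sd=1.6)
    s = settings or SamplerSettings()
    shotgun = [a.value for a in SHOTGUN_AMMO]
    miss = {a: 0.0 for a in shotgun}
    tot = {a: 0.0 for a in shotgun}
    seen = {a: 0 for a in shotgun}
    for rec in postmortem:
        arm = _arm_of(rec, ammo).value
        if arm not in shotgun or rec.pellets_expected == 0:
            continue
        detected = rec.pellets_detected
        if detected > rec.pellets_expected:
            raise ValueError(
                f"{rec.animal_id}: detected pellets {detected} exceed expected "
                f"{rec.pellets_expected}"
            )
        miss[arm] += rec.pellets_expected - detected
        tot[arm] += rec.pellets_expected
        seen[arm] += 1
    empty = [a for a in shotgun if seen[a] == 0]
    if empty:
        raise ValueError(f"no examined shotgun carcases for arm(s): {', '.join(empty)}")
    succ = np.array([miss[a] for a in shotgun])
    trials = np.array([tot[a] for a in shotgun])

    chains = sample(_binomial_logit_logpost(succ, trials, prior.sd),
                    np.zeros(len(shotgun)), s)
    prop_chains = expit(_eta_from_draws(chains.draws))
    pooled = sample(
        _binomial_logit_logpost(
            np.array([succ.sum()]), np.array([trials.sum()]), prior.sd
        ),
        np.zeros(1), s,
    )
    totals = pd.DataFrame(
        {
            "arm": shotgun,
            "pellets_missing": succ.astype(int),
            "pellets_expected": trials.astype(int),
            "carcases": [seen[a] for a in shotgun],
        }
    )
    return MissingPelletFit(
        arms=tuple(shotgun),
        prop_chains=prop_chains,
        pooled_chains=expit(pooled.draws[:, :, 0]),
        totals=totals,
    )
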