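"""Bayesian logistic models for encounter outcomes.

Each of the four encounter outcomes (immediate insensibility within 1 s,
delayed insensibility, wounded escape, clean miss) is modelled one-vs-rest
with ammunition type as a reference-coded categorical covariate on the
logit scale.  An intercept-only (pooled) fit supplies the across-all-arms
summary.  Posterior contrasts between arms are computed directly on the
probability draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .data_model import Ammo, EncounterRecord, Outcome
from .mcmc import (
    ChainSet,
    NormalPrior,
    PosteriorSummary,
    SamplerSettings,
    sample,
    summarize,
)

__all__ = ["OutcomeFit", "fit_outcome", "prob_greater"]


def _binomial_logit_logpost(succ: np.ndarray, tot: np.ndarray, sd: float):
    """Vectorised log posterior for reference-coded binomial-logit counts."""
    succ = np.asarray(succ, dtype=float)
    tot = np.asarray(tot, dtype=float)

    def logpost(beta: np.ndarray) -> np.ndarray:
        beta = np.atleast_2d(beta)
        eta = beta[:, :1] + np.concatenate(
            [np.zeros((beta.shape[0], 1)), beta[:, 1:]], axis=1
        )
        ll = (succ * eta - tot * np.logaddexp(0.0, eta)).sum(axis=1)
        return ll - 0.5 * (beta ** 2).sum(axis=1) / sd ** 2

    return logpost


def _eta_from_draws(draws: np.ndarray) -> np.ndarray:
    """Per-arm linear predictor (chain, iter, arm) from coefficient draws."""
    zeros = np.zeros(draws.shape[:2] + (1,))
    return draws[:, :, :1] + np.concatenate([zeros, draws[:, :, 1:]], axis=2)


@dataclass
class OutcomeFit:
    """Posterior outcome probabilities per ammunition arm and pooled."""

    outcome: Outcome
    arms: tuple[str, ...]
    p_chains: np.ndarray  # (chain, iteration, arm) on the probability scale
    overall_chains: np.ndarray  # (chain, iteration) pooled probability
    counts: pd.DataFrame

    def p_draws(self, arm: str) -> np.ndarray:
        return self.p_chains[:, :, self.arms.index(arm)].reshape(-1)

    @property
    def overall_draws(self) -> np.ndarray:
        return self.overall_chains.reshape(-1)

    def summary(self, mass: float = 0.90) -> pd.DataFrame:
        named = {
            arm: self.p_chains[:, :, k] for k, arm in enumerate(self.arms)
        }
        named["pooled"] = self.overall_chains
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

    def worst_rhat(self) -> float:
        return float(self.summary()["rhat"].max())


def fit_outcome(
    records: Sequence[EncounterRecord],
    outcome_of_interest: Outcome,
    priors: NormalPrior | None = None,
    settings: SamplerSettings | None = None,
) -> OutcomeFit:
    """Fit the one-vs-rest logistic model for one encounter outcome.

    Every ammunition arm must contain at least one record.  Returns posterior
    probability draws per arm plus the pooled (intercept-only) probability.
    """
    if not records:
        raise ValueError("no encounter records")
    prior = priors or NormalPrior(sd=1.6)
    s = settings or SamplerSettings()
    arms = [a.value for a in Ammo]
    succ = np.zeros(len(arms))
    tot = np.zeros(len(arms))
    for r in records:
        k = arms.index(r.ammo.value)
        tot[k] += 1
        succ[k] += r.outcome is outcome_of_interest
    empty = [arm for arm, n in zip(arms, tot) if n == 0]
    if empty:
        raise ValueError(f"no records for ammunition arm(s): {', '.join(empty)}")

    chains = sample(_binomial_logit_logpost(succ, tot, prior.sd),
                    np.zeros(len(arms)), s)
    p_chains = expit(_eta_from_draws(chains.draws))

    pooled = sample(
        _binomial_logit_logpost(np.array([succ.sum()]), np.array([tot.sum()]), prior.sd),
        np.zeros(1), s,
    )
    overall = expit(pooled.draws[:, :, 0])
    counts = pd.DataFrame({"arm": arms, "events": succ.astype(int), "n": tot.astype(int)})
    return OutcomeFit(
        outcome=outcome_of_interest,
        arms=tuple(arms),
        p_chains=p_chains,
        overall_chains=overall,
        counts=counts,
    )


def prob_greater(draws_a: np.ndarray, draws_b: np.ndarray) -> float:
    """Posterior probability that quantity A exceeds quantity B.

    Computed as the fraction of paired draws with a > b, ties counted with
    weight one half (so prob_greater(a, b) + prob_greater(b, a) = 1).
    Unequal draw counts are truncated to the shorter sequence.
    """
    a = np.asarray(draws_a, dtype=float).ravel()
    b = np.asarray(draws_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("empty draw vector")
    n = min(a.size, b.size)
    a, b = a[:n], b[:n]
    return float(np.mean((a > b) + 0.5 * (a == b)))
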