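"""Sampling engine and posterior diagnostics shared by every model module.

The sampler is an adaptive per-coordinate random-walk Metropolis scheme
(target acceptance rate ~0.44, the classic optimum for one-dimensional
updates).  Proposal scales adapt in batches during burn-in only and are
frozen afterwards, so the post-burn-in chain satisfies detailed balance.
All chains advance in lock-step from one seeded generator, which keeps the
whole run deterministic for a given master seed and lets the per-coordinate
updates vectorise across chains.

Diagnostics follow the classical definitions: the highest posterior density
interval (HPDI) is the shortest contiguous window of the sorted draws holding
the requested mass; the Gelman-Rubin potential scale reduction factor is
computed from between- and within-chain variances, R-hat =
sqrt(((n-1)/n * W + B/n) / W); and the deviance information criterion is
DIC = mean deviance + pD with pD = mean deviance - deviance at the posterior
mean.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "SamplerSettings",
    "ChainSet",
    "PosteriorSummary",
    "NormalPrior",
    "GammaPrior",
    "sample",
    "hpdi",
    "gelman_rubin",
    "dic",
    "summarize",
]


@dataclass(frozen=True)
class NormalPrior:
    """Zero-mean normal prior on regression coefficients."""

    sd: float = 10.0

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("prior sd must be > 0")


@dataclass(frozen=True)
class GammaPrior:
    """Gamma(shape, rate) prior on a positive rate parameter."""

    shape: float = 0.001
    rate: float = 0.001

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.rate > 0):
            raise ValueError("Gamma prior shape and rate must be > 0")


@dataclass(frozen=True)
class SamplerSettings:
    """Run-length and tuning knobs for the Metropolis sampler.

    Defaults match the analysis protocol: 4 chains, 10,000 retained draws per
    chain after 5,000 burn-in draws.
    """

    n_chains: int = 4
    n_draws: int = 10_000
    n_burn: int = 5_000
    seed: int = 0
    target_accept: float = 0.44
    adapt_interval: int = 50
    init_scale: float = 0.5
    thin_latent: int = 10

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_draws < 1 or self.n_burn < 0:
            raise ValueError("n_chains/n_draws must be >= 1 and n_burn >= 0")
        if not 0 < self.target_accept < 1:
            raise ValueError("target_accept must be in (0, 1)")


@dataclass
class ChainSet:
    """Posterior draws indexed (chain, iteration, parameter)."""

    draws: np.ndarray
    n_burn: int
    param_names: tuple[str, ...] | None = None
    accept_rates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.draws = np.asarray(self.draws, dtype=float)
        if self.draws.ndim != 3:
            raise ValueError("draws must have shape (chain, iteration, parameter)")
        if not np.all(np.isfinite(self.draws)):
            raise ValueError("draws contain non-finite values")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    @property
    def n_params(self) -> int:
        return self.draws.shape[2]

    def chains(self, param: int = 0) -> np.ndarray:
        """Draws for one parameter, shape (chain, iteration)."""
        return self.draws[:, :, param]

    def flat(self, param: int = 0) -> np.ndarray:
        """Chain-concatenated draws for one parameter."""
        return self.draws[:, :, param].reshape(-1)


@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior mean, 90% HPDI and convergence diagnostic for one scalar."""

    mean: float
    hpdi_lo: float
    hpdi_hi: float
    rhat: float
    mass: float = 0.90

    def __post_init__(self) -> None:
        if not self.hpdi_lo <= self.hpdi_hi:
            raise ValueError("hpdi_lo must not exceed hpdi_hi")


def sample(
    log_posterior: Callable[[np.ndarray], np.ndarray],
    init: np.ndarray | Sequence[float],
    settings: SamplerSettings | None = None,
) -> ChainSet:
    """Draw from ``log_posterior`` by adaptive random-walk Metropolis.

    Parameters
    ----------
    log_posterior
        Vectorised log target density: maps an array of shape
        ``(n_chains, d)`` to log densities of shape ``(n_chains,)``.
        Additive constants are irrelevant.
    init
        Starting point, shape ``(d,)`` (jittered across chains) or
        ``(n_chains, d)``.
    settings
        Run configuration; defaults to :class:`SamplerSettings`.
    """
    s = settings or SamplerSettings()
    rng = np.random.default_rng(s.seed)
    init = np.asarray(init, dtype=float)
    if init.ndim == 1:
        x = np.tile(init, (s.n_chains, 1))
        # overdispersed starts so the Gelman-Rubin diagnostic has teeth
        x += s.init_scale * rng.standard_normal(x.shape)
    elif init.ndim == 2 and init.shape[0] == s.n_chains:
        x = init.copy()
    else:
        raise ValueError("init must have shape (d,) or (n_chains, d)")
    C, d = x.shape
    lp = np.asarray(log_posterior(x), dtype=float)
    if lp.shape != (C,):
        raise ValueError("log_posterior must return shape (n_chains,)")
    if not np.all(np.isfinite(lp)):
        raise ValueError("log_posterior is non-finite at the initial point")

    scales = np.full((C, d), s.init_scale)
    acc_batch = np.zeros((C, d))
    acc_kept = np.zeros((C, d))
    out = np.empty((C, s.n_draws, d))
    batch = 0
    for it in range(s.n_burn + s.n_draws):
        for j in range(d):
            prop = x.copy()
            prop[:, j] += scales[:, j] * rng.standard_normal(C)
            lp_prop = np.asarray(log_posterior(prop), dtype=float)
            with np.errstate(invalid="ignore"):
                accept = np.log(rng.random(C)) < lp_prop - lp
            accept &= np.isfinite(lp_prop)
            x[accept] = prop[accept]
            lp[accept] = lp_prop[accept]
            acc_batch[:, j] += accept
            if it >= s.n_burn:
                acc_kept[:, j] += accept
        if it < s.n_burn and (it + 1) % s.adapt_interval == 0:
            batch += 1
            rate = acc_batch / s.adapt_interval
            delta = min(0.5, batch ** -0.5)
            scales *= np.exp(delta * (rate - s.target_accept))
            acc_batch[:] = 0.0
        if it >= s.n_burn:
            out[:, it - s.n_burn] = x
    rates = acc_kept / s.n_draws
    if np.any(rates < 0.05) or np.any(rates > 0.8):
        logger.warning(
            "acceptance rate outside (0.05, 0.8) after adaptation: min=%.3f max=%.3f",
            float(rates.min()), float(rates.max()),
        )
    return ChainSet(draws=out, n_burn=s.n_burn, accept_rates=rates)


def hpdi(draws: np.ndarray | Sequence[float], mass: float = 0.90) -> tuple[float, float]:
    """Shortest contiguous interval of the sorted draws holding ``mass``.

    Ties between equal-width windows break to the lowest starting index,
    which makes the result deterministic.
    """
    if not 0 < mass < 1:
        raise ValueError(f"mass must be in (0, 1), got {mass}")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = x.size
    if n < 10:
        raise ValueError(f"need at least 10 draws for an HPDI, got {n}")
    m = min(n, int(math.ceil(mass * n)))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))  # argmin takes the first minimum: lowest start
    return float(x[i]), float(x[i + m - 1])


def gelman_rubin(
    chains: ChainSet | np.ndarray,
    param: int = 0,
    split: bool = False,
) -> float:
    """Potential scale reduction factor R-hat for one parameter.

    ``chains`` may be a :class:`ChainSet` or a 2-D array indexed
    (chain, iteration).  The classical (unsplit) statistic is the default;
    ``split=True`` halves each chain first.
    """
    if isinstance(chains, ChainSet):
        a = chains.chains(param)
    else:
        a = np.asarray(chains, dtype=float)
    if a.ndim != 2:
        raise ValueError("expected draws indexed (chain, iteration)")
    if split:
        half = a.shape[1] // 2
        a = np.concatenate([a[:, :half], a[:, half: 2 * half]], axis=0)
    C, N = a.shape
    if C < 2:
        raise ValueError("Gelman-Rubin needs at least 2 chains")
    if N < 10:
        raise ValueError("Gelman-Rubin needs at least 10 draws per chain")
    within = a.var(axis=1, ddof=1)
    W = float(within.mean())
    if W == 0.0:
        raise ValueError("degenerate chains: zero within-chain variance")
    B_over_n = float(a.mean(axis=1).var(ddof=1))
    var_hat = (N - 1) / N * W + B_over_n
    return math.sqrt(var_hat / W)


def dic(deviance_draws: np.ndarray | Sequence[float], deviance_at_mean: float) -> float:
    """Deviance information criterion from posterior deviance draws.

    DIC = Dbar + pD where Dbar is the posterior mean deviance and
    pD = Dbar - D(posterior mean) is the effective parameter count.
    A negative pD (possible for badly behaved posteriors) is logged as a
    warning but the value is still returned.
    """
    dev = np.asarray(deviance_draws, dtype=float).ravel()
    if dev.size == 0 or not np.all(np.isfinite(dev)) or not np.isfinite(deviance_at_mean):
        raise ValueError("deviance inputs must be finite and non-empty")
    dbar = float(dev.mean())
    p_d = dbar - float(deviance_at_mean)
    if p_d < 0:
        logger.warning("negative pD (%.3f): DIC may be unreliable", p_d)
    return dbar + p_d


def summarize(
    draws_by_name: dict[str, np.ndarray],
    mass: float = 0.90,
) -> dict[str, PosteriorSummary]:
    """Posterior summaries for a dict of (chain, iteration) draw arrays."""
    out: dict[str, PosteriorSummary] = {}
    for name, a in draws_by_name.items():
        a = np.asarray(a, dtype=float)
        if a.ndim == 1:
            a = a[None, :]
        lo, hi = hpdi(a.ravel(), mass)
        rhat = gelman_rubin(a) if a.shape[0] >= 2 else float("nan")
        out[name] = PosteriorSummary(
            mean=float(a.mean()), hpdi_lo=lo, hpdi_hi=hi, rhat=rhat, mass=mass
        )
    return out


def summaries_to_frame(summaries: dict[str, PosteriorSummary]):
    """Tabulate summaries as a DataFrame (parameter, mean, hpdi_lo, hpdi_hi, rhat)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "parameter": list(summaries),
            "mean": [s.mean for s in summaries.values()],
            "hpdi_lo": [s.hpdi_lo for s in summaries.values()],
            "hpdi_hi": [s.hpdi_hi for s in summaries.values()],
            "rhat": [s.rhat for s in summaries.values()],
        }
    )
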