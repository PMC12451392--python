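"""Exponential time-to-event models with censoring-aware imputation.

Chase time (CT), time to insensibility (TTI) and total time (TT = CT + TTI)
are modelled with exponential survival distributions (a Weibull with shape
fixed at 1), either pooled across ammunition types or with ammunition as a
categorical covariate on the log rate.

Censored TTI values are observed only as minima (the animal was out of view
when it became insensible).  They are treated as latent draws from the fitted
exponential restricted to the interval between the row's observed minimum and
the maximum time observed anywhere in the data, and are resampled within the
Gibbs sweep alternately with the rate parameters — the standard
interval-censor construct.  A uniform-imputation mode is available for
sensitivity analysis.

TT is derived inside the model: for each retained imputation draw the
per-animal TT is formed as CT plus the observed or imputed TTI, and a second
exponential is refitted to it, so imputation uncertainty propagates into the
TT posterior.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data_model import Ammo
from .mcmc import (
    ChainSet,
    GammaPrior,
    NormalPrior,
    PosteriorSummary,
    SamplerSettings,
    gelman_rubin,
    hpdi,
    dic as _dic,
    summarize,
)

logger = logging.getLogger(__name__)

POOLED = "pooled"

__all__ = [
    "ExponentialSurvivalFit",
    "SurvivalCurve",
    "ModelComparison",
    "fit_exponential",
    "derive_tt",
    "percentile",
    "survival_curve",
    "compare_models",
]


def _arm_labels(ammo) -> tuple[list[str], np.ndarray]:
    """Ordered arm labels and per-row integer arm index."""
    ammo = list(ammo)
    labels = [a.value if isinstance(a, Ammo) else str(a) for a in ammo]
    enum_order = [a.value for a in Ammo]
    present = sorted(set(labels), key=lambda v: (
        enum_order.index(v) if v in enum_order else len(enum_order), v))
    lut = {v: k for k, v in enumerate(present)}
    return present, np.array([lut[v] for v in labels], dtype=np.intp)


@dataclass
class ExponentialSurvivalFit:
    """Posterior of an exponential survival model.

    ``rate_chains`` holds the per-arm rate draws (chain, iteration, arm);
    ``imputed`` holds thinned latent draws for the censored rows, flattened
    across chains, one column per censored row in data order.
    """

    covariate_mode: str
    arms: tuple[str, ...]
    rate_chains: np.ndarray
    times: np.ndarray
    censored: np.ndarray
    arm_index: np.ndarray
    t_max: float
    imputed: np.ndarray
    censored_index: np.ndarray
    deviance_draws: np.ndarray
    deviance_at_mean: float
    dic: float
    tt_draws: np.ndarray | None = None

    def rate_draws(self, arm: str | None = None) -> np.ndarray:
        """Flattened posterior rate draws for one arm (or the only arm)."""
        if arm is None:
            if len(self.arms) != 1:
                raise ValueError(f"specify one of {self.arms}")
            k = 0
        else:
            k = self.arms.index(arm)
        return self.rate_chains[:, :, k].reshape(-1)

    def percentile_draws(self, q: float, arm: str | None = None) -> np.ndarray:
        """Draws of the time by which a fraction ``q`` of animals has the event."""
        return percentile(self.rate_draws(arm), q)

    def rhat(self, arm: str) -> float:
        return gelman_rubin(self.rate_chains[:, :, self.arms.index(arm)])

    def worst_rhat(self) -> float:
        return max(self.rhat(a) for a in self.arms)

    def summary(self, mass: float = 0.90) -> pd.DataFrame:
        """Per-arm posterior summary of the rate and the median time."""
        rows = []
        for k, arm in enumerate(self.arms):
            lam = self.rate_chains[:, :, k]
            med = math.log(2.0) / lam
            lam_lo, lam_hi = hpdi(lam.ravel(), mass)
            med_lo, med_hi = hpdi(med.ravel(), mass)
            rhat = gelman_rubin(lam) if lam.shape[0] >= 2 else float("nan")
            rows.append(
                {
                    "arm": arm,
                    "rate_mean": float(lam.mean()),
                    "rate_hpdi_lo": lam_lo,
                    "rate_hpdi_hi": lam_hi,
                    "median_s_mean": float(med.mean()),
                    "median_s_hpdi_lo": med_lo,
                    "median_s_hpdi_hi": med_hi,
                    "rhat": rhat,
                }
            )
        return pd.DataFrame(rows)


def _validate_times(times, censored):
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-D array")
    if censored is None:
        cens = np.zeros(t.size, dtype=bool)
    else:
        cens = np.asarray(censored, dtype=bool)
        if cens.shape != t.shape:
            raise ValueError("censored flags must align with times")
    if np.any(~np.isfinite(t)):
        raise ValueError("non-finite time")
    if np.any(t[~cens] <= 0):
        raise ValueError("non-positive uncensored time")
    if np.any(t[cens] < 0):
        raise ValueError("negative censored minimum")
    if cens.all():
        raise ValueError("all values censored: rate not identifiable")
    return t, cens


def _trunc_exp_draw(rng, lam, lo, width):
    """Inverse-CDF draw from Exp(lam) truncated to [lo, lo + width].

    ``lam`` and ``lo``/``width`` broadcast; zero-width intervals collapse to
    the lower bound.
    """
    u = rng.random(np.broadcast_shapes(np.shape(lam), np.shape(lo)))
    p = -np.expm1(-lam * width)  # mass of the interval under Exp(lam), shifted
    return lo - np.log1p(-u * p) / lam


def fit_exponential(
    times: Sequence[float] | np.ndarray,
    censored: Sequence[bool] | np.ndarray | None = None,
    ammo: Sequence | None = None,
    covariate_mode: str = "by_ammo",
    priors: GammaPrior | NormalPrior | None = None,
    settings: SamplerSettings | None = None,
    imputation: str = "model",
) -> ExponentialSurvivalFit:
    """Fit the exponential survival model with censored-value imputation.

    Parameters
    ----------
    times
        Event times in seconds; for censored rows, the observed minimum.
    censored
        Right-censoring flags aligned with ``times`` (default: none).
    ammo
        Per-row ammunition labels; required when ``covariate_mode='by_ammo'``.
    covariate_mode
        ``'by_ammo'`` puts ammunition type on the log rate
        (reference-coded, normal priors on coefficients); ``'pooled'`` fits a
        single rate with a conjugate Gamma prior via direct Gibbs updates.
    imputation
        ``'model'`` resamples censored values from the fitted exponential
        truncated to [row minimum, global maximum observed time];
        ``'uniform'`` draws them uniformly on that interval (sensitivity mode).
    """
    if covariate_mode not in ("by_ammo", "pooled"):
        raise ValueError(f"unknown covariate_mode {covariate_mode!r}")
    if imputation not in ("model", "uniform"):
        raise ValueError(f"unknown imputation mode {imputation!r}")
    s = settings or SamplerSettings()
    t, cens = _validate_times(times, censored)
    n = t.size
    if covariate_mode == "by_ammo":
        if ammo is None:
            raise ValueError("ammo labels required for covariate_mode='by_ammo'")
        arms, arm_idx = _arm_labels(ammo)
        if len(arms) < 2:
            logger.warning("by_ammo fit with a single level; equivalent to pooled")
    else:
        arms, arm_idx = [POOLED], np.zeros(n, dtype=np.intp)
    K = len(arms)
    t_max = float(t.max())
    cens_idx = np.flatnonzero(cens)
    m = t[cens_idx]
    arm_c = arm_idx[cens_idx]
    n_cens = cens_idx.size
    width = t_max - m

    n_k = np.bincount(arm_idx, minlength=K).astype(float)
    n_unc_k = np.bincount(arm_idx[~cens], minlength=K).astype(float)
    sum_unc_k = np.bincount(arm_idx[~cens], weights=t[~cens], minlength=K)
    sum_obs_k = np.bincount(arm_idx, weights=t, minlength=K)  # observed-data sums
    cens_groups = [np.flatnonzero(arm_c == k) for k in range(K)]

    rng = np.random.default_rng(s.seed)
    C = s.n_chains
    if covariate_mode == "pooled" and not isinstance(priors, NormalPrior):
        prior = priors or GammaPrior()
        if not isinstance(prior, GammaPrior):
            raise ValueError("pooled mode takes a GammaPrior")
        fit = _gibbs_pooled(t, cens, m, width, n, prior, s, rng, imputation)
        rate_chains, imputed = fit
    else:
        prior = priors or NormalPrior(sd=10.0)
        if not isinstance(prior, NormalPrior):
            raise ValueError("covariate mode takes a NormalPrior on coefficients")
        rate_chains, imputed = _mh_covariate(
            t, cens, m, width, arm_c, cens_groups, n_k, sum_unc_k, K, prior, s,
            rng, imputation,
        )

    lam_flat = rate_chains.reshape(-1, K)
    dev = -2.0 * (lam_flat @ (-sum_obs_k) + np.log(lam_flat) @ n_unc_k)
    lam_bar = lam_flat.mean(axis=0)
    dev_at_mean = float(-2.0 * (np.dot(-sum_obs_k, lam_bar) + np.dot(n_unc_k, np.log(lam_bar))))
    return ExponentialSurvivalFit(
        covariate_mode=covariate_mode,
        arms=tuple(arms),
        rate_chains=rate_chains,
        times=t,
        censored=cens,
        arm_index=arm_idx,
        t_max=t_max,
        imputed=imputed,
        censored_index=cens_idx,
        deviance_draws=dev,
        deviance_at_mean=dev_at_mean,
        dic=_dic(dev, dev_at_mean),
    )


def _gibbs_pooled(t, cens, m, width, n, prior, s, rng, imputation):
    """Conjugate Gamma Gibbs sampler for the pooled rate with imputation."""
    C = s.n_chains
    n_cens = m.size
    sum_unc = float(t[~cens].sum())
    latent = np.tile(m + 0.5 * width, (C, 1)) if n_cens else np.zeros((C, 0))
    # overdispersed rate starts around the crude complete-data estimate
    lam = (n / max(t.sum(), 1e-12)) * np.exp(0.5 * rng.standard_normal(C))
    out = np.empty((C, s.n_draws, 1))
    kept_idx = range(0, s.n_draws, s.thin_latent)
    imp_out = np.empty((C, len(list(kept_idx)), n_cens))
    k_out = 0
    for it in range(s.n_burn + s.n_draws):
        if n_cens:
            if imputation == "model":
                latent = _trunc_exp_draw(rng, lam[:, None], m[None, :], width[None, :])
            else:
                latent = m[None, :] + rng.random((C, n_cens)) * width[None, :]
            assert np.all(latent >= m[None, :] - 1e-9)
            assert np.all(latent <= m[None, :] + width[None, :] + 1e-9)
            total = sum_unc + latent.sum(axis=1)
        else:
            total = np.full(C, sum_unc)
        lam = rng.gamma(prior.shape + n, 1.0 / (prior.rate + total))
        if it >= s.n_burn:
            j = it - s.n_burn
            out[:, j, 0] = lam
            if j % s.thin_latent == 0:
                imp_out[:, k_out] = latent
                k_out += 1
    return out, imp_out.reshape(-1, n_cens) if n_cens else np.zeros((0, 0))


def _mh_covariate(
    t, cens, m, width, arm_c, cens_groups, n_k, sum_unc_k, K, prior, s, rng,
    imputation,
):
    """Metropolis-within-Gibbs for reference-coded log-rate coefficients.

    The likelihood reduces to per-arm sufficient statistics (count, time sum
    including the current latent values), so each coordinate update is O(K)
    and vectorises across chains.
    """
    C = s.n_chains
    n_cens = m.size
    d = K  # intercept + K-1 offsets
    sd2 = prior.sd ** 2

    def lam_of(beta):
        eta = beta[:, :1] + np.concatenate(
            [np.zeros((beta.shape[0], 1)), beta[:, 1:]], axis=1
        )
        return np.exp(eta)

    def logpost(beta, S):
        lam = lam_of(beta)
        ll = (n_k * np.log(lam) - lam * S).sum(axis=1)
        return ll - 0.5 * (beta ** 2).sum(axis=1) / sd2

    crude = math.log(max(len(t), 1) / max(float(t.sum()), 1e-12))
    beta = np.zeros((C, d))
    beta[:, 0] = crude
    beta += 0.3 * rng.standard_normal((C, d))
    latent = np.tile(m + 0.5 * width, (C, 1)) if n_cens else np.zeros((C, 0))
    scales = np.full((C, d), 0.3)
    acc = np.zeros((C, d))
    batch = 0
    out = np.empty((C, s.n_draws, K))
    n_kept_lat = len(range(0, s.n_draws, s.thin_latent))
    imp_out = np.empty((C, n_kept_lat, n_cens))
    k_out = 0
    S = np.tile(sum_unc_k, (C, 1))
    for it in range(s.n_burn + s.n_draws):
        lam = lam_of(beta)
        if n_cens:
            lam_rows = lam[:, arm_c]
            if imputation == "model":
                latent = _trunc_exp_draw(rng, lam_rows, m[None, :], width[None, :])
            else:
                latent = m[None, :] + rng.random((C, n_cens)) * width[None, :]
            assert np.all(latent >= m[None, :] - 1e-9)
            assert np.all(latent <= m[None, :] + width[None, :] + 1e-9)
            for k in range(K):
                idx = cens_groups[k]
                S[:, k] = sum_unc_k[k] + (latent[:, idx].sum(axis=1) if idx.size else 0.0)
        lp = logpost(beta, S)
        for j in range(d):
            prop = beta.copy()
            prop[:, j] += scales[:, j] * rng.standard_normal(C)
            lp_prop = logpost(prop, S)
            ok = np.log(rng.random(C)) < lp_prop - lp
            beta[ok] = prop[ok]
            lp[ok] = lp_prop[ok]
            acc[:, j] += ok
        if it < s.n_burn and (it + 1) % s.adapt_interval == 0:
            batch += 1
            delta = min(0.5, batch ** -0.5)
            scales *= np.exp(delta * (acc / s.adapt_interval - s.target_accept))
            acc[:] = 0.0
        if it >= s.n_burn:
            jj = it - s.n_burn
            out[:, jj] = lam_of(beta)
            if jj % s.thin_latent == 0:
                imp_out[:, k_out] = latent
                k_out += 1
    return out, imp_out.reshape(-1, n_cens) if n_cens else np.zeros((0, 0))


def derive_tt(
    fit: ExponentialSurvivalFit,
    ct: Sequence[float] | np.ndarray,
    priors: GammaPrior | None = None,
    settings: SamplerSettings | None = None,
    refit: str = "per_draw",
) -> ExponentialSurvivalFit:
    """Derive total time TT = CT + TTI inside the model and refit it.

    For every retained (thinned) imputation draw of the TTI fit, per-animal
    TT values are formed and a second exponential is refitted by conjugate
    Gamma updates per arm; the resulting rate draws are pooled, so TT
    uncertainty integrates over the imputation.  ``refit='posterior_mean'``
    instead conditions on the posterior-mean imputed TTI (single refit).
    """
    if refit not in ("per_draw", "posterior_mean"):
        raise ValueError(f"unknown refit mode {refit!r}")
    s = settings or SamplerSettings()
    prior = priors or GammaPrior()
    ct = np.asarray(ct, dtype=float)
    if ct.shape != fit.times.shape:
        raise ValueError(
            f"ct has {ct.size} entries but the TTI fit covers {fit.times.size} animals"
        )
    if np.any(ct < 0):
        raise ValueError("negative chase time")
    rng = np.random.default_rng(s.seed + 1)
    K = len(fit.arms)
    n_k = np.bincount(fit.arm_index, minlength=K).astype(float)

    tti_mean = fit.times.copy()
    if fit.censored_index.size:
        tti_mean[fit.censored_index] = fit.imputed.mean(axis=0)
    tt_mean = ct + tti_mean

    if refit == "posterior_mean" or fit.censored_index.size == 0:
        imp_sets = tt_mean[None, :]
    else:
        imp_sets = np.tile(ct + fit.times, (fit.imputed.shape[0], 1))
        imp_sets[:, fit.censored_index] = ct[fit.censored_index] + fit.imputed
    M = imp_sets.shape[0]
    # per-imputation per-arm time sums
    S = np.empty((M, K))
    for k in range(K):
        S[:, k] = imp_sets[:, fit.arm_index == k].sum(axis=1)
    target = s.n_chains * s.n_draws
    r = max(1, math.ceil(target / M))
    lam = rng.gamma(prior.shape + n_k, 1.0 / (prior.rate + S), size=(r, M, K))
    lam = lam.reshape(-1, K)
    # pseudo-chain layout so downstream diagnostics have a uniform interface
    per = lam.shape[0] // s.n_chains
    rate_chains = lam[: per * s.n_chains].reshape(s.n_chains, per, K)

    S_mean = np.array([tt_mean[fit.arm_index == k].sum() for k in range(K)])
    lam_flat = rate_chains.reshape(-1, K)
    dev = -2.0 * (np.log(lam_flat) @ n_k - lam_flat @ S_mean)
    lam_bar = lam_flat.mean(axis=0)
    dev_at_mean = float(-2.0 * (np.dot(n_k, np.log(lam_bar)) - np.dot(S_mean, lam_bar)))
    return ExponentialSurvivalFit(
        covariate_mode=fit.covariate_mode,
        arms=fit.arms,
        rate_chains=rate_chains,
        times=tt_mean,
        # keep the censoring structure: these entries embed imputed TTIs
        censored=fit.censored.copy(),
        arm_index=fit.arm_index,
        t_max=float(tt_mean.max()),
        imputed=np.zeros((0, 0)),
        censored_index=fit.censored_index.copy(),
        deviance_draws=dev,
        deviance_at_mean=dev_at_mean,
        dic=_dic(dev, dev_at_mean),
        tt_draws=imp_sets if refit == "per_draw" else None,
    )


def percentile(rate: float | np.ndarray, q: float) -> float | np.ndarray:
    """Time by which a fraction ``q`` of animals has the event: -ln(1-q)/rate."""
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0, 1), got {q}")
    rate_arr = np.asarray(rate, dtype=float)
    out = -np.log1p(-q) / rate_arr
    return float(out) if np.isscalar(rate) or rate_arr.ndim == 0 else out


@dataclass
class SurvivalCurve:
    """Pointwise posterior mean and HPDI band of S(t) = exp(-rate * t)."""

    arms: tuple[str, ...]
    t: np.ndarray
    mean: np.ndarray  # (arm, time)
    lo: np.ndarray
    hi: np.ndarray
    mass: float = 0.90

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k, arm in enumerate(self.arms):
            rows.append(
                pd.DataFrame(
                    {
                        "arm": arm,
                        "t": self.t,
                        "mean": self.mean[k],
                        "lo": self.lo[k],
                        "hi": self.hi[k],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


def survival_curve(
    fit: ExponentialSurvivalFit,
    t_grid: Sequence[float] | np.ndarray,
    mass: float = 0.90,
    max_draws: int = 4000,
) -> SurvivalCurve:
    """Posterior survival curves over a time grid, per arm."""
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0):
        raise ValueError("time grid must be non-negative")
    worst = fit.worst_rhat()
    if worst > 1.01:
        logger.warning("survival_curve on a fit with worst R-hat %.3f > 1.01", worst)
    K = len(fit.arms)
    mean = np.empty((K, t.size))
    lo = np.empty((K, t.size))
    hi = np.empty((K, t.size))
    for k in range(K):
        lam = fit.rate_chains[:, :, k].reshape(-1)
        if lam.size > max_draws:
            stride = lam.size // max_draws
            lam = lam[::stride][:max_draws]
        surv = np.exp(-np.outer(lam, t))
        mean[k] = surv.mean(axis=0)
        for j in range(t.size):
            lo[k, j], hi[k, j] = hpdi(surv[:, j], mass)
    return SurvivalCurve(arms=fit.arms, t=t, mean=mean, lo=lo, hi=hi, mass=mass)


@dataclass(frozen=True)
class ModelComparison:
    """DIC comparison between the by-ammunition and pooled survival models."""

    dic_by_ammo: float
    dic_pooled: float
    preferred: str  # "by_ammo" | "pooled" | "tie"


def compare_models(
    fit_by_ammo: ExponentialSurvivalFit,
    fit_pooled: ExponentialSurvivalFit,
) -> ModelComparison:
    """Compare two fits of the same data by DIC; lower is preferred.

    The fits must share the censoring structure and agree exactly on every
    uncensored time; entries embedding imputed values (derived TT fits) may
    differ between the two models' imputations.
    """
    same_cens = np.array_equal(fit_by_ammo.censored, fit_pooled.censored)
    mask = ~fit_by_ammo.censored if same_cens else None
    if not (
        same_cens
        and fit_by_ammo.times.shape == fit_pooled.times.shape
        and np.array_equal(fit_by_ammo.times[mask], fit_pooled.times[mask])
    ):
        raise ValueError("model comparison requires fits on identical data")
    a, p = fit_by_ammo.dic, fit_pooled.dic
    preferred = "tie" if a == p else ("by_ammo" if a < p else "pooled")
    return ModelComparison(dic_by_ammo=a, dic_pooled=p, preferred=preferred)
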