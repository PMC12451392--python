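"""Sample-size power simulation for detecting an increase in total time.

Baseline total times (pursuit start to insensibility) are modelled as
log-normal, parameterised from previously reported summaries: a geometric
mean of 148 s with 5th and 95th percentiles of 50 and 700 s.  A treatment
effect of ``effect_s`` seconds shifts the log-mean by
``ln((gm + effect) / gm)``, i.e. a multiplicative increase located at the
geometric mean.  Each Monte-Carlo replicate draws two groups of ``n``
animals and applies a one-sided two-sample test for an increase; power is
the rejection fraction.

The default test is the pooled-variance t-test on log-times at one-sided
alpha = 0.05, which is exact for log-normal data.  A Wilcoxon rank-sum test
and an exponential-rate likelihood-ratio (rate-comparison) test are provided
as alternatives.  A closed-form normal-theory oracle
``power = Phi(dmu/sigma * sqrt(n/2) - z_{1-alpha})`` is exposed for
cross-checking.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PowerConfig",
    "PowerResult",
    "lognormal_from_summary",
    "analytic_power",
    "simulate_power",
    "power_table",
]


def lognormal_from_summary(
    geometric_mean: float, p5: float, p95: float
) -> tuple[float, float]:
    """Log-normal (mu_log, sigma_log) from a geometric mean and 5th/95th percentiles.

    mu_log = ln(geometric mean); sigma_log = ln(p95/p5) / (2 z_0.95) with
    z_0.95 the standard-normal 95th percentile.
    """
    if not 0 < p5 < p95:
        raise ValueError(f"need 0 < p5 < p95, got p5={p5}, p95={p95}")
    if not p5 < geometric_mean < p95:
        raise ValueError(
            f"geometric mean {geometric_mean} must lie between p5={p5} and p95={p95}"
        )
    z95 = stats.norm.ppf(0.95)
    return math.log(geometric_mean), math.log(p95 / p5) / (2.0 * z95)


@dataclass(frozen=True)
class PowerConfig:
    """One cell of the power analysis."""

    baseline_geometric_mean: float = 148.0
    baseline_p5: float = 50.0
    baseline_p95: float = 700.0
    n_per_group: int = 100
    effect_s: float = 48.0
    alpha: float = 0.05
    reps: int = 10_000
    seed: int = 0
    test: str = "t"  # "t" | "wilcoxon" | "exp_lrt"

    def __post_init__(self) -> None:
        lognormal_from_summary(
            self.baseline_geometric_mean, self.baseline_p5, self.baseline_p95
        )
        if self.effect_s < 0:
            raise ValueError("effect_s must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.test not in ("t", "wilcoxon", "exp_lrt"):
            raise ValueError(f"unknown test {self.test!r}")

    @property
    def mu_sigma(self) -> tuple[float, float]:
        return lognormal_from_summary(
            self.baseline_geometric_mean, self.baseline_p5, self.baseline_p95
        )

    @property
    def log_shift(self) -> float:
        gm = self.baseline_geometric_mean
        return math.log((gm + self.effect_s) / gm)


@dataclass(frozen=True)
class PowerResult:
    """Monte-Carlo power estimate with its binomial standard error."""

    power: float
    mc_se: float
    config: PowerConfig

    def __post_init__(self) -> None:
        expected = math.sqrt(self.power * (1.0 - self.power) / self.config.reps)
        if not math.isclose(self.mc_se, expected, abs_tol=1e-12):
            raise ValueError("mc_se inconsistent with power and reps")


def analytic_power(config: PowerConfig) -> float:
    """Normal-theory oracle: Phi(dmu/sigma * sqrt(n/2) - z_{1-alpha})."""
    _, sigma = config.mu_sigma
    z = stats.norm.ppf(1.0 - config.alpha)
    ncp = config.log_shift / sigma * math.sqrt(config.n_per_group / 2.0)
    return float(stats.norm.cdf(ncp - z))


def _reject_t(log_c: np.ndarray, log_t: np.ndarray, alpha: float) -> np.ndarray:
    """Vectorised one-sided pooled-variance t-test on log-times (reps, n)."""
    n = log_c.shape[1]
    mc, mt = log_c.mean(axis=1), log_t.mean(axis=1)
    vc, vt = log_c.var(axis=1, ddof=1), log_t.var(axis=1, ddof=1)
    sp2 = 0.5 * (vc + vt)
    tstat = (mt - mc) / np.sqrt(sp2 * 2.0 / n)
    tcrit = stats.t.ppf(1.0 - alpha, df=2 * n - 2)
    return tstat > tcrit


def simulate_power(config: PowerConfig) -> PowerResult:
    """Monte-Carlo power for one (n, effect) cell."""
    if config.reps < 100:
        warnings.warn(
            f"reps={config.reps} gives a large Monte-Carlo error", stacklevel=2
        )
    mu, sigma = config.mu_sigma
    rng = np.random.default_rng(config.seed)
    n, reps = config.n_per_group, config.reps
    log_c = mu + sigma * rng.standard_normal((reps, n))
    log_t = mu + config.log_shift + sigma * rng.standard_normal((reps, n))
    if config.test == "t":
        rejected = _reject_t(log_c, log_t, config.alpha)
    elif config.test == "wilcoxon":
        rejected = np.array(
            [
                stats.mannwhitneyu(log_t[i], log_c[i], alternative="greater").pvalue
                < config.alpha
                for i in range(reps)
            ]
        )
    else:  # exponential-rate comparison on the raw times
        tc, tt = np.exp(log_c), np.exp(log_t)
        # under H0 equal rates, the treatment mean-over-control mean follows F
        fstat = tt.mean(axis=1) / tc.mean(axis=1)
        fcrit = stats.f.ppf(1.0 - config.alpha, 2 * n, 2 * n)
        rejected = fstat > fcrit
    power = float(rejected.mean())
    return PowerResult(
        power=power,
        mc_se=math.sqrt(power * (1.0 - power) / reps),
        config=config,
    )


def power_table(
    effects: Sequence[float], config: PowerConfig | None = None
) -> pd.DataFrame:
    """Power across effect sizes; one row per effect.

    Returns a DataFrame with columns ``effect_s, n, power, mc_se``.  Each
    cell uses a distinct sub-seed derived from ``config.seed``.
    """
    if len(effects) == 0:
        raise ValueError("effects must be non-empty")
    config = config or PowerConfig()
    rows = []
    for i, eff in enumerate(effects):
        cell = replace(config, effect_s=float(eff), seed=config.seed + 7919 * i)
        res = simulate_power(cell)
        rows.append(
            {
                "effect_s": float(eff),
                "n": config.n_per_group,
                "power": res.power,
                "mc_se": res.mc_se,
            }
        )
    return pd.DataFrame(rows)
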