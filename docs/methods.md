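# Methods

This note documents the statistical models, the sampling machinery, the
synthetic-data generator and the design choices that were genuinely open.

## Time-to-event models

Chase time (CT), time to insensibility (TTI) and total time (TT = CT + TTI)
are modelled with exponential survival distributions — Weibull distributions
with the shape parameter fixed at 1 — so each fit estimates a rate λ (s⁻¹)
per ammunition arm or pooled.  Two parameterisations are provided:

* **pooled**: a single rate with a conjugate Gamma(0.001, 0.001) prior,
  updated by direct Gibbs draws λ | t ~ Gamma(a + n, b + Σt);
* **by-ammunition**: λ = exp(β₀ + β_arm) with reference coding (rifle arm as
  reference) and independent normal(0, sd 10) priors on the coefficients,
  updated by adaptive random-walk Metropolis.  The likelihood reduces to
  per-arm sufficient statistics, so coordinate updates are O(K) regardless
  of sample size.

**Censored-TTI imputation.**  A censored row contributes a latent event time
resampled every Gibbs sweep from the current exponential restricted to the
interval between that row's observed minimum and the maximum time observed
anywhere in the data (inverse-CDF sampling of the truncated exponential).
This is the standard interval-censor construct in a Gibbs framework: the
rate update then treats the latent times as complete data.  Marginally it is
equivalent (up to the finite upper truncation, whose effect shrinks with
sample size) to the usual right-censored likelihood with survival terms
S(minimum).  A uniform-on-the-interval imputation mode is available as a
sensitivity flag; it systematically inflates the latent times and lowers the
fitted rate, and is not used by default.

**Derived total time.**  For every retained (thinned, default every 10th)
imputation draw, per-animal TT values are formed as CT plus the observed or
imputed TTI, and the second exponential is refitted to them by conjugate
Gamma updates per arm; the rate draws are pooled across imputation draws, so
the TT posterior integrates over the imputation uncertainty.  A
`posterior_mean` mode conditions on the posterior-mean imputation instead
(single refit).  CT is modelled without censoring (it is always observed).

**Model comparison.**  DIC = D̄ + pD with pD = D̄ − D(posterior mean).  The
deviance is computed from the observed-data likelihood — log density for
uncensored rows, log survival at the recorded minimum for censored rows —
rather than conditionally on the latent imputations.  With this choice pD
approximates the free-parameter count (≈1 pooled, ≈4 with the covariate)
and the comparison between the pooled and covariate models behaves as the
nested-model asymptotics predict: under equal true rates the pooled model is
preferred whenever the likelihood-ratio improvement is below twice the
parameter difference (≈89% of replicates).  The TT fit's deviance conditions
on the posterior-mean imputation, since its draws come from conjugate refits.

**Summaries.**  Percentiles of the fitted distribution are closed-form,
t_q = −ln(1−q)/λ; survival curves report the pointwise posterior mean and
90% HPDI of e^(−λt) over the rate draws.

## Outcome and wound models

Encounter outcomes are modelled one-vs-rest: for a chosen outcome (most
importantly insensibility within 1 s of the first shot), logit(p_arm) =
β₀ + β_arm with normal(0, sd 1.6) priors — roughly uniform on the
probability scale — plus an intercept-only fit for the across-arms summary.
Posterior contrasts `prob_greater(a, b)` count paired draws with a > b,
ties at half weight, so the contrast and its reverse always sum to one.

Wound tracts per carcase follow a Poisson regression, log(μ_arm) =
β₀ + β_arm, normal(0, sd 10) priors.  Pellet zone proportions use
independent per-zone Poisson means with Gamma(0.5, ~0) priors sharing the
per-arm exposure; normalising the per-zone Gamma draws row-wise is exactly a
Dirichlet(0.5 + zone totals) posterior on the proportions, which is sampled
directly.  The missing-pellet model is a binomial logit on
(expected − detected) out of expected pellets per arm, expected = shots
fired × pellets per cartridge (1 for the rifle bullet, 9/16/27 for 00/1/4
Buck); the binomial likelihood depends only on per-arm totals, so the fit is
invariant to aggregating carcases within an arm.  The rifle arm is excluded
from the two pellet models: a bullet fragments rather than scattering
countable pellets.

The priors above are package assumptions; the hyperparameters used in the
original JAGS analyses are not recoverable from the source material.

## Sampling engine and diagnostics

The sampler is per-coordinate random-walk Metropolis with batch adaptation
of the proposal scales toward an acceptance rate of 0.44 during burn-in
only; scales are frozen afterwards, preserving detailed balance for the
retained draws.  Defaults are 4 chains × 10,000 retained draws after 5,000
burn-in.  All chains advance in lock-step from a single seeded generator
(rather than per-chain seed increments), which keeps runs bit-reproducible
for a given master seed and lets every update vectorise across chains;
chains remain mutually independent.  Chain starts are jittered for
overdispersion.  An acceptance rate outside (0.05, 0.8) after adaptation is
logged as a warning.

The 90% HPDI is the shortest contiguous window of the sorted draws
containing ⌈0.9 n⌉ points, ties broken at the lowest starting index (an
exhaustive-window oracle test guarantees exact agreement).  R̂ is the
classical Gelman–Rubin statistic √(((n−1)/n · W + B/n)/W) without
within-chain splitting; a `split=True` flag halves each chain first.

## Power simulation

Baseline total times are log-normal with μ_log = ln(148) ≈ 4.997 and
σ_log = ln(700/50)/(2 z₀.₉₅) ≈ 0.802, i.e. parameterised from the
previously reported geometric mean (148 s) and 5th/95th percentiles
(50/700 s).  The baseline is located at the geometric mean, not the median
(133 s).  A treatment effect of E seconds shifts μ_log by ln((148+E)/148).
Each replicate draws two groups of n log-normal times and applies a
one-sided pooled-variance t-test on the log scale at α = 0.05 — exact for
log-normal data; Wilcoxon and exponential-rate (F) alternatives are
pluggable.  The closed-form oracle Φ(Δμ/σ·√(n/2) − z₁₋α) gives 0.797,
0.913 and 0.973 at effects 48, 60 and 74 s with n = 100; the simulated
t-test powers sit within half a point of these.  Monte-Carlo error is
reported as √(p(1−p)/reps).

## Synthetic trial generator

The generator emulates the trial's design so every downstream stage is
testable without field data:

* four ammunition types assigned to sorties in independent permuted blocks
  of four (final block truncated);
* per-arm animal totals either fixed (the packaged configuration pins them
  at 100/97/99/94 = 390 across 17 sorties, inside the design's 94–100
  range) or Poisson per sortie; animals are clustered into groups of mean
  size ≈ 3.3;
* chase times log-normal (default median 60 s, σ_log 0.8, giving a long
  right tail to ~10 minutes);
* TTIs exponential with the arm's rate, specified either directly or by
  solving P(T ≤ 1) = 1 − e^(−λ) from per-arm instant-kill probabilities
  (the packaged configuration uses 0.07/0.03/0.05/0.05).  These two
  calibrations are mutually exclusive and cannot both match a single
  exponential — an instant-kill probability of 0.05 implies λ = 0.051,
  whereas a 43-second 95th percentile implies λ = 0.0697 — so the choice is
  a fixture convention, not an estimate;
* **censoring**: an animal goes out of view at an independent exponential
  time C ~ Exp(λc/(1−c)); if C precedes insensibility the row is censored
  and records C as the observed minimum.  Independence from the event
  process is essential: a mechanism that draws the recorded minimum as a
  uniform fraction of the true event time is informative (the minimum
  carries information about the event time beyond a bound) and biases the
  fitted rate low by ~13% at 23% censoring, which would corrupt both the
  interval coverage and the percentile summaries.  The chosen mechanism
  yields the target censored fraction c in expectation and keeps the
  survival fits calibrated (90% HPDI frequentist coverage ≈ 0.87–0.89 at
  n = 100; the residual shortfall from nominal comes from the finite upper
  truncation of the imputation interval and small-sample skew);
* a FAAST-style two-shot minimum: shots fired = 2 + Poisson(mean − 2);
* post-mortem examination of a random fifth of carcases (78% of those
  transported for ex-situ radiography); detected pellets per examined
  shotgun kill are Binomial(shots × pellets-per-cartridge, 0.22), so ~78%
  of fired pellets go undetected; at least one detected pellet is
  guaranteed and reassigned to the thorax if necessary, honouring the
  protocol's mandatory thorax shot;
* pellet zone allocation is multinomial around a thorax-dominant aim-point
  map, blended towards a uniform spread by a per-arm scatter fraction that
  grows with pellets per cartridge (0.15/0.30/0.50) — more, lighter pellets
  pattern more widely — so thorax concentration declines from 00 Buck to
  4 Buck structurally;
* body masses are normal (mean 68.5, sd 20.4 kg, floored at 17 kg) and
  censored at the 100-kg scale limit.

What the generator does **not** emulate: terrain and vegetation effects,
within-sortie density decline, shooter learning, inter-group dependence,
non-exponential TTI shapes, and wounded-escape outcomes (all animals are
killed, matching the trial's NFWR of zero).  Passing tests therefore
demonstrate correct recovery of the assumed data-generating process, not
robustness to the ways real field data depart from it.

## Numerical choices and limitations

* Imputed latent times are asserted to stay inside [row minimum, global
  maximum] every sweep.
* A zero-width imputation interval (minimum equal to the global maximum)
  collapses to the bound.
* Times are stored as decimal seconds; the generator rounds to 0.1 s
  (0.01 s below one second), reflecting voice-recorder resolution.
* CSV round-trips are byte-stable: floats are serialised with `repr`, so
  write → read → write reproduces files exactly.
* Fits whose worst R̂ exceeds 1.1 are aborted by the pipeline driver (the
  run continues and the manifest records the abort).
* The test suite runs the heavier simulation studies at reduced size: the
  interval-coverage study uses 600 replicates per rate with 2 chains ×
  1,500 retained draws, and the DIC preference study 200 replicates; both
  leave Monte-Carlo error small against their acceptance bands.
* `prob_greater` truncates unequal draw vectors to the shorter length
  rather than resampling, keeping it deterministic.
* The four-category outcome is handled as four one-vs-rest binary fits,
  matching how per-outcome probabilities are reported; a joint multinomial
  model is out of scope, as are covariates beyond ammunition type and
  random effects for sortie or group.
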