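# Methods

## Model

The measurement model for p items and m factors is

    y_i = ν + Λ η_i + ε_i,    η_i ~ N_m(0, Φ),    ε_i ~ N_p(0, Θ),

with Θ diagonal, η and ε uncorrelated, and Φ = diag(σ_f) R diag(σ_f)
decomposed into factor SDs and a correlation matrix.  Integrating the
factors out gives y_i ~ N_p(ν, ΛΦΛ′ + Θ); all estimation works with this
marginal likelihood, which depends on the data only through the sample mean
ȳ, the ML (divisor-N) sample covariance S, and N.  Divisor N, rather than
N − 1, is used so that the χ² discrepancy equals 2(L_saturated − L_model)
exactly.  The latent scale is set by unit loading identification: the first
item of each factor has its loading fixed to 1 and the factor variances are
free.  Each item loads on exactly one factor; there are no cross-loadings
or correlated uniquenesses.  Completely standardized solutions rescale
items and factors to unit variance, so loadings become item–factor
correlations and λ*² + θ* = 1 per item.

## Priors

Free loadings N(0, 100); intercepts N(0, 1024); residual and factor SDs
Gamma(shape 1, rate 0.5) (mean 2); factor correlations jointly uniform over
the positive-definite region (the elliptope), normalized by its volume
(2 for m = 2, π²/2 for m = 3).  Because of the truncation, the marginal
prior of each correlation is only approximately uniform on [−1, 1] — the
joint construction is a modeling choice the marginal description leaves
open.  All priors are mutually independent over free parameters.

## Sampling

The posterior is sampled on an unconstrained reparameterization: SDs are
mapped through the inverse CDF of their gamma prior composed with the
normal CDF (so the prior on each transformed SD coordinate is exactly
N(0, 1)), correlations through atanh, with all Jacobians included in the
target.  The kernel is independence Metropolis–Hastings: a multivariate t
proposal (df 10) centered at the posterior mode found by multi-start
L-BFGS, with covariance equal to the inverse finite-difference Hessian
inflated by 1.2.  For these 24–39-parameter posteriors at n in the
thousands the target is close to Gaussian, so kept draws are nearly
independent — chains of 1000 kept iterations after 1000 burn-in pass the
PSRF (< 1.1, unsplit Gelman–Rubin) and batch-means MCSE (< 5% of posterior
SD, batch size ⌊√s⌋) checks with a wide margin.  The proposal is fixed
before sampling, so warmup is pure burn-in; each chain draws its RNG stream
from an independent spawn of the master seed and starts at an independent
proposal draw, making runs exactly reproducible.  An adaptive
moment-matching refresh of the proposal during warmup was evaluated and
discarded: with few accepted draws the empirical covariance is
rank-deficient and degrades acceptance.

With the likelihood switched off the same machinery samples the prior; the
Gaussianized SD coordinates make the prior-only target nearly identical to
the proposal, which is how the sampler's correctness is validated (prior
moment recovery, uniform-ish correlation marginals).

## Fit assessment

The discrepancy is χ² = N[log|Σ̂| − log|S| + tr(SΣ̂⁻¹) − p +
(ȳ−μ̂)′Σ̂⁻¹(ȳ−μ̂)].  For each kept draw, a full replicate dataset of size
N is simulated from the implied distribution at that draw and reduced to
its own moments; PPP is the proportion of draws whose replicate fits worse
than the observed data, i.e. Pr(D_rep > D_obs).  Under this convention a
well-specified model gives PPP ≈ 0.5 and misfit drives PPP toward 0.  (The
opposite inequality sometimes appears in verbal definitions in the
literature; it is inconsistent with the reported usage of small values as
misfit, so the convention here follows the behavior, not the wording.)

pD is the marginalized-deviance effective parameter count, mean D(θ_i) −
D(θ̄) with θ̄ the posterior mean on the natural scale; under vague priors it
lands within a unit or two of the free-parameter count (36 for the
one-factor, 39 for the three-factor structure).  BRMSEA applies a square
root to max(0, D_obs − p*)/((p* − pD)N) — the rooted form is the one that
reproduces published three-decimal values from their printed χ²/pD/N — and
BCFI floors its numerator at 0 and caps the ratio into [0, 1], the
frequentist CFI convention.  The BCFI baseline is the independence model
(free means and variances, zero covariances) fitted with identical chain
settings so iterations pair one-to-one by (chain, iteration) index.

## Model comparison

Log marginal likelihoods use the Laplace approximation at the posterior
mode on the unconstrained scale, with the transform Jacobians in the
density and the Hessian by central finite differences (relative step 1e-4,
with per-entry step halving when a stencil point leaves the support — this
matters when a mis-specified model drives factor correlations toward 1).
Bayes factors are differences of log marginals, reported also as log10 and
as a mantissa–exponent string because the factors can reach thousands of
orders of magnitude.  Laplace is exact for Gaussian posteriors (verified
against the conjugate-normal closed form) and accurate here because the
posteriors are near-Gaussian at these sample sizes; no bridge sampling or
thermodynamic integration is attempted.

## Reliability

Ω_H = (Σλ)²ψ / ((Σλ)²ψ + Σθ) per subscale, evaluated at each kept
iteration's standardized solution, summarized by the posterior mean and
central 95% interval.  Ω_H is invariant to the latent scaling convention
(ULI with free ψ versus standardized factor), which is asserted per draw in
the tests.  A sensitivity variant with the observed total-score variance
1′S1 in the denominator is provided but not used by default: the
model-based denominator is the form that reproduces the published subscale
values (0.95/0.92/0.92) from the published standardized estimates.
Credible intervals are central (equal-tailed) quantiles.

## Criterion validity

Kendall's τ-b (tie-corrected, appropriate for heavily tied subscale totals)
on pairwise-complete observations.  Bayesian inference uses the asymptotic
normality of the standardized Kendall statistic, T* ≈ N(1.5τ√n, 1), with a
uniform [−1, 1] prior: the posterior is a truncated normal and BF10 is the
Savage–Dickey density ratio at τ = 0.  Everything is closed-form and
deterministic.  Synthetic paired scores for testing use Greiner's relation
(Pearson r = sin(πτ/2)) on bivariate normal deviates, optionally
discretized into equal-mass levels to emulate Likert totals.

## Synthetic-data generator

The generator draws from the congeneric model at a truth set matching the
published standardized solution: loadings 0.821–0.936 in three 4-item
blocks, residual variances 0.124–0.326 (so λ² + θ ≈ 1), factor
correlations 0.505/0.537/0.636, raw-scale intercepts 3.88–4.55.  Raw item
SDs are not published; they default to 1, an assumption, making the
continuous responses mean-shifted standardized deviates.  Likert mode
rounds to the nearest integer and clips to [1, 5]; this attenuates
correlations and shrinks extreme item means by up to ~0.2 toward the scale
midpoint (the exact discretized expectation is the test oracle), which is
why recovery checks use continuous mode — the mean-structure model actually
fitted assumes continuous responses.  Missingness is MCAR with per-item
rates linearly spaced over the reported 0.02%–0.18% range (per-item rates
are not published).  What the generator does not emulate: ordinal threshold
response processes, response styles, non-MCAR missingness, survey design
effects.  Passing recovery tests therefore shows the estimation machinery
is correct under the model's own assumptions, not that the model is robust
to ordinal or non-ignorable features of real survey data.

## Problem sizes and numerical choices

Default analyses run 3 chains × (1000 warmup + 1000 kept) at n = 3868 —
one model fit takes a few seconds on one core because the likelihood is
evaluated on sufficient statistics.  Test-suite simulation studies use
reduced but still informative sizes chosen as a deliberate design point:
PPP calibration over 20 replications at n = 500 and interval coverage over
20 replications at n = 1000, both with 2 chains × (400 + 400); the
pipeline demonstration at n = 600.  Degenerate inputs are handled
explicitly: a non-positive-definite implied covariance yields −∞
log-likelihood (a rejected point, not an exception), support violations
yield −∞ prior, a singular sample covariance raises in the χ² discrepancy,
zero within-chain variance yields NaN PSRF with a warning, and convergence
failure is reported with a warning while downstream indices are still
computed.

## Known limitations

Only simple-structure mean-structure models (no thresholds, cross-loadings,
residual correlations, multigroup invariance or modification indices).  The
Laplace approximation is strained when a mis-specified model pushes
correlations near the boundary; comparisons remain directionally reliable
there but the log-marginal error is larger than the near-Gaussian case.
Reliability intervals reflect parameter-posterior uncertainty only.  The
Kendall Bayes factor relies on the asymptotic likelihood of τ̂ and a
parametric yoking argument rather than an exact finite-sample likelihood.
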