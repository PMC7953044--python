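"""Posterior predictive model checking and Bayesian fit indices.

The discrepancy is the likelihood-ratio chi-square

    chi2 = N [ log|Sigma_hat| - log|S| + tr(S Sigma_hat^-1) - p
               + (ybar - mu_hat)' Sigma_hat^-1 (ybar - mu_hat) ],

algebraically equal to 2 (L_saturated - L_model).  The posterior predictive
p-value is the proportion of kept iterations in which a full replicate
dataset of size N simulated at that iteration's parameters fits worse than
the observed data: ppp = Pr(D_rep > D_obs).  Values near 0.5 indicate
adequate fit; values near 0 indicate misfit.  (Some verbal descriptions in
the literature state the opposite inequality; the convention used here is
the one under which a well-specified model yields ~0.5 and reported misfit
yields ppp < 0.001.)

BRMSEA and BCFI are per-iteration analogues of the RMSEA/CFI built from the
observed-data discrepancy, the number of unique sample moments
p* = p(p+3)/2 and the effective number of parameters pD from the
marginalized deviance (mean deviance minus deviance at the posterior mean).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import (
    ModelImpliedMoments,
    ModelSpec,
    SampleMoments,
    implied_moments,
    marginal_loglik,
)
from .sampler import PosteriorDraws, PriorSettings, run_chains

__all__ = [
    "FitPosterior",
    "chisq_discrepancy",
    "posterior_predictive",
    "effective_parameters",
    "brmsea",
    "bcfi",
    "fit_independence_model",
    "assess_fit",
    "summarize_fit",
]


def chisq_discrepancy(sm: SampleMoments, im: ModelImpliedMoments) -> float:
    """Likelihood-ratio chi-square between sample and model-implied moments."""
    sign_s, logdet_s = np.linalg.slogdet(sm.S)
    if sign_s <= 0 or not np.isfinite(logdet_s):
        raise ValueError("sample covariance is singular; chi-square discrepancy undefined")
    try:
        chol = np.linalg.cholesky(im.sigma_hat)
    except np.linalg.LinAlgError:
        raise ValueError("model-implied covariance is not positive definite") from None
    logdet_m = 2.0 * np.sum(np.log(np.diag(chol)))
    inv = np.linalg.inv(im.sigma_hat)
    diff = sm.ybar - im.mu_hat
    val = logdet_m - logdet_s + float(np.sum(sm.S * inv)) - sm.p + float(diff @ inv @ diff)
    return sm.N * val


def _replicate_moments(mu, sigma, n, rng) -> SampleMoments:
    """Sample moments of one replicated dataset of size n from N(mu, sigma)."""
    chol = np.linalg.cholesky(sigma)
    y = mu + rng.standard_normal((n, len(mu))) @ chol.T
    ybar = y.mean(axis=0)
    yc = y - ybar
    return SampleMoments(S=yc.T @ yc / n, ybar=ybar, N=n, p=len(mu))


def posterior_predictive(
    draws: PosteriorDraws, sm: SampleMoments, spec: ModelSpec, seed: int | None = 0
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-iteration observed and replicated discrepancies and the PPP.

    For each kept draw theta_i: d_obs[i] is the chi-square of the observed
    moments against the moments implied by theta_i; a replicate dataset of
    size N is then simulated at theta_i and d_rep[i] is its chi-square
    against the same implied moments.  Returns (d_obs, d_rep, ppp).
    """
    flat = draws.stacked()
    if flat.shape[0] == 0:
        raise ValueError("no kept iterations")
    rng = np.random.default_rng(seed)
    d_obs = np.empty(flat.shape[0])
    d_rep = np.empty(flat.shape[0])
    for i, row in enumerate(flat):
        params = draws.transform.params_from_natural(row)
        im = implied_moments(params, spec)
        d_obs[i] = chisq_discrepancy(sm, im)
        rep = _replicate_moments(im.mu_hat, im.sigma_hat, sm.N, rng)
        d_rep[i] = chisq_discrepancy(rep, im)
    ppp = float(np.mean(d_rep > d_obs))
    return d_obs, d_rep, ppp


def effective_parameters(draws: PosteriorDraws, sm: SampleMoments, spec: ModelSpec) -> float:
    """Effective number of parameters pD from the marginalized deviance:
    mean_i D(theta_i) - D(theta_bar), D = -2 log marginal likelihood,
    theta_bar the posterior mean on the natural scale."""
    flat = draws.stacked()
    if flat.shape[0] == 0:
        raise ValueError("no kept iterations")
    dev = np.array([-2.0 * marginal_loglik(draws.transform.params_from_natural(r), sm, spec)
                    for r in flat])
    dev_at_mean = -2.0 * marginal_loglik(draws.posterior_mean_parameters(), sm, spec)
    return float(dev.mean() - dev_at_mean)


def brmsea(d_obs, p_star: int, pD: float, N: int):
    """Per-iteration Bayesian RMSEA:
    sqrt( max(0, d_obs - p*) / ((p* - pD) N) ).  Vectorized over d_obs."""
    if p_star <= pD:
        raise ValueError(f"p_star={p_star} must exceed pD={pD:.2f} (negative effective df)")
    d_obs = np.asarray(d_obs, dtype=float)
    out = np.sqrt(np.maximum(0.0, d_obs - p_star) / ((p_star - pD) * N))
    return float(out) if out.ndim == 0 else out


def bcfi(d_obs_h, d_obs_0, p_star: int, eps: float = 1e-12):
    """Per-iteration Bayesian CFI:
    1 - max(0, d_H - p*) / max(eps, d_0 - p*), capped to [0, 1], with the
    hypothesized and independence (baseline) iterations paired by index."""
    d_obs_h = np.asarray(d_obs_h, dtype=float)
    d_obs_0 = np.asarray(d_obs_0, dtype=float)
    num = np.maximum(0.0, d_obs_h - p_star)
    den = np.maximum(eps, d_obs_0 - p_star)
    out = np.clip(1.0 - num / den, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def fit_independence_model(
    sm: SampleMoments,
    priors: PriorSettings | None = None,
    item_names=None,
    **chain_kwargs,
) -> PosteriorDraws:
    """Fit the baseline model with zero inter-item covariances and free
    intercepts/variances, with the same chain settings as the hypothesized
    model so iterations pair one-to-one by index."""
    names = tuple(item_names) if item_names is not None else tuple(f"q{i+1}" for i in range(sm.p))
    indep = ModelSpec(item_names=names, factors={})
    return run_chains(sm, indep, priors=priors, **chain_kwargs)


@dataclass(frozen=True)
class FitPosterior:
    """Posterior fit assessment of one hypothesized model."""

    d_obs: np.ndarray
    d_rep: np.ndarray
    ppp: float
    pD: float
    brmsea_draws: np.ndarray
    bcfi_draws: np.ndarray
    p_star: int
    N: int

    @property
    def chisq_posterior_mean(self) -> float:
        return float(self.d_obs.mean())

    @property
    def df_effective(self) -> float:
        return self.p_star - self.pD


def assess_fit(
    draws: PosteriorDraws,
    indep_draws: PosteriorDraws,
    sm: SampleMoments,
    spec: ModelSpec,
    seed: int | None = 0,
) -> FitPosterior:
    """Full posterior predictive fit assessment: PPP, pD, and per-iteration
    BRMSEA/BCFI realizations (baseline iterations paired by index)."""
    d_obs, d_rep, ppp = posterior_predictive(draws, sm, spec, seed=seed)
    pD = effective_parameters(draws, sm, spec)
    indep_spec = indep_draws.spec
    d_obs_0 = np.array([
        chisq_discrepancy(sm, implied_moments(indep_draws.transform.params_from_natural(r), indep_spec))
        for r in indep_draws.stacked()
    ])
    k = min(len(d_obs), len(d_obs_0))
    return FitPosterior(
        d_obs=d_obs,
        d_rep=d_rep,
        ppp=ppp,
        pD=pD,
        brmsea_draws=brmsea(d_obs, sm.p_star, pD, sm.N),
        bcfi_draws=bcfi(d_obs[:k], d_obs_0[:k], sm.p_star),
        p_star=sm.p_star,
        N=sm.N,
    )


def summarize_fit(fp: FitPosterior, model: str = "model") -> dict:
    """One fit-table row: chi-square posterior mean, pD, effective df, PPP,
    and BRMSEA/BCFI posterior means with central 90% credible intervals."""
    lo_b, hi_b = np.quantile(fp.brmsea_draws, [0.05, 0.95])
    lo_c, hi_c = np.quantile(fp.bcfi_draws, [0.05, 0.95])
    return {
        "model": model,
        "chisq_mean": fp.chisq_posterior_mean,
        "pD": fp.pD,
        "df": fp.df_effective,
        "ppp": fp.ppp,
        "brmsea_mean": float(fp.brmsea_draws.mean()),
        "brmsea_lo90": float(lo_b),
        "brmsea_hi90": float(hi_b),
        "bcfi_mean": float(fp.bcfi_draws.mean()),
        "bcfi_lo90": float(lo_c),
        "bcfi_hi90": float(hi_c),
    }


def fit_table(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows)
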