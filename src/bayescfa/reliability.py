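"""Model-based subscale reliability: McDonald's omega_H with a posterior
distribution.

For a congeneric subscale with loadings lambda_j, factor variance psi and
residual variances theta_j, the proportion of total-score variance due to
the common factor is

    omega_H = (sum_j lambda_j)^2 psi / ( (sum_j lambda_j)^2 psi + sum_j theta_j ).

Evaluating the formula at every kept MCMC iteration (on the completely
standardized solution of that iteration) yields a posterior distribution of
reliability, summarized by its mean and central 95% credible interval.
omega_H is invariant to the latent scaling convention: the ULI solution
(free psi, reference loading 1) and the factor-standardized solution give
the same value draw by draw.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ModelSpec, standardize
from .sampler import PosteriorDraws

__all__ = ["ReliabilityPosterior", "omega_plugin", "omega_posterior"]


def omega_plugin(loadings, residual_variances, factor_variance: float = 1.0) -> float:
    """omega_H evaluated at one parameter point.

    With completely standardized parameters pass ``factor_variance=1`` (the
    default).  All-zero loadings give 0 by convention.
    """
    lam = np.asarray(loadings, dtype=float)
    theta = np.asarray(residual_variances, dtype=float)
    if lam.size < 2:
        raise ValueError("a subscale needs at least 2 items")
    if lam.size != theta.size:
        raise ValueError("loadings and residual variances must have equal length")
    if np.any(theta < 0) or factor_variance <= 0:
        raise ValueError("residual variances must be non-negative and factor variance positive")
    common = lam.sum() ** 2 * factor_variance
    if common == 0.0:
        return 0.0
    return float(common / (common + theta.sum()))


def omega_sample_denominator(loadings, factor_variance: float, S_sub: np.ndarray) -> float:
    """Sensitivity variant with the observed total-score variance 1' S 1 of
    the subscale items in the denominator instead of the model-implied one."""
    lam = np.asarray(loadings, dtype=float)
    total_var = float(np.sum(S_sub))
    if total_var <= 0:
        raise ValueError("non-positive total-score variance")
    return float(lam.sum() ** 2 * factor_variance / total_var)


@dataclass(frozen=True)
class ReliabilityPosterior:
    subscale: str
    omega_draws: np.ndarray

    @property
    def posterior_mean(self) -> float:
        return float(self.omega_draws.mean())

    @property
    def ci95(self) -> tuple[float, float]:
        lo, hi = np.quantile(self.omega_draws, [0.025, 0.975])
        return float(lo), float(hi)


def omega_posterior(draws: PosteriorDraws, spec: ModelSpec, subscale: str) -> ReliabilityPosterior:
    """omega_H computed at each kept iteration (on that iteration's
    completely standardized solution), giving a posterior distribution of
    the subscale's reliability."""
    if subscale not in spec.factors:
        raise KeyError(f"unknown subscale {subscale!r}; have {list(spec.factors)}")
    k = spec.factor_names.index(subscale)
    idx = [spec.item_names.index(it) for it in spec.items_of(subscale)]
    omegas = np.empty(draws.n_chains * draws.n_kept)
    for i, params in enumerate(draws.iter_parameters()):
        std = standardize(params, spec)
        omegas[i] = omega_plugin(std.lam[idx, k], std.theta[idx], 1.0)
    return ReliabilityPosterior(subscale=subscale, omega_draws=omegas)
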