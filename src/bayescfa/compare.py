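"""Bayes-factor comparison of factorial structures via Laplace-approximated
log marginal likelihoods.

The Laplace approximation is taken on the unconstrained transform of the
parameter vector (log SDs, atanh correlations) with the transform Jacobian
included in the density, so the approximated integral is over the full
posterior mass regardless of boundary constraints.  Extreme Bayes factors
are reported on the log and log10 scales to avoid overflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .laplace import find_map, laplace_evidence, numeric_hessian
from .model import CFAParameters, ModelSpec, SampleMoments
from .sampler import PriorSettings, build_log_posterior, default_start

__all__ = [
    "ComparisonResult",
    "map_estimate",
    "ml_estimate",
    "laplace_log_marginal",
    "bayes_factor",
    "compare_models",
]


def _find_mode(sm, spec, priors, likelihood_weight=1.0, n_starts=5, seed=0):
    tf, logpost = build_log_posterior(sm, spec, priors, likelihood_weight)
    x0 = default_start(sm, spec, tf, likelihood_weight)
    x_map, lp = find_map(logpost, x0, n_starts=n_starts, seed=seed)
    return tf, logpost, x_map, lp


def map_estimate(
    sm: SampleMoments,
    spec: ModelSpec,
    priors: PriorSettings | None = None,
    n_starts: int = 5,
    seed: int | None = 0,
) -> CFAParameters:
    """Posterior mode by quasi-Newton maximization on the unconstrained
    transform, with jittered multi-start."""
    priors = priors or PriorSettings()
    tf, _, x_map, _ = _find_mode(sm, spec, priors, 1.0, n_starts, seed)
    return tf.unpack(x_map)


def ml_estimate(
    sm: SampleMoments,
    spec: ModelSpec,
    n_starts: int = 5,
    seed: int | None = 0,
) -> CFAParameters:
    """Maximum-likelihood solution: direct maximization of the marginal
    log-likelihood (flat improper prior on the unconstrained scale).  Serves
    as the frequentist oracle the large-sample posterior should match."""
    tf, _ = build_log_posterior(sm, spec, PriorSettings(), likelihood_weight=1.0)
    from .model import marginal_loglik

    def loglik_only(x):
        return marginal_loglik(tf.unpack(x), sm, spec)

    x0 = default_start(sm, spec, tf, 1.0)
    x_hat, _ = find_map(loglik_only, x0, n_starts=n_starts, seed=seed)
    return tf.unpack(x_hat)


def laplace_log_marginal(
    sm: SampleMoments,
    spec: ModelSpec,
    priors: PriorSettings | None = None,
    n_starts: int = 5,
    seed: int | None = 0,
) -> float:
    """Log marginal likelihood by the Laplace approximation at the posterior
    mode.  Raises when the negative-log-posterior Hessian at the mode is not
    positive definite."""
    priors = priors or PriorSettings()
    _, logpost, x_map, _ = _find_mode(sm, spec, priors, 1.0, n_starts, seed)
    H = -numeric_hessian(logpost, x_map)
    return laplace_evidence(logpost, x_map, hessian=H)


@dataclass(frozen=True)
class ComparisonResult:
    """Bayes factor of model A over model B."""

    logml_a: float
    logml_b: float

    @property
    def logbf(self) -> float:
        return self.logml_a - self.logml_b

    @property
    def log10bf(self) -> float:
        return float(self.logbf / np.log(10.0))

    @property
    def bf(self) -> float:
        """Exponentiated Bayes factor; inf/0 when not representable (use
        ``log10bf`` or ``bf_string`` for extreme magnitudes)."""
        with np.errstate(over="ignore"):
            return float(np.exp(self.logbf))

    @property
    def bf_string(self) -> str:
        """Base-10 scientific notation, safe for any magnitude."""
        l10 = self.log10bf
        expo = int(np.floor(l10))
        mant = 10.0 ** (l10 - expo)
        return f"{mant:.2f}e{expo:+d}"

    def reversed(self) -> "ComparisonResult":
        return ComparisonResult(self.logml_b, self.logml_a)


def bayes_factor(logml_a: float, logml_b: float) -> ComparisonResult:
    """Bayes factor of model A over model B from their log marginals."""
    return ComparisonResult(logml_a=logml_a, logml_b=logml_b)


def compare_models(
    sm: SampleMoments,
    specs: dict[str, ModelSpec],
    priors: PriorSettings | None = None,
    n_starts: int = 5,
    seed: int | None = 0,
) -> dict:
    """Log marginal likelihood per model plus the pairwise log10 Bayes-factor
    matrix (rows over columns)."""
    logml = {name: laplace_log_marginal(sm, spec, priors, n_starts=n_starts, seed=seed)
             for name, spec in specs.items()}
    names = list(specs)
    mat = {a: {b: bayes_factor(logml[a], logml[b]).log10bf for b in names} for a in names}
    return {"log_marginal": logml, "log10_bf": mat}
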