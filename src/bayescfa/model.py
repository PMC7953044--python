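"""Confirmatory factor model structures, implied moments and the marginal likelihood.

The measurement model for a p-vector of item responses is

    y_i = nu + Lambda eta_i + eps_i,

with latent factors eta_i ~ N_m(0, Phi) and residuals eps_i ~ N_p(0, Theta),
Theta diagonal, eta and eps uncorrelated.  Integrating the factors out,
y_i ~ N_p(nu, Lambda Phi Lambda' + Theta): the "marginal" likelihood used
throughout this package depends on the data only through the sample mean,
the ML (divisor-N) sample covariance and the sample size.

The latent scale is set by unit loading identification (ULI): the loading of
the first item of each factor is fixed to 1 and the factor variances are free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ModelSpec",
    "CFAParameters",
    "ModelImpliedMoments",
    "SampleMoments",
    "mspss_specs",
    "MSPSS_ITEM_NAMES",
    "compute_sample_moments",
    "implied_moments",
    "marginal_loglik",
    "saturated_loglik",
    "standardize",
]

#: Default item labels for the 12-item social-support scale: q1-q4 Significant
#: Other (SO), q5-q8 Family (FA), q9-q12 Friends (FR).
MSPSS_ITEM_NAMES = tuple(f"q{i}" for i in range(1, 13))


@dataclass(frozen=True)
class ModelSpec:
    """A simple-structure factor pattern: each item loads on exactly one factor.

    ``factors`` maps factor name -> list of item names (order defines the
    loading order); the first item of each factor is the ULI reference item
    whose loading is fixed to 1.  ``m == 0`` (no factors) encodes the
    independence model used as the baseline in incremental fit indices.
    """

    item_names: tuple[str, ...]
    factors: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self):
        items = list(self.item_names)
        if len(set(items)) != len(items):
            raise ValueError("duplicate item names")
        seen: list[str] = []
        for name, f_items in self.factors.items():
            if len(f_items) < 1:
                raise ValueError(f"factor {name!r} has no items")
            for it in f_items:
                if it not in items:
                    raise ValueError(f"factor {name!r} references unknown item {it!r}")
                if it in seen:
                    raise ValueError(f"item {it!r} loads on more than one factor")
                seen.append(it)
        if self.m > 0 and len(seen) != len(items):
            missing = sorted(set(items) - set(seen))
            raise ValueError(f"items not assigned to any factor: {missing}")

    @property
    def p(self) -> int:
        return len(self.item_names)

    @property
    def m(self) -> int:
        return len(self.factors)

    @property
    def factor_names(self) -> tuple[str, ...]:
        return tuple(self.factors)

    @property
    def pattern(self) -> np.ndarray:
        """p x m boolean indicator of (free or fixed) loadings."""
        pat = np.zeros((self.p, self.m), dtype=bool)
        for k, f_items in enumerate(self.factors.values()):
            for it in f_items:
                pat[self.item_names.index(it), k] = True
        return pat

    @property
    def reference_items(self) -> tuple[str, ...]:
        """First listed item of each factor; its loading is fixed to 1 (ULI)."""
        return tuple(f_items[0] for f_items in self.factors.values())

    @property
    def reference_idx(self) -> np.ndarray:
        return np.array([self.item_names.index(it) for it in self.reference_items], dtype=int)

    @property
    def free_loading_idx(self) -> list[tuple[int, int]]:
        """(item, factor) positions of the free (non-reference) loadings."""
        ref = set(self.reference_items)
        out = []
        for k, f_items in enumerate(self.factors.items()):
            _, its = f_items
            for it in its:
                if it not in ref:
                    out.append((self.item_names.index(it), k))
        return out

    @property
    def n_free_parameters(self) -> int:
        """Count of free parameters: intercepts, free loadings, residual
        variances, factor SDs and factor correlations."""
        m = self.m
        free_loadings = self.p - m if m > 0 else 0
        return self.p + free_loadings + self.p + m + m * (m - 1) // 2

    def items_of(self, factor: str) -> tuple[str, ...]:
        if factor not in self.factors:
            raise KeyError(f"unknown factor {factor!r}; have {list(self.factors)}")
        return tuple(self.factors[factor])

    # -- config round-trip -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "item_names": list(self.item_names),
            "factors": {k: list(v) for k, v in self.factors.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            item_names=tuple(d["item_names"]),
            factors={k: tuple(v) for k, v in d.get("factors", {}).items()},
        )


def mspss_specs(item_names: tuple[str, ...] = MSPSS_ITEM_NAMES) -> dict[str, ModelSpec]:
    """The five canonical factorial structures for the 12-item scale, in the
    order they are evaluated: one-factor, the three two-factor collapses
    (SO+FR, FA+FR, FA+SO), and the theoretical three-factor structure."""
    so, fa, fr = item_names[0:4], item_names[4:8], item_names[8:12]
    return {
        "one_factor": ModelSpec(item_names, {"G": so + fa + fr}),
        "two_factor_so_fr": ModelSpec(item_names, {"SO+FR": so + fr, "FA": fa}),
        "two_factor_fa_fr": ModelSpec(item_names, {"SO": so, "FA+FR": fa + fr}),
        "two_factor_fa_so": ModelSpec(item_names, {"FA+SO": fa + so, "FR": fr}),
        "three_factor": ModelSpec(item_names, {"SO": so, "FA": fa, "FR": fr}),
    }


@dataclass(frozen=True)
class CFAParameters:
    """One point in parameter space.

    ``lam`` is the full p x m loading matrix with the ULI reference loadings
    in place; ``theta`` the residual variances (diagonal of the residual
    covariance); ``factor_sds`` and ``factor_corr`` jointly parameterize the
    factor covariance Phi = diag(sd) R diag(sd).
    """

    nu: np.ndarray
    lam: np.ndarray
    theta: np.ndarray
    factor_sds: np.ndarray
    factor_corr: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "nu", np.asarray(self.nu, dtype=float))
        object.__setattr__(self, "lam", np.atleast_2d(np.asarray(self.lam, dtype=float)))
        object.__setattr__(self, "theta", np.asarray(self.theta, dtype=float))
        object.__setattr__(self, "factor_sds", np.asarray(self.factor_sds, dtype=float))
        object.__setattr__(self, "factor_corr", np.atleast_2d(np.asarray(self.factor_corr, dtype=float)))

    @property
    def phi(self) -> np.ndarray:
        """Factor covariance matrix."""
        d = np.diag(self.factor_sds)
        return d @ self.factor_corr @ d


@dataclass(frozen=True)
class ModelImpliedMoments:
    mu_hat: np.ndarray
    sigma_hat: np.ndarray


@dataclass(frozen=True)
class SampleMoments:
    """Sufficient statistics of a complete-case response matrix under the
    marginal multivariate-normal likelihood."""

    S: np.ndarray
    ybar: np.ndarray
    N: int
    p: int

    @property
    def p_star(self) -> int:
        """Number of unique sample moments, p(p+3)/2 (means + covariances)."""
        return self.p * (self.p + 3) // 2


def compute_sample_moments(rm) -> SampleMoments:
    """ML sample moments (covariance divisor N, not N-1) of a complete-case
    response matrix.

    Raises if missing values are present (filter with
    :func:`bayescfa.datasets.complete_cases` first); warns if N <= p or a
    column is constant, either of which makes S singular.
    """
    values = np.asarray(rm.values if hasattr(rm, "values") else rm, dtype=float)
    if values.ndim != 2:
        raise ValueError("expected an n x p matrix")
    if np.isnan(values).any():
        raise ValueError(
            "response matrix contains missing values; apply complete_cases() before computing moments"
        )
    n, p = values.shape
    ybar = values.mean(axis=0)
    centered = values - ybar
    S = centered.T @ centered / n
    if n < p + 1:
        warnings.warn(f"N={n} <= p={p}: sample covariance is singular", stacklevel=2)
    if np.any(np.diag(S) == 0.0):
        warnings.warn("constant column detected: sample covariance is singular", stacklevel=2)
    return SampleMoments(S=S, ybar=ybar, N=n, p=p)


def implied_moments(params: CFAParameters, spec: ModelSpec) -> ModelImpliedMoments:
    """Model-implied mean nu and covariance Lambda Phi Lambda' + diag(theta)."""
    p = spec.p
    if params.nu.shape != (p,) or params.theta.shape != (p,):
        raise ValueError("parameter dimensions do not match the model spec")
    if spec.m == 0:
        return ModelImpliedMoments(mu_hat=params.nu.copy(), sigma_hat=np.diag(params.theta))
    if params.lam.shape != (p, spec.m):
        raise ValueError(f"loading matrix must be {p} x {spec.m}, got {params.lam.shape}")
    sigma = params.lam @ params.phi @ params.lam.T + np.diag(params.theta)
    return ModelImpliedMoments(mu_hat=params.nu.copy(), sigma_hat=sigma)


def _gauss_loglik(S: np.ndarray, ybar: np.ndarray, N: int, mu: np.ndarray, sigma: np.ndarray) -> float:
    p = len(ybar)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.sum(np.log(np.diag(chol)))
    inv = np.linalg.inv(sigma)
    diff = ybar - mu
    quad = float(diff @ inv @ diff)
    tr = float(np.sum(S * inv))  # trace(S sigma^-1) for symmetric S
    return -0.5 * N * (p * np.log(2.0 * np.pi) + logdet + tr + quad)


def marginal_loglik(params: CFAParameters, sm: SampleMoments, spec: ModelSpec) -> float:
    """Log-likelihood of the sample with latent factors integrated out.

    Returns -inf (a rejected point, not an exception) when the implied
    covariance is not positive definite.
    """
    im = implied_moments(params, spec)
    return _gauss_loglik(sm.S, sm.ybar, sm.N, im.mu_hat, im.sigma_hat)


def saturated_loglik(sm: SampleMoments) -> float:
    """Log-likelihood of the saturated model (implied moments = sample moments)."""
    return _gauss_loglik(sm.S, sm.ybar, sm.N, sm.ybar, sm.S)


def standardize(params: CFAParameters, spec: ModelSpec) -> CFAParameters:
    """Completely standardized solution: items and factors rescaled to unit
    variance.  Standardized loadings become item-factor correlations; per item
    lambda*^2 + theta* = 1; the factor correlation matrix is unchanged."""
    im = implied_moments(params, spec)
    item_var = np.diag(im.sigma_hat)
    if np.any(item_var <= 0):
        raise ValueError("zero or negative implied item variance; cannot standardize")
    item_sd = np.sqrt(item_var)
    if spec.m == 0:
        return replace(params, theta=params.theta / item_var)
    lam_std = params.lam * params.factor_sds[None, :] / item_sd[:, None]
    theta_std = params.theta / item_var
    return CFAParameters(
        nu=params.nu.copy(),
        lam=lam_std,
        theta=theta_std,
        factor_sds=np.ones(spec.m),
        factor_corr=params.factor_corr.copy(),
    )
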