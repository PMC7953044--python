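"""Posterior sampling for the CFA under vague priors, with the three-chain
protocol and convergence diagnostics.

Priors (mutually independent over free parameters):

* free loadings          N(0, 100)
* intercepts             N(0, 1024)
* residual SDs           Gamma(shape 1, rate 0.5)  (mean 2)
* factor SDs             Gamma(shape 1, rate 0.5)
* factor correlations    jointly uniform over the positive-definite region
                         (each off-diagonal marginally close to, but not
                         exactly, uniform on [-1, 1] once truncated)

Sampling operates on an unconstrained transform of the parameter vector
(log SDs, atanh correlations) with the transform Jacobian included in the
target.  The kernel is an independence Metropolis-Hastings sampler whose
proposal is a multivariate t built from the Laplace approximation at the
posterior mode; for these near-Gaussian posteriors the kept draws are close
to independent, which is what the PSRF/MCSE convergence contract requires.
A warmup period is run and discarded; the proposal is frozen before the kept
iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .laplace import find_map, numeric_hessian, regularized_covariance
from .model import CFAParameters, ModelSpec, SampleMoments, marginal_loglik

__all__ = [
    "PriorSettings",
    "PosteriorDraws",
    "ConvergenceReport",
    "ParameterTransform",
    "log_prior",
    "run_chains",
    "psrf",
    "mcse_batch_means",
    "convergence_report",
    "trace_export",
]

# log volume of the set of m x m correlation matrices (elliptope), used to
# normalize the jointly-uniform correlation prior; exact for m <= 3.
_LOG_ELLIPTOPE_VOLUME = {0: 0.0, 1: 0.0, 2: np.log(2.0), 3: np.log(np.pi**2 / 2.0)}


@dataclass(frozen=True)
class PriorSettings:
    """Vague prior hyperparameters.  Variances / shapes / rates must be
    positive."""

    loading_mean: float = 0.0
    loading_var: float = 100.0
    intercept_mean: float = 0.0
    intercept_var: float = 1024.0
    residual_sd_shape: float = 1.0
    residual_sd_rate: float = 0.5
    factor_sd_shape: float = 1.0
    factor_sd_rate: float = 0.5

    def __post_init__(self):
        for name in ("loading_var", "intercept_var", "residual_sd_shape",
                     "residual_sd_rate", "factor_sd_shape", "factor_sd_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def _gamma_logpdf(x, shape, rate):
    from scipy.special import gammaln

    x = np.asarray(x, dtype=float)
    out = np.where(
        x > 0,
        shape * np.log(rate) - gammaln(shape) + (shape - 1) * np.log(np.where(x > 0, x, 1.0)) - rate * x,
        -np.inf,
    )
    return out


def log_prior(params: CFAParameters, priors: PriorSettings, spec: ModelSpec) -> float:
    """Sum of independent log prior densities over the free parameters.

    Densities are evaluated on the natural scales (SDs for the gamma priors,
    correlations for the uniform prior); support violations (negative SD,
    non-positive-definite or out-of-range correlation matrix) return -inf
    rather than raising.
    """
    p, m = spec.p, spec.m
    lp = 0.0
    # intercepts
    lp += float(np.sum(-0.5 * np.log(2 * np.pi * priors.intercept_var)
                       - 0.5 * (params.nu - priors.intercept_mean) ** 2 / priors.intercept_var))
    # free loadings (reference loadings are fixed, not parameters)
    if m > 0:
        free = np.array([params.lam[i, k] for i, k in spec.free_loading_idx])
        lp += float(np.sum(-0.5 * np.log(2 * np.pi * priors.loading_var)
                           - 0.5 * (free - priors.loading_mean) ** 2 / priors.loading_var))
    # residual SDs
    if np.any(params.theta <= 0):
        return -np.inf
    lp += float(np.sum(_gamma_logpdf(np.sqrt(params.theta), priors.residual_sd_shape, priors.residual_sd_rate)))
    # factor SDs
    if m > 0:
        if np.any(params.factor_sds <= 0):
            return -np.inf
        lp += float(np.sum(_gamma_logpdf(params.factor_sds, priors.factor_sd_shape, priors.factor_sd_rate)))
        # correlations: jointly uniform over the PD region
        R = params.factor_corr
        off = R[np.triu_indices(m, k=1)]
        if np.any(np.abs(off) >= 1.0):
            return -np.inf
        try:
            np.linalg.cholesky(R)
        except np.linalg.LinAlgError:
            return -np.inf
        lp -= _LOG_ELLIPTOPE_VOLUME.get(m, (m * (m - 1) // 2) * np.log(2.0))
    return lp


def _sd_from_u(u, shape, rate):
    """Inverse-CDF Gaussianization: sd = F_gamma^{-1}(Phi(u)); the gamma
    prior on the SD is exactly standard normal in u."""
    from scipy import special

    u = np.asarray(u, dtype=float)
    if shape == 1.0:
        # exponential case, stable in both tails: F^-1(Phi(u)) = -log Phi(-u) / rate
        return -special.log_ndtr(-u) / rate
    return special.gammaincinv(shape, special.ndtr(u)) / rate


def _u_from_sd(sd, shape, rate):
    from scipy import special

    sd = np.asarray(sd, dtype=float)
    if shape == 1.0:
        q = -np.expm1(-rate * sd)
    else:
        q = special.gammainc(shape, rate * sd)
    return special.ndtri(np.clip(q, 1e-15, 1.0 - 1e-15))


class ParameterTransform:
    """Bijection between CFAParameters and an unconstrained vector, plus the
    natural-scale summary vector stored in :class:`PosteriorDraws`.

    Unconstrained layout: intercepts | free loadings | Gaussianized residual
    SDs | Gaussianized factor SDs | atanh correlations.  SDs use the
    inverse-CDF map sd = F_gamma^{-1}(Phi(u)), under which the gamma prior is
    exactly N(0, 1) in u — with the likelihood switched off the target is
    then almost exactly Gaussian, which keeps the independence proposal
    efficient in every regime.  Natural layout replaces the last three blocks
    by residual variances, factor SDs and correlations.
    """

    def __init__(self, spec: ModelSpec, priors: "PriorSettings | None" = None):
        self.spec = spec
        self.priors = priors or PriorSettings()
        p, m = spec.p, spec.m
        self.q = len(spec.free_loading_idx) if m else 0
        self.c = m * (m - 1) // 2
        self.d = p + self.q + p + m + self.c
        self._triu = np.triu_indices(m, k=1)
        # slices into the unconstrained vector
        self.s_nu = slice(0, p)
        self.s_lam = slice(p, p + self.q)
        self.s_lrsd = slice(p + self.q, p + self.q + p)
        self.s_lfsd = slice(p + self.q + p, p + self.q + p + m)
        self.s_z = slice(p + self.q + p + m, self.d)

    @property
    def names(self) -> list[str]:
        spec = self.spec
        out = [f"nu[{it}]" for it in spec.item_names]
        fn = spec.factor_names
        out += [f"lambda[{spec.item_names[i]}~{fn[k]}]" for i, k in spec.free_loading_idx]
        out += [f"theta[{it}]" for it in spec.item_names]
        out += [f"psi_sd[{f}]" for f in fn]
        out += [f"corr[{fn[i]}~{fn[j]}]" for i, j in zip(*self._triu)]
        return out

    def unpack(self, x: np.ndarray) -> CFAParameters:
        spec = self.spec
        pr = self.priors
        p, m = spec.p, spec.m
        nu = x[self.s_nu]
        rsd = _sd_from_u(x[self.s_lrsd], pr.residual_sd_shape, pr.residual_sd_rate)
        lam = np.zeros((p, max(m, 1)))
        fsd = _sd_from_u(x[self.s_lfsd], pr.factor_sd_shape, pr.factor_sd_rate) if m else np.ones(0)
        R = np.eye(m)
        if m:
            lam[spec.reference_idx, np.arange(m)] = 1.0
            for (i, k), v in zip(spec.free_loading_idx, x[self.s_lam]):
                lam[i, k] = v
            R[self._triu] = np.tanh(x[self.s_z])
            R.T[self._triu] = R[self._triu]
        return CFAParameters(nu=nu, lam=lam[:, :m] if m else np.zeros((p, 0)),
                             theta=rsd**2, factor_sds=fsd, factor_corr=R)

    def pack(self, params: CFAParameters) -> np.ndarray:
        spec = self.spec
        x = np.empty(self.d)
        x[self.s_nu] = params.nu
        x[self.s_lam] = [params.lam[i, k] for i, k in spec.free_loading_idx]
        pr = self.priors
        x[self.s_lrsd] = _u_from_sd(np.sqrt(params.theta), pr.residual_sd_shape, pr.residual_sd_rate)
        if spec.m:
            x[self.s_lfsd] = _u_from_sd(params.factor_sds, pr.factor_sd_shape, pr.factor_sd_rate)
            x[self.s_z] = np.arctanh(np.clip(params.factor_corr[self._triu], -0.999999, 0.999999))
        return x

    def log_jacobian(self, x: np.ndarray) -> float:
        """log |d(natural SD / correlation) / d(unconstrained)|:
        d sd / d u = phi(u) / f_gamma(sd) per SD, (1 - r^2) per correlation."""
        pr = self.priors
        lj = 0.0
        for sl, shape, rate in ((self.s_lrsd, pr.residual_sd_shape, pr.residual_sd_rate),
                                (self.s_lfsd, pr.factor_sd_shape, pr.factor_sd_rate)):
            u = x[sl]
            if u.size:
                sd = _sd_from_u(u, shape, rate)
                lj += float(np.sum(-0.5 * np.log(2 * np.pi) - 0.5 * u**2
                                   - _gamma_logpdf(sd, shape, rate)))
        z = x[self.s_z]
        lj += float(np.sum(np.log1p(-np.tanh(z) ** 2)))
        return lj

    # -- natural-scale summary vector -------------------------------------
    def natural(self, x: np.ndarray) -> np.ndarray:
        pr = self.priors
        out = x.copy()
        out[self.s_lrsd] = _sd_from_u(x[self.s_lrsd], pr.residual_sd_shape, pr.residual_sd_rate) ** 2
        out[self.s_lfsd] = _sd_from_u(x[self.s_lfsd], pr.factor_sd_shape, pr.factor_sd_rate)
        out[self.s_z] = np.tanh(x[self.s_z])                 # correlations
        return out

    def params_from_natural(self, v: np.ndarray) -> CFAParameters:
        spec = self.spec
        p, m = spec.p, spec.m
        lam = np.zeros((p, m))
        R = np.eye(m)
        if m:
            lam[spec.reference_idx, np.arange(m)] = 1.0
            for (i, k), val in zip(spec.free_loading_idx, v[self.s_lam]):
                lam[i, k] = val
            R[self._triu] = v[self.s_z]
            R.T[self._triu] = R[self._triu]
        return CFAParameters(nu=v[self.s_nu], lam=lam, theta=v[self.s_lrsd],
                             factor_sds=v[self.s_lfsd], factor_corr=R)


def build_log_posterior(sm: SampleMoments, spec: ModelSpec, priors: PriorSettings,
                        likelihood_weight: float = 1.0):
    """Unnormalized log posterior density on the unconstrained scale
    (likelihood + prior + transform Jacobian)."""
    tf = ParameterTransform(spec, priors)

    def logpost(x: np.ndarray) -> float:
        params = tf.unpack(x)
        lp = log_prior(params, priors, spec)
        if not np.isfinite(lp):
            return -np.inf
        lp += tf.log_jacobian(x)
        if likelihood_weight != 0.0:
            ll = marginal_loglik(params, sm, spec)
            if not np.isfinite(ll):
                return -np.inf
            lp += likelihood_weight * ll
        return lp

    return tf, logpost


def default_start(sm: SampleMoments, spec: ModelSpec, tf: ParameterTransform,
                  likelihood_weight: float = 1.0) -> np.ndarray:
    """Moment-informed starting point (the prior mode, x = 0, when the
    likelihood is off)."""
    x = np.zeros(tf.d)
    if likelihood_weight == 0.0:
        return x
    pr = tf.priors
    x[tf.s_nu] = sm.ybar
    x[tf.s_lam] = 0.9
    diag = np.maximum(np.diag(sm.S), 1e-3)
    x[tf.s_lrsd] = _u_from_sd(np.sqrt(diag / 3.0), pr.residual_sd_shape, pr.residual_sd_rate)
    if spec.m:
        ref_var = diag[spec.reference_idx]
        x[tf.s_lfsd] = _u_from_sd(np.sqrt(np.maximum(ref_var * 0.6, 1e-3)),
                                  pr.factor_sd_shape, pr.factor_sd_rate)
        x[tf.s_z] = np.arctanh(0.4)
    return x


@dataclass
class PosteriorDraws:
    """Kept posterior draws on the natural scale, chain-labelled.

    ``values`` has shape (n_chains, n_kept, n_params); ``param_names`` labels
    the last axis (intercepts, free loadings, residual variances, factor SDs,
    factor correlations).
    """

    values: np.ndarray
    param_names: list[str]
    spec: ModelSpec
    seed: int | None
    acceptance: np.ndarray
    map_x: np.ndarray | None = None
    _transform: ParameterTransform | None = field(default=None, repr=False)

    @property
    def transform(self) -> ParameterTransform:
        if self._transform is None:
            self._transform = ParameterTransform(self.spec)
        return self._transform

    @property
    def n_chains(self) -> int:
        return self.values.shape[0]

    @property
    def n_kept(self) -> int:
        return self.values.shape[1]

    def stacked(self) -> np.ndarray:
        """All chains concatenated: (n_chains * n_kept, n_params)."""
        return self.values.reshape(-1, self.values.shape[2])

    def parameters_at(self, chain: int, iteration: int) -> CFAParameters:
        return self.transform.params_from_natural(self.values[chain, iteration])

    def iter_parameters(self):
        for row in self.stacked():
            yield self.transform.params_from_natural(row)

    def posterior_mean_parameters(self) -> CFAParameters:
        """CFAParameters at the per-parameter posterior mean (natural scale)."""
        return self.transform.params_from_natural(self.stacked().mean(axis=0))


def _mvt_logpdf_factory(mean: np.ndarray, cov: np.ndarray, df: float):
    d = mean.size
    cho = sla.cho_factor(cov, lower=True)
    logdet = 2.0 * np.sum(np.log(np.diag(cho[0])))
    from scipy.special import gammaln

    const = gammaln((df + d) / 2) - gammaln(df / 2) - 0.5 * d * np.log(df * np.pi) - 0.5 * logdet

    def logpdf(x):
        delta = x - mean
        q = float(delta @ sla.cho_solve(cho, delta))
        return const - 0.5 * (df + d) * np.log1p(q / df)

    chol = np.linalg.cholesky(cov)

    def sample(rng):
        g = rng.standard_normal(d)
        w = rng.chisquare(df) / df
        return mean + (chol @ g) / np.sqrt(w)

    return logpdf, sample


def run_chains(
    sm: SampleMoments,
    spec: ModelSpec,
    priors: PriorSettings | None = None,
    n_chains: int = 3,
    n_warmup: int = 1000,
    n_kept: int = 1000,
    seed: int | None = 0,
    likelihood_weight: float = 1.0,
    n_starts: int = 3,
    proposal_df: float = 10.0,
    proposal_inflation: float = 1.2,
) -> PosteriorDraws:
    """Sample the CFA posterior with independent chains.

    The proposal is a multivariate t (df ``proposal_df``) centered at the
    posterior mode with the Laplace covariance inflated by
    ``proposal_inflation``; the proposal is fixed before sampling begins, so
    warmup serves purely as burn-in.  Each chain starts from an independent
    proposal draw.  Identical arguments give identical draws.  Convergence
    failure (any PSRF >= 1.1) emits a warning, never a silent pass.
    """
    priors = priors or PriorSettings()
    tf, logpost = build_log_posterior(sm, spec, priors, likelihood_weight)
    x0 = default_start(sm, spec, tf, likelihood_weight)
    x_map, _ = find_map(logpost, x0, n_starts=n_starts, seed=seed)
    H = -numeric_hessian(logpost, x_map)
    cov0 = regularized_covariance(H) * proposal_inflation

    ss = np.random.SeedSequence(seed if seed is not None else None)
    chain_seeds = ss.spawn(n_chains)
    values = np.empty((n_chains, n_kept, tf.d))
    acc = np.zeros(n_chains)
    prop_logpdf, prop_sample = _mvt_logpdf_factory(x_map, cov0, proposal_df)
    for c in range(n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        # overdispersed start: proposal draw (retry until finite density)
        for _ in range(1000):
            x = prop_sample(rng)
            lp = logpost(x)
            if np.isfinite(lp):
                break
        else:
            raise RuntimeError("could not initialize chain inside the posterior support")
        lq = prop_logpdf(x)
        n_acc = 0
        total = n_warmup + n_kept
        for it in range(total):
            xn = prop_sample(rng)
            lpn = logpost(xn)
            if np.isfinite(lpn):
                lqn = prop_logpdf(xn)
                if np.log(rng.random()) < (lpn - lp) - (lqn - lq):
                    x, lp, lq = xn, lpn, lqn
                    if it >= n_warmup:
                        n_acc += 1
            if it >= n_warmup:
                values[c, it - n_warmup] = tf.natural(x)
        acc[c] = n_acc / n_kept

    draws = PosteriorDraws(values=values, param_names=tf.names, spec=spec, seed=seed,
                           acceptance=acc, map_x=x_map, _transform=tf)
    if np.any(acc < 0.05):
        warnings.warn(f"low acceptance rate in at least one chain: {acc}", stacklevel=2)
    if n_chains >= 2 and n_kept >= 10:
        r = psrf(draws)
        if np.any(np.nan_to_num(r, nan=1.0) >= 1.1):
            bad = [n for n, v in zip(draws.param_names, r) if np.isfinite(v) and v >= 1.1]
            warnings.warn(f"PSRF >= 1.1 for parameters {bad}: chains have not converged", stacklevel=2)
    return draws


# -- diagnostics -----------------------------------------------------------

def psrf(draws: PosteriorDraws) -> np.ndarray:
    """Gelman-Rubin potential scale reduction factor per parameter (unsplit
    chains): sqrt(((n-1)/n W + B/n) / W).  NaN (with a warning) where the
    within-chain variance is zero."""
    v = draws.values
    m, n = v.shape[0], v.shape[1]
    if m < 2:
        raise ValueError("PSRF requires at least 2 chains")
    if n < 10:
        raise ValueError("PSRF requires at least 10 kept iterations per chain")
    chain_means = v.mean(axis=1)
    W = v.var(axis=1, ddof=1).mean(axis=0)
    B_over_n = chain_means.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(((n - 1) / n * W + B_over_n) / W)
    if np.any(W == 0):
        warnings.warn("zero within-chain variance: PSRF undefined (NaN) for some parameters",
                      stacklevel=2)
        out = np.where(W == 0, np.nan, out)
    return out


def mcse_batch_means(draws: PosteriorDraws) -> np.ndarray:
    """Monte Carlo standard error of the posterior mean by batch means over
    the concatenated chains, batch size floor(sqrt(s))."""
    flat = draws.stacked()
    s = flat.shape[0]
    if s < 100:
        raise ValueError(f"batch-means MCSE requires >= 100 kept draws, got {s}")
    b = int(np.floor(np.sqrt(s)))
    nb = s // b
    batches = flat[: nb * b].reshape(nb, b, -1).mean(axis=1)
    if nb < 2:
        raise ValueError("too few batches")
    return np.sqrt(batches.var(axis=0, ddof=1) / nb)


@dataclass(frozen=True)
class ConvergenceReport:
    """Per-parameter PSRF and batch-means MCSE with the two pass/fail flags:
    PSRF < 1.1 and MCSE < 5% of the posterior SD."""

    param_names: list[str]
    psrf: np.ndarray
    mcse: np.ndarray
    posterior_sd: np.ndarray
    psrf_ok: bool
    mcse_ok: bool

    @property
    def passed(self) -> bool:
        return self.psrf_ok and self.mcse_ok

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"psrf": self.psrf, "mcse": self.mcse, "posterior_sd": self.posterior_sd},
            index=self.param_names,
        )


def convergence_report(draws: PosteriorDraws) -> ConvergenceReport:
    r = psrf(draws)
    mcse = mcse_batch_means(draws)
    sd = draws.stacked().std(axis=0, ddof=1)
    psrf_ok = bool(np.all(np.nan_to_num(r, nan=1.0) < 1.1))
    with np.errstate(divide="ignore", invalid="ignore"):
        mcse_ok = bool(np.all(mcse < 0.05 * np.where(sd > 0, sd, np.inf)))
    return ConvergenceReport(param_names=draws.param_names, psrf=r, mcse=mcse,
                             posterior_sd=sd, psrf_ok=psrf_ok, mcse_ok=mcse_ok)


def trace_export(draws: PosteriorDraws, path, plot_path=None) -> pd.DataFrame:
    """Write the per-chain, per-iteration natural-scale series to CSV
    (columns: chain, iteration, one column per parameter); optionally render
    trace plots to ``plot_path`` (requires matplotlib)."""
    m, n, k = draws.values.shape
    df = pd.DataFrame(draws.stacked(), columns=draws.param_names)
    df.insert(0, "iteration", np.tile(np.arange(n), m))
    df.insert(0, "chain", np.repeat(np.arange(m), n))
    df.to_csv(path, index=False)
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        ncol = 4
        nrow = int(np.ceil(k / ncol))
        fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 1.8 * nrow), squeeze=False)
        for j, name in enumerate(draws.param_names):
            ax = axes[j // ncol][j % ncol]
            for c in range(m):
                ax.plot(draws.values[c, :, j], lw=0.4)
            ax.set_title(name, fontsize=7)
        for j in range(k, nrow * ncol):
            axes[j // ncol][j % ncol].axis("off")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=100)
        plt.close(fig)
    return df
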