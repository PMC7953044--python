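"""Synthetic item-response generation for the 12-item perceived social
support scale.

The generator draws from the congeneric factor model the analysis assumes:
factors eta ~ N(0, R) with R the factor correlation matrix, residuals
eps ~ N(0, diag(theta)), and

    y = intercepts + diag(item_sds) * (Lambda eta + eps).

With standardized loadings and residual variances (lambda_j^2 + theta_j = 1)
and unit ``item_sds``, the population correlation structure of the printed
standardized solution is reproduced exactly while responses live on the 1-5
scale.  ``likert`` mode rounds to the nearest integer and clips to [1, 5];
``continuous`` mode leaves responses real-valued (the mean-structure model
actually fitted downstream).  Missingness is injected MCAR per item.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml

from .model import MSPSS_ITEM_NAMES

__all__ = [
    "GeneratingParameters",
    "ResponseMatrix",
    "default_generating_parameters",
    "generate_responses",
    "inject_missingness",
    "complete_cases",
    "read_responses",
    "write_responses",
    "load_generator_config",
]

# Posterior-mean standardized solution of the three-factor model
# (SO = items 1-4, FA = 5-8, FR = 9-12).
_LOADINGS = (
    0.898, 0.936, 0.908, 0.873,   # Significant Other
    0.866, 0.924, 0.821, 0.829,   # Family
    0.862, 0.884, 0.881, 0.841,   # Friends
)
_INTERCEPTS = (
    4.048, 4.272, 3.979, 4.126,
    4.291, 4.037, 3.883, 4.072,
    4.546, 4.430, 4.538, 4.249,
)
_RESIDUAL_VARIANCES = (
    0.194, 0.124, 0.176, 0.238,
    0.250, 0.146, 0.326, 0.314,
    0.257, 0.219, 0.224, 0.292,
)
_FACTOR_CORR = (
    (1.000, 0.636, 0.505),   # SO ~~ FA, SO ~~ FR
    (0.636, 1.000, 0.537),   # FA ~~ FR
    (0.505, 0.537, 1.000),
)


@dataclass(frozen=True)
class GeneratingParameters:
    """Truth set driving the synthetic-data generator.

    ``loadings`` and ``residual_variances`` are standardized (per item,
    loadings^2 + residual_variance ~= 1); ``intercepts`` are raw item means on
    the 1-5 response scale; ``item_sds`` rescale the standardized latent part
    to the raw scale (default 1.0: raw item SDs are not reported, so unit
    scale is an assumption); ``missing_rates`` are per-item MCAR proportions.
    """

    loadings: np.ndarray
    intercepts: np.ndarray
    residual_variances: np.ndarray
    factor_correlations: np.ndarray
    item_sds: np.ndarray
    missing_rates: np.ndarray
    item_names: tuple[str, ...] = MSPSS_ITEM_NAMES
    factor_sizes: tuple[int, ...] = (4, 4, 4)

    def __post_init__(self):
        for name in ("loadings", "intercepts", "residual_variances", "item_sds", "missing_rates"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        object.__setattr__(
            self, "factor_correlations", np.atleast_2d(np.asarray(self.factor_correlations, dtype=float))
        )
        p = len(self.loadings)
        if sum(self.factor_sizes) != p:
            raise ValueError("factor_sizes must sum to the number of items")
        R = self.factor_correlations
        if not np.allclose(np.diag(R), 1.0):
            raise ValueError("factor correlation matrix must have unit diagonal")
        if np.min(np.linalg.eigvalsh(R)) <= 0:
            raise ValueError("factor correlation matrix is not positive definite")
        if np.any(self.missing_rates < 0) or np.any(self.missing_rates >= 1):
            raise ValueError("missing rates must lie in [0, 1)")

    @property
    def p(self) -> int:
        return len(self.loadings)

    @property
    def m(self) -> int:
        return len(self.factor_sizes)

    @property
    def lam(self) -> np.ndarray:
        """p x m loading matrix with the simple block structure."""
        lam = np.zeros((self.p, self.m))
        start = 0
        for k, size in enumerate(self.factor_sizes):
            lam[start : start + size, k] = self.loadings[start : start + size]
            start += size
        return lam

    def population_moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Population mean and covariance of the generated responses:
        mu = intercepts, Sigma = D (Lam R Lam' + Theta) D with D = diag(item_sds)."""
        lam = self.lam
        std_cov = lam @ self.factor_correlations @ lam.T + np.diag(self.residual_variances)
        D = np.diag(self.item_sds)
        return self.intercepts.copy(), D @ std_cov @ D


def default_generating_parameters() -> GeneratingParameters:
    """The posterior-mean three-factor truth set: standardized loadings
    0.821-0.936, intercepts 3.88-4.55, residual variances 0.124-0.326, factor
    correlations 0.505-0.636; unit item SDs; per-item MCAR rates linearly
    spaced over the reported 0.02%-0.18% range."""
    return GeneratingParameters(
        loadings=_LOADINGS,
        intercepts=_INTERCEPTS,
        residual_variances=_RESIDUAL_VARIANCES,
        factor_correlations=_FACTOR_CORR,
        item_sds=np.ones(12),
        missing_rates=np.linspace(0.0002, 0.0018, 12),
    )


@dataclass(frozen=True)
class ResponseMatrix:
    """n x p item responses; missing entries are NaN.  ``likert`` mode holds
    integers 1-5 (stored as floats so NaN can mark missing)."""

    values: np.ndarray
    item_names: tuple[str, ...]
    mode: str = "continuous"

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 2:
            raise ValueError("values must be an n x p matrix")
        if self.values.shape[1] != len(self.item_names):
            raise ValueError("item_names length does not match column count")
        if self.values.shape[0] < 1:
            raise ValueError("response matrix must have at least one row")
        if self.mode == "likert":
            finite = self.values[~np.isnan(self.values)]
            if finite.size and (np.any(finite != np.round(finite)) or finite.min() < 1 or finite.max() > 5):
                raise ValueError("likert-mode responses must be integers in 1..5")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.item_names))


def generate_responses(
    gp: GeneratingParameters, n: int, mode: str = "continuous", seed: int | None = 0
) -> ResponseMatrix:
    """Draw n respondents from the generating model.

    Deterministic in (gp, n, mode, seed).  ``likert`` rounds to the nearest
    integer and clips to [1, 5], which attenuates sample correlations
    slightly relative to the continuous population values.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mode not in ("continuous", "likert"):
        raise ValueError(f"mode must be 'continuous' or 'likert', got {mode!r}")
    rng = np.random.default_rng(seed)
    R = gp.factor_correlations
    chol = np.linalg.cholesky(R)  # PD guaranteed by GeneratingParameters
    eta = rng.standard_normal((n, gp.m)) @ chol.T
    eps = rng.standard_normal((n, gp.p)) * np.sqrt(gp.residual_variances)
    y = gp.intercepts + (eta @ gp.lam.T + eps) * gp.item_sds
    if mode == "likert":
        y = np.clip(np.round(y), 1, 5)
    return ResponseMatrix(values=y, item_names=gp.item_names, mode=mode)


def inject_missingness(rm: ResponseMatrix, rates, seed: int | None = 0) -> ResponseMatrix:
    """Set each cell of item j missing independently with probability rates[j]
    (missing completely at random)."""
    rates = np.broadcast_to(np.asarray(rates, dtype=float), (rm.p,))
    if np.any(rates < 0) or np.any(rates >= 1):
        raise ValueError("missing rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    mask = rng.random(rm.values.shape) < rates
    values = rm.values.copy()
    values[mask] = np.nan
    return replace(rm, values=values)


def complete_cases(rm: ResponseMatrix) -> ResponseMatrix:
    """Rows with no missing entries, in their original order."""
    keep = ~np.isnan(rm.values).any(axis=1)
    if not keep.any():
        raise ValueError("no complete cases remain")
    return replace(rm, values=rm.values[keep])


# -- CSV round-trip --------------------------------------------------------

def write_responses(rm: ResponseMatrix, path) -> None:
    """One respondent per row, header of item names, missing as empty field."""
    rm.to_frame().to_csv(path, index=False)


def read_responses(path, mode: str = "continuous") -> ResponseMatrix:
    """Read an item-response CSV (missing as empty field or "NA").  In likert
    mode, non-missing values outside {1..5} raise a validation error."""
    df = pd.read_csv(path, na_values=["NA"])
    if df.shape[1] < 1 or df.shape[0] < 1:
        raise ValueError(f"empty or malformed response file: {path}")
    values = df.to_numpy(dtype=float)
    return ResponseMatrix(values=values, item_names=tuple(df.columns), mode=mode)


def load_generator_config(path) -> tuple[GeneratingParameters, dict]:
    """Read a YAML/JSON generator config: n, mode, seed, plus optional
    overrides of any GeneratingParameters field.  Returns (parameters,
    run settings)."""
    with open(path) as fh:
        cfg = json.load(fh) if str(path).endswith(".json") else yaml.safe_load(fh)
    gp = default_generating_parameters()
    overrides = {k: v for k, v in cfg.items() if k in GeneratingParameters.__dataclass_fields__}
    if overrides:
        if "item_names" in overrides:
            overrides["item_names"] = tuple(overrides["item_names"])
        if "factor_sizes" in overrides:
            overrides["factor_sizes"] = tuple(overrides["factor_sizes"])
        gp = replace(gp, **overrides)
    run = {k: cfg.get(k, d) for k, d in (("n", 3868), ("mode", "continuous"), ("seed", 0))}
    return gp, run
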