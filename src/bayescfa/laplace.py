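"""Generic mode finding, finite-difference Hessians and Laplace evidence.

These helpers operate on an arbitrary unnormalized log-density f(x) over an
unconstrained parameter vector; the CFA-specific wrappers live in
:mod:`bayescfa.compare` and :mod:`bayescfa.sampler`.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

__all__ = ["find_map", "numeric_hessian", "laplace_evidence"]

_BIG = 1e12


def find_map(
    logpost,
    x0: np.ndarray,
    n_starts: int = 5,
    jitter: float = 0.5,
    seed: int | None = 0,
    maxiter: int = 2000,
):
    """Maximize an unnormalized log posterior by L-BFGS-B with multi-start.

    The first start is ``x0`` itself; the remaining ``n_starts - 1`` starts are
    x0 plus N(0, jitter^2) noise.  Returns (x_map, logpost_at_map).  Raises if
    no start converges to a finite optimum.
    """
    x0 = np.asarray(x0, dtype=float)
    rng = np.random.default_rng(None if seed is None else [int(seed) & 0x7FFFFFFF, 0x5EED])

    def neg(x):
        v = logpost(x)
        return _BIG if not np.isfinite(v) else -v

    best_x, best_val = None, np.inf
    for s in range(max(1, n_starts)):
        start = x0 if s == 0 else x0 + jitter * rng.standard_normal(x0.size)
        res = optimize.minimize(neg, start, method="L-BFGS-B", options={"maxiter": maxiter})
        if np.isfinite(res.fun) and res.fun < best_val and res.fun < _BIG / 2:
            best_x, best_val = res.x, res.fun
    if best_x is None:
        raise RuntimeError("MAP optimization failed to find a finite optimum in all starts")
    return best_x, -best_val


def numeric_hessian(f, x: np.ndarray, rel_step: float = 1e-4, max_halvings: int = 8) -> np.ndarray:
    """Symmetric central-difference Hessian of a scalar function.

    Step per coordinate is ``rel_step * max(1, |x_i|)``.  When the mode sits
    near a support boundary (e.g. a correlation approaching +-1) a stencil
    point can fall outside the support; the step for that entry is then
    halved until all four evaluations are finite.
    """
    x = np.asarray(x, dtype=float)
    d = x.size
    h0 = rel_step * np.maximum(1.0, np.abs(x))
    H = np.empty((d, d))
    f0 = f(x)
    if not np.isfinite(f0):
        raise ValueError("function is not finite at the expansion point")

    def stencil(hi, hj, i, j):
        ei = np.zeros(d)
        ej = np.zeros(d)
        ei[i] = hi
        ej[j] = hj
        return f(x + ei + ej), f(x + ei - ej), f(x - ei + ej), f(x - ei - ej)

    for i in range(d):
        hi = h0[i]
        for _ in range(max_halvings):
            ei = np.zeros(d)
            ei[i] = hi
            fp, fm = f(x + ei), f(x - ei)
            if np.isfinite(fp) and np.isfinite(fm):
                H[i, i] = (fp - 2.0 * f0 + fm) / hi**2
                break
            hi *= 0.5
        else:
            raise ValueError(f"could not evaluate Hessian diagonal {i} inside the support")
    for i in range(d):
        for j in range(i + 1, d):
            hi, hj = h0[i], h0[j]
            for _ in range(max_halvings):
                vals = stencil(hi, hj, i, j)
                if all(np.isfinite(v) for v in vals):
                    H[i, j] = H[j, i] = (vals[0] - vals[1] - vals[2] + vals[3]) / (4.0 * hi * hj)
                    break
                hi *= 0.5
                hj *= 0.5
            else:
                raise ValueError(
                    f"could not evaluate Hessian entry ({i},{j}) inside the support")
    return H


def laplace_evidence(logpost, x_map: np.ndarray, hessian: np.ndarray | None = None) -> float:
    """Laplace approximation to the log marginal likelihood:

        log ML ~= logpost(x_map) + (d/2) log(2 pi) - 0.5 log |H|,

    where H is the Hessian of the negative log posterior at the mode.
    ``logpost`` must be the full unnormalized log posterior (log likelihood +
    properly normalized log prior, with any transform Jacobian included).
    Raises when H is not positive definite, naming the offending eigenvalue.
    """
    x_map = np.asarray(x_map, dtype=float)
    H = -numeric_hessian(logpost, x_map) if hessian is None else np.asarray(hessian, dtype=float)
    H = 0.5 * (H + H.T)
    eigvals = np.linalg.eigvalsh(H)
    if eigvals[0] <= 0:
        raise ValueError(
            f"negative-log-posterior Hessian is not positive definite at the mode "
            f"(smallest eigenvalue {eigvals[0]:.3e})"
        )
    d = x_map.size
    return float(logpost(x_map) + 0.5 * d * np.log(2.0 * np.pi) - 0.5 * np.sum(np.log(eigvals)))


def regularized_covariance(hessian: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    """Inverse of a Hessian with eigenvalues clipped away from zero, for use
    as a proposal covariance."""
    H = 0.5 * (hessian + hessian.T)
    w, V = np.linalg.eigh(H)
    w = np.maximum(w, floor * max(1.0, w.max()))
    return (V / w) @ V.T
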