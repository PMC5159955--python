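"""Sparse inverse covariance estimation by the graphical lasso.

The precision matrix Theta is the minimiser over positive-definite
matrices of the L1-penalised negative Gaussian log-likelihood

    tr(S Theta) - log det(Theta) + lam * ||Theta||_1,

where the L1 norm runs over ALL entries of Theta, diagonal included.
The coordinate-descent solver (scikit-learn's graphical lasso) penalises
only the off-diagonal, but since the diagonal of a positive-definite
matrix is positive the two problems coincide after absorbing the
diagonal penalty into the input:

    argmin tr(S T) - logdet T + lam ||T||_1
  = argmin tr((S + lam I) T) - logdet T + lam ||offdiag(T)||_1.

A ``penalize_diagonal=False`` switch gives the off-diagonal-only variant
used by some implementations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.covariance import graphical_lasso
from sklearn.exceptions import ConvergenceWarning

from .msa import N_STATES

DEFAULT_LAMBDA = 0.01


@dataclass
class PrecisionMatrix:
    """Estimated sparse precision matrix and solver diagnostics."""

    theta: np.ndarray
    lam: float
    objective_value: float
    converged: bool
    n_iterations: int
    penalize_diagonal: bool = True
    #: bisection trajectory of (lam, block_density) pairs, when lambda was
    #: selected by target density
    lambda_trace: list = field(default_factory=list)

    @property
    def p(self) -> int:
        return self.theta.shape[0]


def objective(sigma_hat: np.ndarray, theta: np.ndarray, lam: float,
              penalize_diagonal: bool = True) -> float:
    """The penalised objective tr(S Theta) − log det Theta + lam‖Theta‖₁."""
    sign, logdet = np.linalg.slogdet(theta)
    if sign <= 0:
        raise ValueError("theta must be positive definite (log det undefined)")
    l1 = np.abs(theta).sum()
    if not penalize_diagonal:
        l1 -= np.abs(np.diag(theta)).sum()
    return float(np.sum(sigma_hat * theta) - logdet + lam * l1)


def glasso_estimate(
    sigma_hat: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
    tol: float = 1e-4,
    max_iter: int = 200,
    penalize_diagonal: bool = True,
) -> PrecisionMatrix:
    """Estimate the sparse precision matrix of a positive-definite input.

    Parameters
    ----------
    sigma_hat : (p, p) array
        Symmetric positive-definite covariance estimate.
    lam : float
        Non-negative sparsity penalty.  ``lam = 0`` returns the plain
        inverse.
    tol : float
        Duality-gap convergence tolerance of the coordinate-descent
        solver.
    penalize_diagonal : bool
        If True (default) the L1 penalty covers the diagonal, matching
        the element-wise definition of ``||Theta||_1``.

    Returns
    -------
    PrecisionMatrix
        With ``converged=False`` (and a warning) rather than an error if
        the solver hit ``max_iter``.
    """
    sigma_hat = np.asarray(sigma_hat, dtype=float)
    if sigma_hat.ndim != 2 or sigma_hat.shape[0] != sigma_hat.shape[1]:
        raise ValueError("sigma_hat must be square")
    if np.max(np.abs(sigma_hat - sigma_hat.T)) > 1e-8:
        raise ValueError("sigma_hat must be symmetric")
    if lam < 0:
        raise ValueError("lam must be non-negative")
    min_eig = float(np.linalg.eigvalsh(sigma_hat)[0])
    if min_eig <= 0:
        raise ValueError(
            f"sigma_hat must be positive definite (smallest eigenvalue {min_eig:.3e}); "
            "apply shrinkage first"
        )

    if lam == 0:
        theta = np.linalg.inv(sigma_hat)
        theta = 0.5 * (theta + theta.T)
        return PrecisionMatrix(
            theta=theta, lam=0.0,
            objective_value=objective(sigma_hat, theta, 0.0),
            converged=True, n_iterations=0,
            penalize_diagonal=penalize_diagonal,
        )

    emp = sigma_hat + lam * np.eye(sigma_hat.shape[0]) if penalize_diagonal else sigma_hat
    with warnings.catch_warnings():
        # the inner coordinate-descent solver warns freely; convergence of
        # the outer problem is judged from the dual-gap trace below
        warnings.simplefilter("ignore", ConvergenceWarning)
        # the inner lasso tolerance caps the achievable outer dual gap, so
        # tie it to the requested tol; an over-tight inner tolerance can
        # destabilise the solver on large blocks, hence the relaxed retry
        try:
            _, theta, costs, n_iter = graphical_lasso(
                emp, alpha=lam, tol=tol, enet_tol=min(tol, 1e-4),
                max_iter=max_iter, return_costs=True, return_n_iter=True,
            )
        except FloatingPointError:
            _, theta, costs, n_iter = graphical_lasso(
                emp, alpha=lam, tol=tol, enet_tol=1e-4,
                max_iter=max_iter, return_costs=True, return_n_iter=True,
            )
    converged = bool(costs) and abs(costs[-1][1]) < tol
    if not converged:
        warnings.warn(
            f"graphical lasso did not converge in {max_iter} iterations "
            f"(dual gap {costs[-1][1]:.3e})",
            RuntimeWarning, stacklevel=2,
        )
    theta = 0.5 * (theta + theta.T)
    return PrecisionMatrix(
        theta=theta, lam=float(lam),
        objective_value=objective(sigma_hat, theta, lam, penalize_diagonal),
        converged=converged, n_iterations=int(n_iter),
        penalize_diagonal=penalize_diagonal,
    )


def block_density(theta: np.ndarray, n_states: int = N_STATES, atol: float = 1e-10) -> float:
    """Fraction of off-diagonal ``n_states x n_states`` blocks with any
    entry above ``atol`` in magnitude."""
    p = theta.shape[0]
    if p % n_states != 0:
        raise ValueError(f"matrix order {p} is not a multiple of {n_states}")
    L = p // n_states
    blocks = np.abs(theta).reshape(L, n_states, L, n_states).max(axis=(1, 3))
    off = ~np.eye(L, dtype=bool)
    return float((blocks[off] > atol).mean()) if L > 1 else 0.0


def select_lambda_by_density(
    sigma_hat: np.ndarray,
    target_density: float,
    bracket: tuple[float, float] = (1e-4, 1.0),
    rel_tol: float = 0.2,
    max_bisect: int = 25,
    **glasso_kwargs,
) -> tuple[float, PrecisionMatrix]:
    """Bisect lambda until the off-diagonal block density of Theta is
    within ``rel_tol`` (relative) of ``target_density``.

    Density is non-increasing in lambda, so plain bisection applies.
    Returns the bracket endpoint's solution if the target is unreachable
    inside the bracket.  The bisection trajectory is recorded on the
    returned :class:`PrecisionMatrix` as ``lambda_trace``.
    """
    if not 0 < target_density < 1:
        raise ValueError("target_density must lie in (0, 1)")
    lo, hi = bracket
    if not (0 <= lo < hi):
        raise ValueError(f"invalid bracket {bracket}")

    trace: list[tuple[float, float]] = []

    def solve(lam: float) -> tuple[PrecisionMatrix, float]:
        prec = glasso_estimate(sigma_hat, lam=lam, **glasso_kwargs)
        dens = block_density(prec.theta)
        trace.append((lam, dens))
        return prec, dens

    prec_lo, dens_lo = solve(lo)
    if dens_lo <= target_density:  # even the loosest penalty is too sparse
        prec_lo.lambda_trace = trace
        return lo, prec_lo
    prec_hi, dens_hi = solve(hi)
    if dens_hi >= target_density:  # even the tightest penalty is too dense
        prec_hi.lambda_trace = trace
        return hi, prec_hi

    best_lam, best_prec, best_err = lo, prec_lo, abs(dens_lo - target_density)
    for _ in range(max_bisect):
        mid = 0.5 * (lo + hi)
        prec_mid, dens_mid = solve(mid)
        err = abs(dens_mid - target_density)
        if err < best_err:
            best_lam, best_prec, best_err = mid, prec_mid, err
        if err <= rel_tol * target_density:
            break
        if dens_mid > target_density:
            lo = mid
        else:
            hi = mid
    best_prec.lambda_trace = trace
    return best_lam, best_prec


def kkt_residuals(sigma_hat: np.ndarray, prec: PrecisionMatrix) -> np.ndarray:
    """Stationarity residual R = sigma_hat − Theta⁻¹ + lam·sign-term.

    At the optimum, |sigma_hat − Theta⁻¹| <= lam off the support and
    equals lam·sign(theta_ij) on it (for the fully penalised problem,
    diagonal included).  Returned as the raw matrix sigma_hat − Theta⁻¹
    for the caller to compare against lam.
    """
    W = np.linalg.inv(prec.theta)
    return sigma_hat - W
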