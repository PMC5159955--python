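"""Weighted site frequencies, sample covariance, and shrinkage to positive
definiteness.

The covariance of an alignment of length L over 21 states is the
21L x 21L matrix

    S[(i,a),(j,b)] = f(A_i B_j) - f(A_i) f(B_j),

built from weighted single-site and pair-site frequencies.  Because the
rows of an MSA never populate all 21 states at every column, S is
(effectively always) singular.  It is made invertible by the
empirical-Bayes shrinkage step

    sigma_hat = S + (p - 1) / (n * tr(S)) * I_p,

applied repeatedly — with the increment recomputed from the current
trace — until the smallest eigenvalue clears a scale-relative floor.
Only the diagonal moves; every off-diagonal entry of S is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .msa import EncodedMSA, N_STATES


class DegenerateAlignmentError(ValueError):
    """All-constant alignment: tr(S) = 0, shrinkage undefined."""


class ShrinkageConvergenceError(RuntimeError):
    pass


@dataclass
class FrequencyTables:
    """Weighted empirical frequencies of an alignment.

    ``single`` is (L, 21) with rows summing to 1; ``pair`` is
    (L, L, 21, 21) with each (i, j) slab summing to 1.  The diagonal
    slabs pair[i, i] are diagonal matrices equal to diag(single[i]).
    """

    single: np.ndarray
    pair: np.ndarray

    @property
    def L(self) -> int:
        return self.single.shape[0]


@dataclass
class ShrunkCovariance:
    """Sample covariance S and its shrinkage-adjusted form sigma_hat.

    ``n`` is the sequence count used in the shrinkage increment
    (p - 1) / (n * tr); ``n_shrink_steps`` counts increment applications.
    """

    S: np.ndarray
    n: Optional[float] = None
    sigma_hat: Optional[np.ndarray] = None
    n_shrink_steps: int = 0
    min_eigenvalue: Optional[float] = None

    @property
    def p(self) -> int:
        return self.S.shape[0]


def site_frequencies(msa: EncodedMSA, pseudocount: float = 0.0) -> FrequencyTables:
    """Weight-normalised single and pair site frequencies.

    ``pseudocount`` adds a flat count to every cell before normalising
    (off by default: making the covariance invertible is the shrinkage
    step's job, not the frequencies').
    """
    n, L, q = msa.n, msa.L, N_STATES
    w = msa.weights
    wsum = w.sum()
    # one-hot expansion: X[r, i*q + a] = w-free indicator
    X = np.zeros((n, L * q))
    X[np.arange(n)[:, None], np.arange(L) * q + msa.codes] = 1.0
    single = (w @ X).reshape(L, q) / wsum
    pair = ((w[:, None] * X).T @ X).reshape(L, q, L, q).transpose(0, 2, 1, 3) / wsum
    if pseudocount > 0:
        single = (single * wsum + pseudocount) / (wsum + q * pseudocount)
        pair = (pair * wsum + pseudocount) / (wsum + q * q * pseudocount)
        # keep the diagonal slabs consistent with the singles
        for i in range(L):
            pair[i, i] = np.diag(single[i])
    return FrequencyTables(single=single, pair=pair)


def sample_covariance(freq: FrequencyTables) -> ShrunkCovariance:
    """Covariance S[(i,a),(j,b)] = pair(i,j,a,b) − single(i,a)·single(j,b)."""
    L, q = freq.L, N_STATES
    s = freq.single.reshape(L * q)
    S = freq.pair.transpose(0, 2, 1, 3).reshape(L * q, L * q) - np.outer(s, s)
    S = 0.5 * (S + S.T)  # remove accumulation asymmetry
    return ShrunkCovariance(S=S)


def shrink_to_pd(
    cov: ShrunkCovariance,
    n: float,
    pd_tolerance: Optional[float] = None,
    max_steps: int = 1000,
) -> ShrunkCovariance:
    """Add (p−1)/(n·tr) to the diagonal until positive definite.

    The increment is recomputed from the current trace at every step, so
    successive increments shrink as the diagonal grows.  ``pd_tolerance``
    defaults to ``1e-8 * tr(S) / p``, a scale-relative eigenvalue floor.
    A matrix already satisfying the floor is returned unchanged with
    ``n_shrink_steps = 0``.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    S = cov.S
    p = S.shape[0]
    tr0 = float(np.trace(S))
    if tr0 <= 0:
        raise DegenerateAlignmentError(
            "tr(S) <= 0: the alignment is constant at every column"
        )
    if pd_tolerance is None:
        pd_tolerance = 1e-8 * tr0 / p

    sigma = S.copy()
    min_eig = _smallest_eigenvalue(sigma)
    steps = 0
    while min_eig <= pd_tolerance:
        if steps >= max_steps:
            raise ShrinkageConvergenceError(
                f"not positive definite after {max_steps} shrinkage steps "
                f"(smallest eigenvalue {min_eig:.3e}, tolerance {pd_tolerance:.3e})"
            )
        delta = (p - 1) / (n * float(np.trace(sigma)))
        sigma[np.diag_indices_from(sigma)] += delta
        min_eig += delta  # eigenvalues of A + cI are lambda_i + c
        steps += 1
    return ShrunkCovariance(
        S=S, n=float(n), sigma_hat=sigma, n_shrink_steps=steps, min_eigenvalue=min_eig
    )


def _smallest_eigenvalue(A: np.ndarray) -> float:
    # eigvalsh is needed once at the start; the contract is an eigenvalue
    # bound, and eigenvalues of A + cI are lambda_i + c thereafter
    return float(np.linalg.eigvalsh(A)[0])


def shrinkage_increment(S: np.ndarray, n: float) -> float:
    """The per-step diagonal increment (p−1)/(n·tr(S))."""
    p = S.shape[0]
    return (p - 1) / (n * float(np.trace(S)))
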