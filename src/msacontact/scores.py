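"""Column-pair coupling scores, average product correction, and contact
ranking.

A column pair (i, j) of the alignment owns a 21x21 block of the
precision matrix.  Its raw coupling score is the L1 norm of the 20x20
amino-acid sub-block — gap-state rows and columns contribute nothing:

    C_ij = sum_{a,b in amino acids} |Theta_ij^{ab}|.

Raw couplings carry entropic and phylogenetic background that is well
approximated by a product of per-column propensities; the average
product correction (APC) removes it:

    corrected_ij = C_ij - mean_i(C) * mean_j(C) / grand_mean(C),

where mean_i(C) is the mean of C_i. over all other columns and the grand
mean runs over all off-diagonal pairs.  Corrected scores, filtered by a
minimum sequence separation, are ranked into the final contact list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .glasso import PrecisionMatrix
from .msa import N_STATES

logger = logging.getLogger(__name__)

DEFAULT_MIN_SEPARATION = 5


@dataclass
class ContactScoreMatrix:
    """Raw and APC-corrected L x L coupling score matrices.

    ``col_means[i]`` is the mean raw coupling of column i to all other
    columns; ``grand_mean`` is the mean over all off-diagonal pairs.
    The diagonal never enters any mean.
    """

    raw: np.ndarray
    corrected: Optional[np.ndarray] = None
    col_means: Optional[np.ndarray] = None
    grand_mean: Optional[float] = None

    @property
    def L(self) -> int:
        return self.raw.shape[0]


@dataclass(frozen=True)
class ContactPrediction:
    """One ranked contact: 1-based columns i < j, descending-score rank."""

    i: int
    j: int
    score: float
    rank: int


def coupling_norms(theta: PrecisionMatrix | np.ndarray, L: Optional[int] = None) -> ContactScoreMatrix:
    """Raw coupling matrix from the precision matrix block L1 norms.

    Only the 20x20 amino-acid sub-block of each 21x21 column-pair block
    contributes; the gap state is excluded.  The diagonal raw_ii is
    computed (same formula) but is never ranked or averaged.
    """
    mat = theta.theta if isinstance(theta, PrecisionMatrix) else np.asarray(theta)
    p = mat.shape[0]
    if L is None:
        if p % N_STATES != 0:
            raise ValueError(f"matrix order {p} is not a multiple of {N_STATES}")
        L = p // N_STATES
    if p != L * N_STATES:
        raise ValueError(f"precision matrix order {p} does not match 21*L = {L * N_STATES}")
    blocks = np.abs(mat).reshape(L, N_STATES, L, N_STATES)
    raw = blocks[:, :20, :, :20].sum(axis=(1, 3))
    raw = 0.5 * (raw + raw.T)
    return ContactScoreMatrix(raw=raw)


def apc_correct(scores: ContactScoreMatrix) -> ContactScoreMatrix:
    """Fill the APC-corrected matrix from the raw couplings.

    With an all-zero raw matrix the correction is undefined (grand mean
    zero); the corrected matrix is then defined as all-zero and a note
    is logged.
    """
    C = scores.raw
    L = C.shape[0]
    if L < 2:
        raise ValueError("APC needs at least two columns")
    off = ~np.eye(L, dtype=bool)
    col_means = (C.sum(axis=1) - np.diag(C)) / (L - 1)
    grand_mean = float(C[off].mean())
    if grand_mean == 0.0:
        logger.info("all-zero raw coupling matrix; APC-corrected scores set to zero")
        corrected = np.zeros_like(C)
    else:
        corrected = C - np.outer(col_means, col_means) / grand_mean
    return ContactScoreMatrix(
        raw=C, corrected=corrected, col_means=col_means, grand_mean=grand_mean
    )


def rank_contacts(
    scores: ContactScoreMatrix, min_separation: int = DEFAULT_MIN_SEPARATION
) -> list[ContactPrediction]:
    """All pairs i < j with |i − j| >= min_separation, sorted by
    descending corrected score; ties broken by (i, j) ascending."""
    if scores.corrected is None:
        raise ValueError("corrected scores not filled; run apc_correct first")
    L = scores.L
    iu, ju = np.triu_indices(L, k=max(1, min_separation))
    vals = scores.corrected[iu, ju]
    order = np.lexsort((ju, iu, -vals))  # primary: score desc; then i, j asc
    return [
        ContactPrediction(i=int(iu[o]) + 1, j=int(ju[o]) + 1, score=float(vals[o]), rank=r + 1)
        for r, o in enumerate(order)
    ]


def minmax_normalise(values: np.ndarray) -> np.ndarray:
    """Affine map onto [0, 1]; a constant input maps to all-0.5."""
    lo, hi = float(np.min(values)), float(np.max(values))
    if hi == lo:
        return np.full_like(np.asarray(values, dtype=float), 0.5)
    return (values - lo) / (hi - lo)


def write_rr(
    contacts: list[ContactPrediction],
    path: str | Path,
    target_sequence: Optional[str] = None,
    header_fields: Optional[dict] = None,
    normalise: bool = False,
) -> None:
    """Write a CASP RR contact list: ``i j 0 8 score`` per line.

    The distance bounds 0 and 8 encode the 8 A contact definition.  With
    ``normalise=True`` scores are min-max mapped to [0, 1] so the last
    column can be read as a probability.
    """
    path = Path(path)
    lines = []
    if header_fields:
        for k, v in header_fields.items():
            lines.append(f"REMARK {k}={v}")
    if target_sequence:
        lines.append(target_sequence)
    if contacts:
        svals = np.array([c.score for c in contacts])
        if normalise:
            svals = minmax_normalise(svals)
        for c, s in zip(contacts, svals):
            lines.append(f"{c.i} {c.j} 0 8 {s:.6f}")
    path.write_text("\n".join(lines) + "\n")


def read_rr(path: str | Path) -> tuple[list[ContactPrediction], dict]:
    """Read a CASP RR file back into ranked predictions + header dict."""
    header: dict = {}
    rows: list[tuple[int, int, float]] = []
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.upper().startswith(("PFRMAT", "TARGET", "MODEL", "AUTHOR", "METHOD", "END")):
            continue
        if ln.upper().startswith("REMARK"):
            body = ln[6:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                header[k.strip()] = v.strip()
            continue
        parts = ln.split()
        if len(parts) == 5:
            try:
                i, j = int(parts[0]), int(parts[1])
                score = float(parts[4])
            except ValueError:
                continue  # sequence line resembling records
            rows.append((i, j, score))
        # anything else (e.g. the target sequence line) is skipped
    rows.sort(key=lambda t: (-t[2], t[0], t[1]))
    return (
        [ContactPrediction(i=i, j=j, score=s, rank=r + 1) for r, (i, j, s) in enumerate(rows)],
        header,
    )
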