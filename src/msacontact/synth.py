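"""Synthetic alignments with planted couplings, and toy structures.

The generator draws alignment columns independently from a fixed
background amino-acid distribution, then overwrites designated column
pairs: with probability equal to the coupling strength the two columns
jointly take one of a small set of preferred state combinations.  This
joint-categorical mixture creates exactly the cross-column covariance
structure the contact pipeline consumes, without the cost of sampling a
full pairwise (Potts) model; a slow Gibbs sampler over such a model is
provided separately for stress tests.

Toy structures place a self-avoiding Ca trace so that a requested set
of residue pairs — and only those, among pairs separated by at least 6
positions — sit within the 8 A contact cutoff.  Cb atoms are placed at
a fixed 0.5 A pseudo-random offset from Ca: synthetic fixture geometry,
chosen so Cb-Cb and Ca-Ca contact maps agree, not chemically realistic.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy.optimize import minimize

from .msa import AA_ALPHABET, GAP_CODE, EncodedMSA

# Robinson-Robinson style background usage frequencies, ordered by the
# package alphabet ACDEFGHIKLMNPQRSTVWY; deliberately non-uniform so
# near-conserved columns arise naturally
BACKGROUND = np.array([
    0.0787, 0.0153, 0.0535, 0.0668, 0.0397, 0.0696, 0.0229, 0.0590,
    0.0595, 0.0963, 0.0241, 0.0414, 0.0484, 0.0398, 0.0540, 0.0683,
    0.0541, 0.0673, 0.0110, 0.0303,
])
BACKGROUND /= BACKGROUND.sum()

N_PREFERRED_COMBOS = 3


@dataclass
class SyntheticMSASpec:
    """Recipe for a synthetic alignment with known coupled column pairs.

    ``coupling`` is the probability mass moved onto the preferred state
    combinations of each planted pair; ``redundancy`` appends
    (redundancy - 1) near-copies of every row, each mutated at one
    position; ``planted_pairs`` uses 0-based column indices.
    """

    L: int
    n: int
    planted_pairs: tuple[tuple[int, int], ...] = ()
    coupling: float = 0.9
    gap_rate: float = 0.0
    redundancy: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.L < 1 or self.n < 1:
            raise ValueError("L and n must be positive")
        if not 0 <= self.coupling <= 1:
            raise ValueError("coupling must lie in [0, 1]")
        if not 0 <= self.gap_rate < 1:
            raise ValueError("gap_rate must lie in [0, 1)")
        if self.redundancy < 1:
            raise ValueError("redundancy must be >= 1")
        seen: set[int] = set()
        pairs = []
        for i, j in self.planted_pairs:
            if not (0 <= i < self.L and 0 <= j < self.L and i != j):
                raise ValueError(f"planted pair {(i, j)} outside alignment of length {self.L}")
            if i in seen or j in seen:
                raise ValueError("planted pairs must be disjoint in columns")
            seen.update((i, j))
            pairs.append((min(i, j), max(i, j)))
        self.planted_pairs = tuple(pairs)


def default_planted_pairs(
    L: int, k: int, min_separation: int = 5, seed: int = 0
) -> tuple[tuple[int, int], ...]:
    """k column-disjoint pairs with |i − j| >= min_separation."""
    rng = np.random.default_rng(seed)
    if 2 * k > L:
        raise ValueError(f"cannot place {k} disjoint pairs in {L} columns")
    for _ in range(200):
        cols = rng.permutation(L)[: 2 * k]
        pairs = [tuple(sorted((int(cols[2 * t]), int(cols[2 * t + 1])))) for t in range(k)]
        if all(j - i >= min_separation for i, j in pairs):
            return tuple(pairs)
    raise ValueError(
        f"planted separation >= {min_separation} infeasible for L={L}, k={k}"
    )


def generate_msa(spec: SyntheticMSASpec) -> tuple[EncodedMSA, set[tuple[int, int]]]:
    """Sample an alignment from the spec; returns (msa, planted truth).

    Deterministic under ``spec.seed``: the same spec yields bit-identical
    codes.
    """
    rng = np.random.default_rng(spec.seed)
    n, L = spec.n, spec.L
    codes = rng.choice(20, size=(n, L), p=BACKGROUND).astype(np.int8)

    for i, j in spec.planted_pairs:
        # fixed preferred combos per pair, drawn once from the seed stream
        combos = rng.choice(20, size=(N_PREFERRED_COMBOS, 2), replace=True)
        coupled = rng.random(n) < spec.coupling
        which = rng.integers(0, N_PREFERRED_COMBOS, size=n)
        codes[coupled, i] = combos[which[coupled], 0].astype(np.int8)
        codes[coupled, j] = combos[which[coupled], 1].astype(np.int8)

    if spec.gap_rate > 0:
        gaps = rng.random((n, L)) < spec.gap_rate
        gaps[0] = False  # the first row is the target and stays gap-free,
        codes[gaps] = GAP_CODE  # as in query-anchored alignment formats

    if spec.redundancy > 1:
        copies = []
        for _ in range(spec.redundancy - 1):
            dup = codes[:n].copy()
            pos = rng.integers(0, L, size=n)
            dup[np.arange(n), pos] = rng.integers(0, 20, size=n).astype(np.int8)
            copies.append(dup)
        codes = np.vstack([codes] + copies)

    return EncodedMSA(codes=codes), set(spec.planted_pairs)


def gibbs_msa(
    L: int,
    n: int,
    planted_pairs: Iterable[tuple[int, int]],
    coupling_strength: float = 2.0,
    n_sweeps: int = 50,
    seed: int = 0,
) -> tuple[EncodedMSA, set[tuple[int, int]]]:
    """Slow pairwise-model (Potts) Gibbs sampler for stress tests.

    Fields are log-background; each planted pair carries a coupling
    matrix J with ``coupling_strength`` on a random permutation's
    diagonal.  Each sequence is an independent chain of ``n_sweeps``
    full Gibbs sweeps.
    """
    rng = np.random.default_rng(seed)
    pairs = [tuple(sorted(p)) for p in planted_pairs]
    h = np.log(BACKGROUND)
    J: dict[tuple[int, int], np.ndarray] = {}
    for i, j in pairs:
        perm = rng.permutation(20)
        Jij = np.zeros((20, 20))
        Jij[np.arange(20), perm] = coupling_strength
        J[(i, j)] = Jij

    partner: dict[int, list[tuple[int, np.ndarray]]] = {}
    for (i, j), Jij in J.items():
        partner.setdefault(i, []).append((j, Jij))
        partner.setdefault(j, []).append((i, Jij.T))

    codes = np.empty((n, L), dtype=np.int8)
    for r in range(n):
        x = rng.choice(20, size=L, p=BACKGROUND)
        for _ in range(n_sweeps):
            for c in range(L):
                logits = h.copy()
                for other, Jmat in partner.get(c, ()):
                    logits = logits + Jmat[:, x[other]]
                pvec = np.exp(logits - logits.max())
                pvec /= pvec.sum()
                x[c] = rng.choice(20, p=pvec)
        codes[r] = x
    return EncodedMSA(codes=codes), set(pairs)


def write_flat(msa: EncodedMSA, path) -> None:
    """One aligned sequence per line (PSICOV flat format)."""
    with open(path, "w") as fh:
        fh.write("\n".join(msa.sequences()) + "\n")


def write_fasta(msa: EncodedMSA, path) -> None:
    with open(path, "w") as fh:
        for k, seq in enumerate(msa.sequences()):
            name = msa.ids[k] if msa.ids else f"seq{k + 1}"
            fh.write(f">{name}\n{seq}\n")


# --- toy structures ---------------------------------------------------

_BOND = 3.8       # consecutive Ca spacing, A
_CONTACT_TARGET = 6.0   # optimiser pulls requested pairs below this
_CLEAR_TARGET = 9.5     # and pushes every other sep>=6 pair above this
_CB_OFFSET = 0.5        # synthetic Cb offset magnitude, A


def _chain_energy(flat: np.ndarray, L: int, want: np.ndarray, avoid_i: np.ndarray,
                  avoid_j: np.ndarray) -> tuple[float, np.ndarray]:
    """Penalty + gradient for the Ca trace layout."""
    X = flat.reshape(L, 3)
    grad = np.zeros_like(X)
    energy = 0.0

    def pair_term(ii, jj, target, sign, weight):
        # sign=+1 penalises d > target, sign=-1 penalises d < target
        nonlocal energy
        d_vec = X[ii] - X[jj]
        d = np.sqrt((d_vec ** 2).sum(axis=1)) + 1e-12
        viol = np.maximum(sign * (d - target), 0.0)
        energy += weight * (viol ** 2).sum()
        coef = (2.0 * weight * sign * viol / d)[:, None]
        np.add.at(grad, ii, coef * d_vec)
        np.add.at(grad, jj, -coef * d_vec)

    ii = np.arange(L - 1)
    # bonds both ways: equality as two inequalities
    pair_term(ii, ii + 1, _BOND, +1, 10.0)
    pair_term(ii, ii + 1, _BOND, -1, 10.0)
    if want.size:
        pair_term(want[:, 0], want[:, 1], _CONTACT_TARGET, +1, 4.0)
    if avoid_i.size:
        pair_term(avoid_i, avoid_j, _CLEAR_TARGET, -1, 2.0)
    # soft self-avoidance for every non-adjacent pair
    ai, aj = np.triu_indices(L, k=2)
    pair_term(ai, aj, 3.5, -1, 1.0)
    return energy, grad.ravel()


def make_toy_structure(
    L: int,
    contacts: Iterable[tuple[int, int]],
    seed: int = 0,
    sequence: Optional[str] = None,
    max_retries: int = 8,
) -> str:
    """PDB text for a Ca/Cb chain realising exactly the requested
    contacts among pairs with separation >= 6.

    ``contacts`` uses 0-based residue indices.  ``sequence`` defaults to
    poly-alanine; glycines receive no Cb atom (their contact coordinate
    is the Ca, matching the contact definition).  Raises ``ValueError``
    if no layout satisfying the map is found within the retry budget.
    """
    contacts = {tuple(sorted(map(int, p))) for p in contacts}
    for i, j in contacts:
        if not (0 <= i < j < L):
            raise ValueError(f"contact {(i, j)} outside chain of length {L}")
        if j - i < 6:
            raise ValueError(f"contact {(i, j)} has separation < 6; not evaluable")
    if sequence is None:
        sequence = "A" * L
    if len(sequence) != L:
        raise ValueError("sequence length must equal L")

    iu, ju = np.triu_indices(L, k=6)
    in_want = np.array([(a, b) in contacts for a, b in zip(iu, ju)])
    want = np.stack([iu[in_want], ju[in_want]], axis=1) if in_want.any() else np.empty((0, 2), int)
    avoid_i, avoid_j = iu[~in_want], ju[~in_want]

    rng = np.random.default_rng(seed)
    for attempt in range(max_retries):
        # start from a loose helix plus noise so the chain can fold in
        t = np.arange(L) * 0.7
        X0 = np.stack([6 * np.cos(t), 6 * np.sin(t), 1.8 * t], axis=1)
        X0 += rng.normal(scale=0.5 + 0.5 * attempt, size=X0.shape)
        res = minimize(
            _chain_energy, X0.ravel(), args=(L, want, avoid_i, avoid_j),
            jac=True, method="L-BFGS-B", options={"maxiter": 2000},
        )
        X = res.x.reshape(L, 3)
        is_gly = np.array([c == "G" for c in sequence])[:, None]
        # Cb offsets are pseudo-random; redraw until the Cb-Cb map
        # matches, since a 0.5 A offset can flip near-boundary pairs
        for _ in range(25):
            dirs = rng.normal(size=(L, 3))
            dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
            cb = X + _CB_OFFSET * dirs
            coord = np.where(is_gly, X, cb)
            d = np.sqrt(((coord[:, None] - coord[None, :]) ** 2).sum(axis=2))
            ok_want = all(d[i, j] < 8.0 for i, j in contacts)
            ok_avoid = np.all(d[avoid_i, avoid_j] >= 8.0) if avoid_i.size else True
            if ok_want and ok_avoid:
                return _pdb_text(X, cb, sequence)
    raise ValueError(
        f"could not realise the requested contact map within {max_retries} attempts"
    )


_THREE = {"A": "ALA", "G": "GLY", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
          "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
          "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
          "W": "TRP", "Y": "TYR"}


def _pdb_text(ca: np.ndarray, cb: np.ndarray, sequence: str) -> str:
    buf = io.StringIO()
    serial = 1
    for r, letter in enumerate(sequence):
        resname = _THREE.get(letter, "ALA")
        atoms = [("CA", ca[r])]
        if letter != "G":
            atoms.append(("CB", cb[r]))
        for name, xyz in atoms:
            buf.write(
                f"ATOM  {serial:5d}  {name:<3s} {resname:3s} A{r + 1:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00          "
                f"{name[0]:>2s}\n"
            )
            serial += 1
    buf.write("END\n")
    return buf.getvalue()
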