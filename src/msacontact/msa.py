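"""Alignment reading, integer encoding, and sequence weighting.

Alignments are encoded over a 21-letter alphabet: the 20 canonical amino
acids in alphabetical one-letter order (``ACDEFGHIKLMNPQRSTVWY``, codes
0-19) plus a gap state (code 20).  Ambiguous or non-canonical letters
(B, J, O, U, X, Z) and the gap characters ``-`` and ``.`` all map to the
gap state; the 21-state model has no other sink for them.

Near-duplicate sequences carry little independent evolutionary
information, so each row is down-weighted by the number of rows within a
fractional-identity threshold of it.  The sum of the weights is the
effective number of sequences, Neff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
GAP_CODE = 20
N_STATES = 21
ALPHABET = AA_ALPHABET + "-"

#: default fractional-identity threshold for clustering near-duplicates
DEFAULT_IDENTITY_THRESHOLD = 0.62

_ENCODE = np.full(256, GAP_CODE, dtype=np.int8)
for _i, _aa in enumerate(AA_ALPHABET):
    _ENCODE[ord(_aa)] = _i
    _ENCODE[ord(_aa.lower())] = _i


class AlignmentFormatError(ValueError):
    """Raised for ragged, empty, or otherwise malformed alignments."""


@dataclass
class EncodedMSA:
    """Integer-encoded multiple sequence alignment.

    Attributes
    ----------
    codes : (n, L) int8 array
        Integer codes in [0, 20]; 20 is the gap state.
    ids : list of str or None
        Per-row identifiers (from FASTA headers) if available.
    weights : (n,) float array
        Per-row weights in (0, 1]; unit weights until
        :func:`compute_weights` is applied.
    """

    codes: np.ndarray
    ids: Optional[list[str]] = None
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2 or self.codes.shape[0] < 1 or self.codes.shape[1] < 1:
            raise AlignmentFormatError(
                f"alignment must be a non-empty 2-D matrix, got shape {self.codes.shape}"
            )
        if self.codes.min() < 0 or self.codes.max() > GAP_CODE:
            raise AlignmentFormatError("alignment codes must lie in [0, 20]")
        if self.weights is None:
            self.weights = np.ones(self.codes.shape[0])
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.codes.shape[0],):
            raise ValueError("weights must have one entry per row")
        if np.any(self.weights <= 0) or np.any(self.weights > 1):
            raise ValueError("weights must lie in (0, 1]")

    @property
    def n(self) -> int:
        """Number of sequences (rows)."""
        return self.codes.shape[0]

    @property
    def L(self) -> int:
        """Alignment length (columns)."""
        return self.codes.shape[1]

    @property
    def neff(self) -> float:
        """Effective number of sequences, the sum of the row weights."""
        return float(self.weights.sum())

    def sequences(self) -> list[str]:
        """Decode back to letter strings (gap rendered as ``-``)."""
        lut = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
        return [bytes(lut[row]).decode() for row in self.codes]

    def ungapped_target(self) -> str:
        """First row with gap columns removed — the prediction target."""
        row = self.codes[0]
        return "".join(AA_ALPHABET[c] for c in row if c != GAP_CODE)


def encode_sequences(seqs: Sequence[str], ids: Optional[list[str]] = None) -> EncodedMSA:
    """Encode aligned letter strings into an :class:`EncodedMSA`."""
    if not seqs:
        raise AlignmentFormatError("empty input: no sequences")
    L = len(seqs[0])
    for k, s in enumerate(seqs):
        if len(s) != L:
            name = ids[k] if ids else f"line {k + 1}"
            raise AlignmentFormatError(
                f"ragged alignment: {name} has length {len(s)}, expected {L}"
            )
    if L == 0:
        raise AlignmentFormatError("empty input: zero-length sequences")
    mat = np.vstack(
        [_ENCODE[np.frombuffer(s.encode("ascii", "replace"), dtype=np.uint8)] for s in seqs]
    )
    return EncodedMSA(codes=mat, ids=ids)


def read_alignment(path: str | Path, format_hint: Optional[str] = None) -> EncodedMSA:
    """Read a flat (one sequence per line) or aligned-FASTA alignment.

    The format is auto-detected when ``format_hint`` is None: a first
    non-blank line starting with ``>`` means FASTA, anything else means
    the flat format used by PSICOV-style tools.  Returns an MSA with
    unit weights; call :func:`compute_weights` before frequency counting.
    """
    path = Path(path)
    text = path.read_text()
    lines = [ln.rstrip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise AlignmentFormatError(f"empty alignment file: {path}")
    fmt = format_hint
    if fmt is None:
        fmt = "fasta" if lines[0].startswith(">") else "flat"
    if fmt not in ("flat", "fasta"):
        raise ValueError(f"unknown format hint {fmt!r} (expected 'flat' or 'fasta')")

    if fmt == "flat":
        return encode_sequences(lines)

    ids: list[str] = []
    seqs: list[str] = []
    current: list[str] = []
    for ln in lines:
        if ln.startswith(">"):
            if ids:
                seqs.append("".join(current))
            ids.append(ln[1:].split()[0] if len(ln) > 1 else f"seq{len(ids) + 1}")
            current = []
        else:
            if not ids:
                raise AlignmentFormatError("FASTA input does not start with a '>' header")
            current.append(ln)
    seqs.append("".join(current))
    return encode_sequences(seqs, ids=ids)


def compute_weights(
    msa: EncodedMSA, identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
) -> EncodedMSA:
    """Down-weight near-duplicate rows by inverse neighbour count.

    The weight of row ``r`` is ``1 / |{s : identity(r, s) >= t}|`` where
    identity is the fraction of the L columns at which the two rows carry
    the same code (gaps compare like any other state) and the neighbour
    set includes ``r`` itself.  Neff becomes the sum of weights.

    Returns a new :class:`EncodedMSA`; the input is not modified.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must lie in (0, 1]")
    codes = msa.codes
    n, L = codes.shape
    counts = np.zeros(n, dtype=np.int64)
    # chunked pairwise identity; O(n^2 L) but vectorised and memory-bounded
    chunk = max(1, int(2e7) // max(1, n * L))
    for start in range(0, n, chunk):
        block = codes[start : start + chunk]  # (b, L)
        ident = (block[:, None, :] == codes[None, :, :]).sum(axis=2)  # (b, n)
        counts[start : start + chunk] = (ident >= identity_threshold * L).sum(axis=1)
    weights = 1.0 / counts
    return replace(msa, weights=weights)


_LN_NEFF_EDGES = [4.0, 5.0, 6.0, 7.0, 8.0, 10.0]


def ln_neff_bin(neff: float) -> str:
    """Bin label for ln(Neff): one of [4,5), [5,6), [6,7), [7,8), [8,10).

    Values with ln(Neff) < 4 or >= 10 return ``"out-of-range"``.
    """
    if neff <= 0:
        raise ValueError(f"neff must be positive, got {neff}")
    x = math.log(neff)
    for lo, hi in zip(_LN_NEFF_EDGES[:-1], _LN_NEFF_EDGES[1:]):
        if lo <= x < hi:
            return f"[{lo:g},{hi:g})"
    return "out-of-range"
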