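"""Native contact maps and CASP-style evaluation metrics.

A residue pair is a native contact when its Cb-Cb distance (Ca for
glycine) in the reference structure is strictly below 8 Angstrom.
Predictions are assessed separately for short (6 <= |i-j| < 12), medium
(12 <= |i-j| < 24) and long (|i-j| >= 24) sequence-separation classes,
with reduced-list metrics (accuracy = TP/(TP+FP) and the Xd distance-
distribution shift) on the top L/k ranked pairs and full-list metrics
(Matthews correlation and precision-recall area) on every scored pair.

Residues absent from the structure are flagged unresolved and excluded
from every metric on both sides — they are never counted as
non-contacts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa
from Bio.SeqUtils import seq1
from sklearn.metrics import matthews_corrcoef, precision_recall_curve

from .scores import ContactPrediction, ContactScoreMatrix, minmax_normalise

CONTACT_CUTOFF = 8.0  # Angstrom, strict <


class StructureMappingError(ValueError):
    """Structure residues could not be mapped onto the target sequence."""


@dataclass(frozen=True)
class RangeClass:
    """Sequence-separation class: lo <= |i - j| < hi."""

    label: str
    lo: int
    hi: float

    def contains(self, separation: int) -> bool:
        return self.lo <= separation < self.hi


SHORT = RangeClass("short", 6, 12)
MEDIUM = RangeClass("medium", 12, 24)
LONG = RangeClass("long", 24, math.inf)
RANGE_CLASSES = (SHORT, MEDIUM, LONG)
#: no separation restriction beyond the conventional minimum of 6
ALL_RANGES = RangeClass("all", 6, math.inf)


@dataclass
class NativeContactMap:
    """Distance and boolean contact matrices for a target sequence.

    ``dist`` is (L, L) in Angstrom with NaN wherever either residue is
    unresolved; ``contact`` is True iff dist < 8 for resolved pairs.
    """

    dist: np.ndarray
    resolved: np.ndarray

    @property
    def L(self) -> int:
        return self.dist.shape[0]

    @property
    def contact(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.dist < CONTACT_CUTOFF

    def pair_indices(self, range_class: RangeClass) -> tuple[np.ndarray, np.ndarray]:
        """Upper-triangle (i, j) index arrays of resolved pairs in class."""
        L = self.L
        iu, ju = np.triu_indices(L, k=1)
        sep = ju - iu
        keep = (
            (sep >= range_class.lo)
            & (sep < range_class.hi)
            & self.resolved[iu]
            & self.resolved[ju]
        )
        return iu[keep], ju[keep]


def native_contact_map(
    structure_path: str | Path,
    target_sequence: str,
    chain_id: Optional[str] = None,
    min_mapped_fraction: float = 0.8,
) -> NativeContactMap:
    """Build a native contact map from a PDB file.

    Structure residues are aligned to the (ungapped) target sequence by
    a high-mismatch-cost global alignment, so only exactly matching
    residues map; at least ``min_mapped_fraction`` of the target must
    map.  The Cb atom provides the coordinate; Ca substitutes for
    glycine and for residues lacking a Cb.  Residues missing both atoms
    are flagged unresolved with a warning.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("target", str(structure_path))
    model = next(structure.get_models())  # first model if several
    chains = list(model.get_chains())
    if chain_id is not None:
        chains = [c for c in chains if c.id == chain_id]
        if not chains:
            raise StructureMappingError(f"chain {chain_id!r} not found in {structure_path}")
    elif len(chains) > 1:
        chains = chains[:1]
    chain = chains[0]

    residues = [r for r in chain.get_residues() if is_aa(r, standard=True)]
    if not residues:
        raise StructureMappingError(f"no standard amino-acid residues in {structure_path}")
    struct_seq = "".join(seq1(r.get_resname()) for r in residues)

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1000  # exact-match mapping only
    aligner.open_gap_score = -0.5
    aligner.extend_gap_score = -0.1
    aln = aligner.align(target_sequence, struct_seq)[0]

    L = len(target_sequence)
    coords = np.full((L, 3), np.nan)
    resolved = np.zeros(L, dtype=bool)
    for (t0, t1), (s0, s1) in zip(*aln.aligned):
        for off in range(t1 - t0):
            t, s = t0 + off, s0 + off
            if target_sequence[t] != struct_seq[s]:
                continue
            res = residues[s]
            atom = None
            if res.get_resname() != "GLY" and "CB" in res:
                atom = res["CB"]
            elif "CA" in res:
                atom = res["CA"]
            if atom is None:
                warnings.warn(
                    f"residue {res.get_id()} has neither CB nor CA; flagged unresolved",
                    stacklevel=2,
                )
                continue
            coords[t] = atom.get_coord()
            resolved[t] = True

    mapped = resolved.sum() / L
    if mapped < min_mapped_fraction:
        raise StructureMappingError(
            f"only {mapped:.0%} of target residues mapped onto the structure "
            f"(need >= {min_mapped_fraction:.0%})"
        )

    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=2))
    return NativeContactMap(dist=dist, resolved=resolved)


def _restrict_predictions(
    pred: Sequence[ContactPrediction], native: NativeContactMap, range_class: RangeClass
) -> list[ContactPrediction]:
    out = []
    for c in pred:
        sep = abs(c.j - c.i)
        if range_class.contains(sep) and native.resolved[c.i - 1] and native.resolved[c.j - 1]:
            out.append(c)
    return out


def accuracy_top(
    pred: Sequence[ContactPrediction],
    native: NativeContactMap,
    list_size: float,
    range_class: RangeClass,
) -> float:
    """Accuracy TP/(TP+FP) of the top ``floor(list_size)`` predictions
    within a separation class (resolved pairs only).

    Returns NaN when the restricted list is empty.
    """
    if list_size < 1:
        raise ValueError(f"list_size must be >= 1, got {list_size}")
    sel = _restrict_predictions(pred, native, range_class)[: int(list_size)]
    if not sel:
        return float("nan")
    contact = native.contact
    tp = sum(1 for c in sel if contact[c.i - 1, c.j - 1])
    return tp / len(sel)


N_XD_BINS = 15
XD_BIN_WIDTH = 4.0  # Angstrom; bins cover (0, 60], overflow into bin 15


def _bin_fractions(distances: np.ndarray) -> np.ndarray:
    """Fraction of distances per 4 A bin; > 60 A accumulates in bin 15."""
    idx = np.minimum(np.ceil(distances / XD_BIN_WIDTH).astype(int), N_XD_BINS) - 1
    counts = np.bincount(np.maximum(idx, 0), minlength=N_XD_BINS)[:N_XD_BINS]
    return counts / counts.sum()


def xd_score(
    pred: Sequence[ContactPrediction], native: NativeContactMap, range_class: RangeClass
) -> float:
    """Distance-distribution shift of predicted pairs vs all class pairs.

    Xd = sum_{i=1..15} (Pip_i - Pia_i) / (d_i * 15) with d_i = i/15 the
    normalised upper bound of the i-th 4 A bin, Pip the proportion of
    predicted pairs and Pia the proportion of all range-class pairs in
    bin i.  Positive Xd means predictions sit at shorter distances than
    chance; identical distributions give exactly 0.
    """
    sel = _restrict_predictions(pred, native, range_class)
    if not sel:
        return float("nan")
    pred_d = np.array([native.dist[c.i - 1, c.j - 1] for c in sel])
    iu, ju = native.pair_indices(range_class)
    if iu.size == 0:
        return float("nan")
    all_d = native.dist[iu, ju]
    pip = _bin_fractions(pred_d)
    pia = _bin_fractions(all_d)
    d = np.arange(1, N_XD_BINS + 1) / N_XD_BINS
    return float(np.sum((pip - pia) / (d * N_XD_BINS)))


def mcc_full(
    scores: ContactScoreMatrix,
    native: NativeContactMap,
    range_class: RangeClass,
    threshold_rule: str = "minmax-0.5",
) -> float:
    """Matthews correlation of the binarised full list of class pairs.

    ``minmax-0.5`` (default) min-max normalises the corrected scores to
    [0, 1] and calls contact above 0.5; ``max-mcc`` scans every score
    threshold and reports the best achievable MCC.  Zero marginals give
    MCC = 0 by convention.
    """
    if scores.corrected is None:
        raise ValueError("corrected scores not filled")
    iu, ju = native.pair_indices(range_class)
    if iu.size == 0:
        return float("nan")
    y = native.contact[iu, ju].astype(int)
    s = scores.corrected[iu, ju]
    if threshold_rule == "minmax-0.5":
        yhat = (minmax_normalise(s) > 0.5).astype(int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return float(matthews_corrcoef(y, yhat))
    if threshold_rule == "max-mcc":
        best = 0.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for t in np.unique(s):
                best = max(best, float(matthews_corrcoef(y, (s >= t).astype(int))))
        return best
    raise ValueError(f"unknown threshold_rule {threshold_rule!r}")


def confusion_counts(
    scores: ContactScoreMatrix,
    native: NativeContactMap,
    range_class: RangeClass,
) -> tuple[int, int, int, int]:
    """(TP, FP, TN, FN) under the minmax-0.5 binarisation."""
    iu, ju = native.pair_indices(range_class)
    if iu.size == 0:
        return 0, 0, 0, 0
    y = native.contact[iu, ju].astype(bool)
    yhat = minmax_normalise(scores.corrected[iu, ju]) > 0.5
    tp = int(np.sum(y & yhat))
    fp = int(np.sum(~y & yhat))
    tn = int(np.sum(~y & ~yhat))
    fn = int(np.sum(y & ~yhat))
    return tp, fp, tn, fn


def pr_auc(
    scores: ContactScoreMatrix, native: NativeContactMap, range_class: RangeClass
) -> float:
    """Area under the precision-recall curve of the full class ranking.

    Equal-score groups are processed atomically (one operating point per
    distinct score).  The curve is anchored at recall 0 with the
    precision of the highest-score group, and integrated over recall by
    the trapezoid rule.  Returns NaN when the class has no positive
    pair.
    """
    if scores.corrected is None:
        raise ValueError("corrected scores not filled")
    iu, ju = native.pair_indices(range_class)
    if iu.size == 0:
        return float("nan")
    y = native.contact[iu, ju].astype(int)
    if y.sum() == 0:
        return float("nan")
    s = scores.corrected[iu, ju]
    precision, recall, _ = precision_recall_curve(y, s)
    # sklearn orders by increasing threshold and appends a (recall=0,
    # precision=1) anchor; drop it and anchor at the first group instead
    precision, recall = precision[:-1][::-1], recall[:-1][::-1]
    recall = np.concatenate(([0.0], recall))
    precision = np.concatenate(([precision[0]], precision))
    return float(np.trapezoid(precision, recall))


LIST_SIZE_DIVISORS = (10, 5, 2, 1)


def evaluation_report(
    pred: Sequence[ContactPrediction],
    scores: Optional[ContactScoreMatrix],
    native: NativeContactMap,
    L: Optional[int] = None,
) -> pd.DataFrame:
    """Tabulate every metric per range class.

    One row per (range class, metric); reduced-list accuracies and Xd at
    top L/10, L/5, L/2 and L with L the alignment length.  Full-list MCC
    and PR-AUC rows appear when a score matrix is supplied.
    """
    if L is None:
        L = native.L
    rows = []
    for rc in RANGE_CLASSES:
        for div in LIST_SIZE_DIVISORS:
            size = max(1, L // div)
            label = f"L/{div}" if div > 1 else "L"
            rows.append(
                {"range": rc.label, "metric": f"accuracy_top_{label}",
                 "value": accuracy_top(pred, native, size, rc)}
            )
        sel = _restrict_predictions(pred, native, rc)[: max(1, L // 2)]
        rows.append({"range": rc.label, "metric": "xd_top_L/2",
                     "value": xd_score(sel, native, rc)})
        if scores is not None:
            rows.append({"range": rc.label, "metric": "mcc_full",
                         "value": mcc_full(scores, native, rc)})
            rows.append({"range": rc.label, "metric": "auc_pr_full",
                         "value": pr_auc(scores, native, rc)})
            tp, fp, tn, fn = confusion_counts(scores, native, rc)
            for name, v in zip(("TP", "FP", "TN", "FN"), (tp, fp, tn, fn)):
                rows.append({"range": rc.label, "metric": name, "value": v})
    return pd.DataFrame(rows)
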