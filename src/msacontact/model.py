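"""Model/Results interface tying the pipeline together.

:class:`ContactModel` wraps an encoded alignment; ``fit()`` runs the
full chain — sequence weighting, weighted site frequencies, the 21L x
21L sample covariance, iterated empirical-Bayes shrinkage to positive
definiteness, graphical-lasso sparse inverse estimation, gap-excluded
block L1 coupling norms, average product correction, and ranking — and
returns a :class:`ContactResults` carrying every intermediate of
interest plus evaluation and export helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import __version__
from .covariance import (
    ShrunkCovariance,
    sample_covariance,
    shrink_to_pd,
    site_frequencies,
)
from .evaluate import NativeContactMap, evaluation_report, native_contact_map
from .glasso import (
    DEFAULT_LAMBDA,
    PrecisionMatrix,
    block_density,
    glasso_estimate,
    select_lambda_by_density,
)
from .msa import DEFAULT_IDENTITY_THRESHOLD, EncodedMSA, compute_weights, read_alignment
from .scores import (
    DEFAULT_MIN_SEPARATION,
    ContactPrediction,
    ContactScoreMatrix,
    apc_correct,
    coupling_norms,
    rank_contacts,
    write_rr,
)


class ContactModel:
    """Residue-residue contact model for one multiple sequence alignment.

    Parameters
    ----------
    msa : EncodedMSA
        The alignment.  Row weights are (re)computed during ``fit``.
    identity_threshold : float
        Fractional identity above which rows share weight.
    use_neff_in_shrinkage : bool
        Use the effective sequence count instead of the raw row count in
        the shrinkage increment (p-1)/(n tr S).
    pseudocount : float
        Optional flat pseudocount on the site frequencies (default 0:
        shrinkage alone handles singularity).
    """

    def __init__(
        self,
        msa: EncodedMSA,
        identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD,
        use_neff_in_shrinkage: bool = False,
        pseudocount: float = 0.0,
    ) -> None:
        self.msa = msa
        self.identity_threshold = identity_threshold
        self.use_neff_in_shrinkage = use_neff_in_shrinkage
        self.pseudocount = pseudocount

    @classmethod
    def from_alignment(cls, path: Union[str, Path], format_hint: Optional[str] = None,
                       **kwargs) -> "ContactModel":
        """Build a model straight from a flat or FASTA alignment file."""
        return cls(read_alignment(path, format_hint=format_hint), **kwargs)

    def fit(
        self,
        lam: float = DEFAULT_LAMBDA,
        target_density: Optional[float] = None,
        pd_tolerance: Optional[float] = None,
        max_shrink_steps: int = 1000,
        min_separation: int = DEFAULT_MIN_SEPARATION,
        tol: float = 1e-4,
        max_iter: int = 200,
        penalize_diagonal: bool = True,
    ) -> "ContactResults":
        """Run the full pipeline and return the fitted results.

        If ``target_density`` is given, the penalty is chosen by
        bisection to reach that fraction of nonzero off-diagonal
        precision blocks and ``lam`` is ignored.
        """
        msa = compute_weights(self.msa, self.identity_threshold)
        freq = site_frequencies(msa, pseudocount=self.pseudocount)
        cov = sample_covariance(freq)
        n_shrink = msa.neff if self.use_neff_in_shrinkage else msa.n
        cov = shrink_to_pd(cov, n=n_shrink, pd_tolerance=pd_tolerance,
                           max_steps=max_shrink_steps)
        if target_density is not None:
            lam, precision = select_lambda_by_density(
                cov.sigma_hat, target_density,
                tol=tol, max_iter=max_iter, penalize_diagonal=penalize_diagonal,
            )
        else:
            precision = glasso_estimate(
                cov.sigma_hat, lam=lam, tol=tol, max_iter=max_iter,
                penalize_diagonal=penalize_diagonal,
            )
        scores = apc_correct(coupling_norms(precision, L=msa.L))
        contacts = rank_contacts(scores, min_separation=min_separation)
        return ContactResults(
            model=self, msa=msa, cov=cov, precision=precision,
            scores=scores, contacts=contacts, min_separation=min_separation,
        )


@dataclass
class ContactResults:
    """Fitted contact prediction results.

    Attributes
    ----------
    msa : EncodedMSA
        The weighted alignment used for the fit.
    cov : ShrunkCovariance
        Sample covariance S and its positive-definite adjustment.
    precision : PrecisionMatrix
        The sparse inverse estimate and solver diagnostics.
    scores : ContactScoreMatrix
        Raw and APC-corrected L x L coupling scores.
    contacts : list of ContactPrediction
        Ranked predictions at the fitted minimum separation.
    """

    model: ContactModel
    msa: EncodedMSA
    cov: ShrunkCovariance
    precision: PrecisionMatrix
    scores: ContactScoreMatrix
    contacts: list[ContactPrediction]
    min_separation: int = DEFAULT_MIN_SEPARATION
    _native: Optional[NativeContactMap] = field(default=None, repr=False)

    @property
    def neff(self) -> float:
        return self.msa.neff

    @property
    def lam(self) -> float:
        return self.precision.lam

    def top_contacts(self, k: Optional[int] = None) -> pd.DataFrame:
        """The ranked contact list (top ``k`` if given) as a DataFrame."""
        sel = self.contacts if k is None else self.contacts[:k]
        return pd.DataFrame([{"rank": c.rank, "i": c.i, "j": c.j, "score": c.score}
                             for c in sel])

    def header_fields(self, **extra) -> dict:
        """Reproducibility header: alignment, fit, and version metadata."""
        fields = {
            "n": self.msa.n,
            "L": self.msa.L,
            "neff": f"{self.neff:.4f}",
            "identity_threshold": self.model.identity_threshold,
            "lambda": self.lam,
            "shrink_steps": self.cov.n_shrink_steps,
            "min_separation": self.min_separation,
            "use_neff_in_shrinkage": self.model.use_neff_in_shrinkage,
            "alphabet": "ACDEFGHIKLMNPQRSTVWY-",
            "version": __version__,
        }
        fields.update(extra)
        return fields

    def to_rr(self, path: Union[str, Path], normalise: bool = False, **extra_header) -> None:
        """Write the ranked list as a CASP RR file with a config header."""
        write_rr(
            self.contacts, path,
            target_sequence=self.msa.ungapped_target(),
            header_fields=self.header_fields(**extra_header),
            normalise=normalise,
        )

    def evaluate(
        self,
        structure: Union[str, Path, NativeContactMap],
        chain_id: Optional[str] = None,
    ) -> pd.DataFrame:
        """Score the predictions against a structure (path or map).

        Returns the per-range-class metric table: reduced-list
        accuracies, Xd, and full-list MCC / PR-AUC with confusion
        counts.
        """
        if isinstance(structure, NativeContactMap):
            native = structure
        else:
            native = native_contact_map(structure, self.msa.ungapped_target(),
                                        chain_id=chain_id)
        self._native = native
        return evaluation_report(self.contacts, self.scores, native, L=self.msa.L)

    def summary(self, top: int = 10) -> str:
        """Human-readable fit summary, statsmodels style."""
        msa, prec = self.msa, self.precision
        dens = block_density(prec.theta)
        lines = [
            "Contact Model Results",
            "=" * 56,
            f"{'Sequences (n)':<34}{msa.n:>22}",
            f"{'Alignment length (L)':<34}{msa.L:>22}",
            f"{'Effective sequences (Neff)':<34}{msa.neff:>22.2f}",
            f"{'Covariance order (p = 21 L)':<34}{self.cov.p:>22}",
            f"{'Shrinkage steps to PD':<34}{self.cov.n_shrink_steps:>22}",
            f"{'Penalty lambda':<34}{prec.lam:>22.4g}",
            f"{'GLasso iterations':<34}{prec.n_iterations:>22}",
            f"{'Converged':<34}{str(prec.converged):>22}",
            f"{'Objective value':<34}{prec.objective_value:>22.6g}",
            f"{'Off-diagonal block density':<34}{dens:>22.4f}",
            "-" * 56,
            f"Top {min(top, len(self.contacts))} contacts (i, j, APC-corrected score):",
        ]
        for c in self.contacts[:top]:
            lines.append(f"  {c.rank:>4}  {c.i:>4} {c.j:>4}  {c.score:>12.4f}")
        return "\n".join(lines)

    def plot_contact_map(self, native: Optional[NativeContactMap] = None, top: Optional[int] = None,
                         ax=None):
        """Predicted contacts (lower triangle) vs native (upper), if given."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        L = self.msa.L
        sel = self.contacts if top is None else self.contacts[:top]
        xs = [c.j for c in sel]
        ys = [c.i for c in sel]
        ax.scatter(ys, xs, s=8, marker="s", label="predicted")
        if native is not None:
            iu, ju = np.nonzero(np.triu(np.nan_to_num(native.dist) < 8, k=1))
            ax.scatter(ju + 1, iu + 1, s=8, marker="s", c="0.6", label="native")
        ax.set_xlim(0, L + 1)
        ax.set_ylim(L + 1, 0)
        ax.set_xlabel("residue j")
        ax.set_ylabel("residue i")
        ax.legend(loc="upper right", fontsize=8)
        return ax
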