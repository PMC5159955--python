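# Methods

## Model and pipeline

The package treats contact prediction as sparse Gaussian graphical
model selection over the one-hot encoding of an alignment. A sequence
row is viewed as a draw of `p = 21L` indicator variables (20 amino
acids + gap per column); conditional independence between two columns,
given all others, corresponds to a zero `21 × 21` block of the
precision matrix. The pipeline is:

1. **Encoding** — alphabet `ACDEFGHIKLMNPQRSTVWY` (codes 0–19) plus gap
   (20). `-`, `.` and the non-canonical letters B, J, O, U, X, Z map to
   the gap state: the 21-state model has no other sink, and ambiguous
   residues carry no usable coevolution signal. Lowercase is
   uppercased. The first alignment row is the prediction target.
2. **Sequence weighting** — weight of a row = 1 / (number of rows,
   itself included, with fractional identity ≥ 0.62 over all columns,
   gaps comparing as a 21st state). Neff = Σ weights. The 0.62
   threshold is the convention of the PSICOV/DCA literature; it is a
   flag, not a fitted constant. Weighting is O(n²L) with chunked
   vectorisation.
3. **Frequencies and covariance** — weighted single and pair
   frequencies give `S[(i,a),(j,b)] = f(A_i B_j) − f(A_i) f(B_j)`. No
   pseudocount by default: making S invertible is the shrinkage step's
   job, not the frequencies' (a flat pseudocount flag exists for
   experimentation). Memory is O(L²·21²); alignments up to a few
   hundred columns fit comfortably.
4. **Shrinkage to positive definiteness** — Σ̂ = S + k·δ·I with
   δ = (p−1)/(n·tr) recomputed from the current trace at each step, and
   k the smallest integer for which the smallest eigenvalue exceeds
   `pd_tolerance` (default `1e-8 · tr(S)/p`, a scale-relative floor).
   Iterating the literal update, rather than applying one larger
   multiple, keeps each application exactly the estimator form; on
   realistic inputs one step suffices because δ (≈ 0.02 for n = 1000,
   L = 30) dwarfs the tolerance. `n` is the raw sequence count by
   default (`use_neff_in_shrinkage` substitutes Neff). Off-diagonal
   entries are provably untouched. An all-constant alignment
   (tr S = 0) raises a degenerate-alignment error.
5. **Sparse inverse** — the L1-penalised log-likelihood
   `tr(Σ̂Θ) − log det Θ + λ‖Θ‖₁` is minimised with the penalty on
   **all** entries, diagonal included, matching the element-wise
   definition of the norm. The coordinate-descent graphical-lasso
   solver penalises only the off-diagonal, so the diagonal penalty is
   absorbed exactly by solving on Σ̂ + λI (valid because the diagonal
   of a PD matrix is positive); a `penalize_diagonal=False` flag gives
   the other convention. Default λ = 0.01 on the covariance scale of
   one-hot indicators, in the range PSICOV-family methods use; a
   bisection (`select_lambda_by_density`) alternatively targets a
   chosen fraction of nonzero off-diagonal blocks, with the recorded
   trajectory exposing the density-vs-λ monotonicity. Convergence is
   declared on the dual gap (default tol 1e-4, max 200 sweeps); the
   inner lasso tolerance is tied to the outer tol, with a relaxed
   retry because an over-tight inner tolerance can destabilise the
   solver on large blocks. Non-convergence returns the iterate with
   `converged=False` and a warning rather than failing.
6. **Scores** — raw coupling `C_ij` = L1 norm of the `20 × 20`
   amino-acid sub-block (gap row/column excluded). APC:
   `C_ij − C̄_(i·)C̄_(·j)/C̄` with the column means taken over **all**
   other columns — not separation-filtered ones — and the grand mean
   over all off-diagonal pairs; the diagonal never enters any mean. An
   all-zero raw matrix (possible at extreme λ) defines the corrected
   matrix as zero with a logged note. Ranking keeps pairs with
   |i−j| ≥ 5, descending score, ties broken by (i, j) ascending so
   output is total and bit-reproducible.

## Evaluation

Native contacts: Cβ–Cβ distance < 8 Å strictly (a pair at exactly
8.0 Å is a non-contact), Cα for glycine and for residues lacking Cβ.
Structure residues are mapped to the target sequence by a global
alignment with prohibitive mismatch cost, i.e. exact subsequence
matching over resolved residues; < 80% mapped is an error. Unresolved
residues are excluded from numerator and denominator of every metric —
never counted as non-contacts.

Reduced-list metrics take the top ⌊L/k⌋ of the ranking *after*
restriction to the separation class and to resolved pairs, with L the
alignment length. Accuracy = TP/(TP+FP). Xd uses 15 bins of 4 Å over
(0, 60] (overflow into bin 15), proportions on the 0–1 scale, and
`d_i = i/15` — the CASP convention of normalising the upper bin bound
by 60 Å; implementations differ on `d_i`, so this is a documented
convention. Xd is exactly 0 when the predicted and
whole-target binned distributions coincide, positive when predictions
are enriched at short distances.

Full-list MCC binarises scores by min-max normalisation with a 0.5
threshold by default (`max-mcc`, the best threshold over the score
range, is available; the binarisation rule is a convention, exposed as
a flag). Zero marginals give MCC = 0. PR-AUC integrates precision over
recall by the trapezoid rule with equal-score groups processed
atomically; the curve is anchored at recall 0 with the precision of the
highest-score group, so an uninformative (all-tied) ranking scores
exactly the contact prevalence, and a perfect ranking scores 1.

## Synthetic data

The generator emulates the covariance structure the pipeline consumes,
not protein evolution. Columns are i.i.d. draws from a fixed
Robinson–Robinson-style background (non-uniform, so near-conserved
columns arise naturally); each planted pair, with probability equal to
the coupling strength, jointly takes one of three preferred state
combinations drawn once per pair from the seed stream. Gaps are
injected i.i.d. at `gap_rate` (the target row stays gap-free, as in
query-anchored alignment formats); redundancy appends near-copies
mutated at one position, exercising the weighting scheme. Everything is
bit-deterministic under the seed. What this does **not** model:
phylogenetic correlation between rows, indel structure, secondary
structure, or entropic gradients along the chain — so passing the
planted-recovery tests demonstrates correctness of the estimator chain,
not field performance on real families. A slow per-sequence Gibbs
sampler over an explicit pairwise (Potts) model is included for stress
tests.

Toy structures place a self-avoiding Cα trace by penalised
quasi-Newton layout (bonds at 3.8 Å, requested pairs pulled under 6 Å,
all other pairs of separation ≥ 6 pushed beyond 9.5 Å) and verify the
realised Cβ–Cβ contact map exactly, retrying with new starts until it
matches. Cβ sits at a fixed 0.5 Å pseudo-random offset from Cα —
synthetic fixture geometry chosen so Cα and Cβ maps agree, not
chemistry.

## Default study conditions

The end-to-end recovery condition used by the tests and the acceptance
script is L = 30, n = 1000, five planted pairs at separation ≥ 5,
coupling 0.9, gap rate 0.05, 20 independent replicates — an alignment
depth and signal strength at which a direct-coupling method should be
essentially perfect, so the pass criterion (all pairs in the top 10 in
≥ 90% of replicates) tests the machinery, not luck. The solver
cross-check uses an independent proximal-gradient (ISTA) minimiser
with backtracking on random PD matrices of order ≤ 10; agreement is
asserted on the objective value (1e-5), which is insensitive to the
flat directions that make parameter-level comparison fragile.

## Known limitations

- Dense matrices throughout: O(L²·441) memory caps practical L around
  a thousand columns on ordinary hardware.
- The λ default is a convention; benchmark-grade accuracy on real
  families is sensitive to it, and no data-driven default is claimed.
- The structure mapper requires exact residue identity; it will refuse
  structures with engineered mutations relative to the target.
- `evaluate` on an RR file reconstructs a full score matrix with zeros
  for unlisted pairs; full-list metrics are only meaningful when the
  RR list covers all pairs of the evaluated classes (the default
  minimum separation 5 does cover them).
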