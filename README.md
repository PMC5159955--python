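# msacontact

Protein residue–residue contact prediction from multiple sequence
alignments, built on an empirical-Bayes covariance shrinkage estimator
and the graphical lasso, with a CASP-style evaluation suite and a
synthetic-alignment generator with planted couplings.

## The problem and the method

Columns of a deep multiple sequence alignment (MSA) that coevolve tend
to be close in the folded structure, so statistical couplings between
columns are a primary source of distance constraints for structure
prediction. Naive covariation measures mix direct and transitive
couplings; sparse inverse covariance estimation separates them.

Each alignment of `n` sequences and `L` columns is encoded over 21
states (20 amino acids + gap). From weighted site frequencies the
sample covariance

```
S_ij^ab = f(A_i B_j) − f(A_i) f(B_j)
```

is formed — a `21L × 21L` matrix that is essentially always singular,
because no column realises all 21 states. Instead of the smoothed
estimator `aS + bF` used by PSICOV-style predictors, the covariance is
repaired by the empirical-Bayes (Haff) shrinkage

```
Σ̂ = S + (p − 1)/(n · tr S) · I_p ,    p = 21L,
```

applied repeatedly (the increment recomputed from the current trace)
until Σ̂ is positive definite. The sparse precision matrix is then the
graphical-lasso estimate

```
Θ̂ = argmin_{Θ ≻ 0}  tr(Σ̂ Θ) − log det Θ + λ‖Θ‖₁ ,
```

whose nonzero `21 × 21` blocks carry the direct couplings between
column pairs. The contact score of pair `(i, j)` is the L1 norm of the
`20 × 20` amino-acid sub-block (gap contributions excluded),

```
C_ij = Σ_ab |Θ_ij^ab| ,
```

cleaned of entropic/phylogenetic background by the average product
correction (APC)

```
score_ij = C_ij − C̄_(i·) C̄_(·j) / C̄ ,
```

and ranked (minimum sequence separation 5) into a CASP RR contact
list. Evaluation against a structure uses the standard contact
definition (Cβ–Cβ distance < 8 Å, Cα for glycine) and reports top-L/k
accuracy `TP/(TP+FP)` and the Xd distance-distribution shift on reduced
lists, plus MCC and precision–recall area on full lists, for short
(6 ≤ |i−j| < 12), medium (12 ≤ |i−j| < 24) and long (|i−j| ≥ 24)
separations.

## Worked example

```python
from msacontact import ContactModel, SyntheticMSASpec, generate_msa, make_toy_structure

spec = SyntheticMSASpec(L=30, n=800, planted_pairs=((2, 10), (5, 23), (1, 28)),
                        coupling=0.9, gap_rate=0.05, seed=42)
msa, truth = generate_msa(spec)
results = ContactModel(msa).fit()
print(results.summary(top=5))
```

```
Contact Model Results
========================================================
Sequences (n)                                        800
Alignment length (L)                                  30
Effective sequences (Neff)                        800.00
Covariance order (p = 21 L)                          630
Shrinkage steps to PD                                  1
Penalty lambda                                      0.01
GLasso iterations                                      3
Converged                                           True
Objective value                                 -1000.22
Off-diagonal block density                        0.1310
--------------------------------------------------------
Top 5 contacts (i, j, APC-corrected score):
     1     6   24       18.4915
     2     3   11       17.9047
     3     2   29       11.8928
     4     6   25        0.2094
     5     8   13        0.1203
```

One shrinkage step sufficed to make the 630 × 630 covariance positive
definite, and the three planted pairs — (3, 11), (6, 24) and (2, 29) in
1-based numbering — occupy the top three ranks, separated from the
background by two orders of magnitude in score. Evaluating against a
toy structure that realises exactly the planted contacts:

```python
pdb = make_toy_structure(30, sorted(truth), seed=42, sequence=msa.sequences()[0])
open("toy.pdb", "w").write(pdb)
report = results.evaluate("toy.pdb")
```

yields, per separation class, `mcc_full = 1.0` and `auc_pr_full = 1.0`
(every class ranks its single true contact first), and
`accuracy_top_L/10 = 0.33` — the top-3 list per class can contain only
the one native contact that exists there, so 1/3 is the ceiling for
this toy.

The same pipeline is available from the shell:

```sh
msacontact fixtures -o fx --seed 7          # synthetic MSA + toy PDB + truth
msacontact predict fx/alignment.flat -o fx/pred.rr
msacontact evaluate fx/pred.rr fx/structure.pdb --aln fx/alignment.flat
```

`predict` writes a CASP RR file (`i j 0 8 score` records) whose header
echoes the full run configuration (n, L, Neff, λ, shrinkage steps,
alphabet, version) so any run can be reproduced bit for bit.

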