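# Methods

## Problem and model

Most experimentally mapped phosphorylation sites have no annotated kinase,
so the kinase–substrate interaction (KSI) network is a sparse bipartite 0/1
matrix with a large hidden positive set. `ksimc` treats KSI prediction as
low-rank completion of a *heterogeneous* network matrix that couples three
sub-networks: kinase–kinase sequence similarity `M_KK` (m×m), substrate–
substrate similarity `M_SS` (n×n), and the known interactions `M_KS` (m×n):

```
M = [ M_KK   M_KS ]      (m+n) × (m+n), symmetric
    [ M_KS'  M_SS ]
```

The working assumption is that similar kinases phosphorylate similar
substrates, which makes the completed matrix approximately low-rank: a few
kinase/substrate "families" explain most edges. Unknown entries of the
interaction blocks are scored by solving

```
min  τ‖X‖* + ½‖X‖F²   s.t.  P_Ω(X) = P_Ω(M)
```

the convex nuclear-norm surrogate of rank minimisation (which is NP-hard),
with the singular value thresholding (SVT) iteration

```
X_k = D_τ(Y_{k-1})
Y_k = Y_{k-1} + δ · P_Ω(M − X_k),      Y_0 = ⌈τ/(δ‖P_Ω(M)‖₂)⌉ · δ · P_Ω(M)
```

where `D_τ` shrinks every singular value by τ and floors at zero, and `P_Ω`
zeroes entries outside the observed set Ω. Because M and Ω are symmetric,
every iterate is symmetric (asserted at 1e-10 each iteration); the score
block is nevertheless read out as the average of the two off-diagonal
blocks, a read-out invariant under transposition.

## Pipeline stages

1. **Similarity.** All-vs-all Smith–Waterman local alignment, BLOSUM62,
   affine gaps costing `gap_open + (L−1)·gap_extend` with open 10 /
   extend 0.5 (the EMBOSS `water` convention). Raw scores are normalised by
   the geometric mean of the self-alignment scores,
   `sim(a,b) = SW(a,b)/√(SW(a,a)·SW(b,b))`, which is standard in
   kernel-style protein similarity and guarantees a unit diagonal and values
   in [0,1] — properties the downstream threshold presupposes. An
   EMBOSS-style percent-positive normalisation is available as an
   alternative mode. The alignment engine is Biopython's `PairwiseAligner`;
   its scores are validated in the test suite against an independently coded
   cubic-time DP that enumerates every gap length explicitly.
2. **Adjustment.** A known edge (k, s1) induces a candidate edge (k, s2)
   whenever `sim(s1, s2) > t` strictly, default `t = 0.9`. One pass only:
   induced edges never seed further induction, so the adjustment cannot
   cascade and densify the network. The substrate side is the default
   (`adjust_mode=substrate`); kinase-side and both-sides variants are flags.
   `t = 1.0` is exactly the identity.
3. **Assembly and Ω.** Similarity blocks enter M as continuous values, not
   thresholded. Under the default `positives_only` policy Ω contains every
   entry of the two similarity blocks plus only the 1-entries of the
   interaction blocks: the interaction zeros are precisely the unknowns
   being predicted. (If zeros were observed, the constraint would pin them
   to 0 and a converged solver could never rank them; prediction would then
   depend entirely on early stopping. The `all_bipartite` policy is retained
   for that ablation.)
4. **Completion.** Defaults: `τ = 5(m+n)`, `δ = (m+n)/|Ω|`, stop when the
   relative residual `‖P_Ω(M−X_k)‖F/‖P_Ω(M)‖F < 1e-4` or after 500
   iterations; residual growth beyond 10× its initial value aborts with a
   divergence error. The δ default is deliberately the literal formula the
   method prescribes even though the SVT literature recommends the larger
   `1.2(m+n)²/|Ω|` (available as `delta="auto_literature"`); the literal
   choice is conservative — small steps, slow but stable progress. The
   kick-start multiplier uses the spectral norm (Frobenius behind a flag).
   Full dense SVD is the default backend, adequate below ~1000 nodes; a
   truncated `svds` backend computing only singular values above τ with an
   incremental-rank heuristic is available for larger systems.

## Evaluation protocols

**Ten-fold cross-validation.** Known positives are partitioned uniformly at
random into ten folds (sizes differ by at most one; deterministic per
seed). For each fold, the held-out positives are removed from the
interaction matrix *before* the adjustment step and the entire pipeline is
rerun on the training network — adjusting once on the full data would leak
test edges into training through similarity-propagated 1s, so the
adjustment is recomputed per fold and a programmatic guard asserts that no
held-out pair is present in the training matrix. Evaluation ranks held-out
positives (label 1) against all pairs never observed as positive (label 0);
training positives are excluded from the pool. The headline number is the
pooled (micro-averaged) ROC over all folds; per-fold AUCs are reported with
mean ± sd.

**De-novo test.** For a queried kinase, *all* of its known interactions are
deleted, the pipeline reruns, and the ROC is computed over that kinase's
row only (its true substrates vs all its other substrates). This models a
kinase arriving with no annotation, where only the sequence-similarity
channel can place it.

**ROC/AUC.** Computed in-package from the TPR/FPR definitions with tied
scores grouped at a single threshold and trapezoidal integration, which
makes the AUC exactly the tie-corrected Mann–Whitney U/(n₊·n₋); the suite
checks this identity against an exhaustive pairwise oracle and against
scikit-learn.

## Synthetic benchmark

The generator plants the structure the method assumes: per cluster, one
uniform-random ancestor sequence with members mutated i.i.d. per position
(substitution to a uniformly random different residue), and a bipartite
stochastic block model over the clusters, whose expected adjacency has rank
equal to the cluster count. A fraction of true edges is hidden as
recoverable ground truth. Defaults: 3 clusters, 8 kinases and 20 substrates
per cluster, length 200, mutation rate 0.05, within/between link
probabilities 0.8/0.02, 20% of edges hidden — an end-to-end run takes
seconds while leaving ≳300 positives, enough for a stable ten-fold AUC.
Sequences use a uniform 20-letter composition: cluster separation, not
biological realism, is what the tests need. What passing these tests shows
is that the implementation recovers planted low-rank bipartite structure
coupled to sequence clusters; it does not show that real kinase–substrate
data satisfies those assumptions, and the generator reproduces neither real
amino-acid composition, nor indels, nor the long-tailed degree
distributions of curated interaction databases (beyond being sparse with
many low-degree nodes).

## Numerical choices and degenerate inputs

- Similarity values are clipped at 1.0 against round-off; BLOSUM62's
  dominant diagonal makes cross-scores ≤ self-scores in practice.
- Ambiguity codes B/Z/X are scored by their extended BLOSUM62 rows; `*` and
  `-` are rejected with the offending character named.
- An empty Ω, an all-zero observed set, non-finite matrices, and a
  single-class label vector are hard errors; an all-zero interaction matrix
  is a warning (completion would have no bipartite signal).
- Ranked outputs break score ties lexicographically on
  (kinase_id, substrate_id), so every table is deterministic; output
  provenance headers carry config, seed and input digests but no
  timestamps, making reruns byte-identical.
- Fold splitting sorts pairs before shuffling, so the split depends only on
  the pair set and seed, not input order.

## Known limitations

- With the literal `δ = (m+n)/|Ω|` step size the solver often hits the
  500-iteration default cap before the 1e-4 residual on desk-scale systems;
  rankings are already stable well before convergence, but users wanting a
  converged solution should raise `max_iter` (the planted-recovery tests run
  with larger caps).
- Exact recovery of a planted low-rank matrix is only guaranteed when the
  sampling density is well above the information limit; on small systems
  (e.g. 10×10 rank-2 at 70% sampling) the nuclear-norm minimiser frequently
  differs from the planted matrix even though the solver is exact — the
  feasible minimiser can have strictly smaller nuclear norm than the truth.
- Quadratic all-vs-all alignment and dense SVD bound the practical scale to
  roughly a thousand proteins; the truncated backend relaxes the SVD cost
  but not the alignment cost.
- Only sequence information is used; no site-level features, protein–protein
  interaction context, or domain annotations.
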