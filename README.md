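# ksimc — kinase–substrate interaction prediction by matrix completion

Protein phosphorylation drives most cellular signalling, yet for the large
majority of experimentally mapped phosphosites the catalysing kinase is
unknown. `ksimc` predicts missing kinase–substrate interactions (KSIs) from
nothing but protein sequences and a list of known interactions, for
computational biologists who want a self-contained, reproducible
network-based predictor with its evaluation protocols built in.

## Method

Kinase–kinase and substrate–substrate similarities are computed by
Smith–Waterman local alignment (BLOSUM62, gap open 10, gap extend 0.5),
normalised to `sim(a,b) = SW(a,b)/√(SW(a,a)·SW(b,b)) ∈ [0,1]`. The known
bipartite network `M_KS` is first *adjusted*: an edge (k, s₁) induces
(k, s₂) whenever `sim(s₁,s₂) > t` (default t = 0.9, single pass). The three
sub-networks are then stacked into one symmetric heterogeneous matrix

    M = [ M_KK   M_KS ]
        [ M_KSᵀ  M_SS ]

and the unknown interaction entries are scored by nuclear-norm matrix
completion,

    min τ‖X‖* + ½‖X‖F²   s.t.  P_Ω(X) = P_Ω(M),

solved with the singular value thresholding (SVT) iteration
`X_k = D_τ(Y_{k−1})`, `Y_k = Y_{k−1} + δ·P_Ω(M − X_k)`, where `D_τ` shrinks
singular values by τ, `δ = (m+n)/|Ω|` and `τ = 5(m+n)` by default. Ω
contains the similarity blocks and the known positives; interaction zeros
are the unknowns being completed. See `docs/methods.md` for assumptions,
parameter semantics and limitations.

## Worked example

Generate a planted synthetic benchmark (3 sequence clusters, a bipartite
block-model network, 20% of true edges hidden), rank all pairs, and
cross-validate — all through the `ksimc` CLI:

```sh
$ ksimc simulate --out-dir demo --seed 0
INFO ksimc: wrote 24 kinases, 60 substrates, 322 observed / 402 true interactions to demo

$ ksimc predict --kinase-fasta demo/kinases.fasta --substrate-fasta demo/substrates.fasta \
                --interactions demo/interactions.tsv --out demo/scores.tsv
INFO ksimc: adjustment added 168 edges at t=0.9 (mode=substrate)
INFO ksimc: SVT: 500 iterations, final residual 0.198, converged=False
INFO ksimc: wrote 1440 ranked pairs to demo/scores.tsv

$ head -14 demo/scores.tsv | tail -2
rank	kinase_id	substrate_id	score	known
1	K11	S21	1.049657902	True
```

`demo/scores.tsv` ranks all 24×60 pairs by completed score (ties broken
lexicographically, so reruns are byte-identical); `known=True` flags pairs
that were in the training list, and high-ranking `known=False` rows are the
predictions. Scores are relative ranks, not probabilities — near 1 means
"as strongly supported as a known edge". The residual note is expected: at
the conservative default step size the ranking stabilises long before full
convergence (raise `--max-iter` for a converged solution).

```sh
$ ksimc crossval --kinase-fasta demo/kinases.fasta --substrate-fasta demo/substrates.fasta \
                 --interactions demo/interactions.tsv --out demo/cv.tsv
INFO ksimc.evaluation: pooled AUC 0.9005 (per-fold mean 0.9009)

$ tail -3 demo/cv.tsv
mean	0.90091419
sd	0.02137117756
pooled	0.9005486172
```

Ten-fold cross-validation removes each fold of known positives *before* the
adjustment step (no leakage), reruns the pipeline, and ranks the held-out
positives against all never-known pairs: pooled AUC 0.90 on this benchmark,
versus ≈0.5 when the network structure is destroyed. `ksimc denovo --kinase
K11 ...` runs the stricter protocol that deletes *all* of one kinase's
edges and measures their recovery. The same operations are available as a
library (`ksimc.cross_validate`, `ksimc.de_novo_test`,
`ksimc.run_pipeline_scores`).

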