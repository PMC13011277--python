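# Methods

## The screening model

The package operates on a typed multilayer network: a disease hub-gene set
D inside a protein–protein interaction (PPI) graph, herbs as sets of
compounds, and compounds as sets of protein targets. All identifiers are
opaque strings; distances are unweighted hops; the PPI is undirected with
self-loops dropped on read.

### Target-level association

For a herb h with target set T_h, the overlap rate is |T_h ∩ D| / |T_h|.
The denominator is the herb's own target count: with a hub set of ~8 genes
and herbs carrying hundreds of targets this produces values of order 0.005,
matching the scale of published per-herb tables; alternative denominators
(disease-set size, union) are exposed as options. The Hscore is the mass
of a two-step uniform random walk herb → compound → target that lands on a
disease gene:

    Hscore(h) = (1/|C_h|) Σ_{c ∈ C_h} |T_c ∩ D| / |T_c|.

Normalisation is per herb so compound-rich herbs are not trivially
favoured. A compound with no targets contributes zero (logged, not an
error).

### Network proximity

d_AB is the symmetric closest measure: the mean over members of each set of
the minimum hop distance to the other set. s_AB = d_AB − (d_AA + d_BB)/2
with self-excluded within-set minima; negative s_AB indicates topological
overlap of the two modules. Unreachable pairs contribute a penalty of
graph diameter + 1 (configurable) rather than being dropped, so
disconnected target sets are penalised. The proximity z-score standardises
d_AB against `n_perm` random draws of target sets degree-matched to A and B
in log2-spaced degree bins (adjacent bins merged until each holds ≥ 10
nodes, sampling without replacement within bins); n_perm ≥ 100 is enforced
and 1000 is the reference setting. All-pairs BFS distances are precomputed
once per graph, making each permutation a submatrix min/mean.

PageRank prioritisation is plain power iteration (damping 0.85, residual
1e-10, ≤ 10 000 iterations) with dangling-node mass redistributed
uniformly; nodes above the cutoff (default 3.00e-3) are retained.

### Empirical co-usage

Pair-level Pscore is the pair's co-prescription frequency normalised by the
table's maximum. A herb's Pscore is ε_h times the mean over its pairs,
where ε_h is the herb's maximum absolute factor loading. The exact printed
form of this statistic is not recoverable from the source material, so the
max-normalisation and the multiplicative role of ε are reconstructions kept
behind one function. Factor loadings come from an eigendecomposition of
the correlation matrix of co-occurrence profiles (principal-axis
approximation): deterministic, with a fixed sign convention (largest-|entry|
of each factor positive) so ε reproduces across platforms. Maximum-
likelihood factor analysis was deliberately not used — only ε is consumed
downstream, and the eigen route is exact and dependency-free.

Mscore is the mean raw co-occurrence frequency of a herb over its pairs at
or above the high-frequency cutoff (default 5), hence a count-scale value.

### Docking effectiveness

Representative compounds occur in ≥ `min_freq` herbs (default 5; a raw
row-count mode exists). A (compound, target) pair is effective when its
affinity is strictly below −5 kcal/mol. The herb effectiveness score is
Ec(j) = (1/N_eff) · (n_jRc / n_j) with N_eff the sum of per-herb effective
counts — so a compound shared by several herbs counts once per herb.

### Structural clustering

Fingerprints are RDKit hashed path fingerprints (1024 bits); parsing
canonicalises SMILES so alternative spellings of one molecule give
identical bits. K-means (k = 3, k-means++ with 10 restarts, fixed seed)
runs on the raw bit vectors — squared Euclidean distance on binary vectors
is monotone in 1 − Tanimoto at fixed popcount — and a PAM-style k-medoid
mode on the exact Tanimoto distance matrix is available. Validity metrics
(Dunn index, silhouette) are computed on Tanimoto distances by default
(Euclidean optional). Singleton clusters get silhouette 0; an
all-singleton clustering yields the Dunn sentinel +inf, excluded from
means. Herbs with fewer than k compounds are skipped; herbs with mean
silhouette ≥ 0.45 are retained for synergy modelling.

## The synergy classifier

Herb nodes carry 12 features: d_ab, s_ab, max module diameter, Ec, overlap
rate, Hscore, Mscore, mean silhouette, drug–drug association (Pscore),
drug–disease association (−z, larger = closer), docking capability
(fraction of the herb's compounds that are effective) and compound efficacy
(mean |affinity| of effective pairs). Features are median-imputed and
z-scored; constant columns become zeros with a warning. All features are
computed before any train/test split.

The model is a two-layer graph convolution H^(l+1) = ReLU(Â H^(l) G^(l))
with Â = D^{-1/2}(A+I)D^{-1/2}; the literal activation-free propagation is
retained as a "linear" mode for oracle tests. Â is built from positive
*training* edges only — test edges never enter message passing. The edge
decoder is score(i,j) = h_iᵀ diag(w) h_j, probability σ(score), predicted
label 1 iff probability > 0.5. Training: full-batch Adam, lr 1e-4, binary
cross-entropy, dropout 0.5 on the hidden activations (training mode only),
global gradient-norm clipping at 1.0, ≤ 100 epochs, early stopping on a
15 % stratified validation slice with patience 10. Negatives are sampled
uniformly without replacement from the complement of the positive pair set
(1:1 by default). Evaluation reports accuracy/precision/recall/F1 at the
0.5 threshold, rank-based AUC, and RMSE/MAE between predicted probabilities
and the binary labels (the minimal regression reading of a probabilistic
binary task); a stratified 70:30 split and threefold CV are both supported.

**Initialisation policy.** With lr 1e-4 and at most 100 full-batch epochs,
Adam's total per-parameter displacement is ≈ lr × epochs = 0.01. A
Glorot-scale random init (~0.3) would therefore fix the learned metric at
the random draw. Layer weights are instead initialised at small scale
(N(0, 0.01²); "glorot" and "identity:α" schemes selectable) and the decoder
at w = 1 — the plain inner product — so the optimiser, not the
initialisation, determines the metric. The implementation is plain numpy
with a hand-derived backward pass (verified against finite differences);
at these problem sizes (tens of nodes, F = 12, hidden 32) dense full-batch
linear algebra is ample and keeps the forward pass exactly auditable.

## SVD ranking and formula assembly

Truncated SVD (deterministic sign convention) reduces the node-feature
matrix; herb vectors U_kΣ_k are compared by cosine-normalised inner
products. For the association matrix the features are min–max normalised
to [0, 1] first, so the vectors live in the positive orthant and cosines
fall in [0, 1]; the > 0.5 association threshold then separates above- from
below-median partner similarity, consistent with published association
values sitting just above 0.5. (The z-scored matrix would centre cosines
at 0 and make a 0.5 cutoff unreachable.) GCN degree counts partners with
edge probability > 0.5; average drug association is the mean association
over exactly those partners (0 and flagged when there are none). The
formula keeps herbs with degree > 10 and association > 0.5, ranked by
(degree desc, association desc, herb id asc — documented tie-break), and
the top ⌈25 %⌉ are core components, the remainder auxiliary.

Ablation variants: S drops the clustering feature (mean silhouette, 11
columns); E drops the clinical-experience features (Mscore and the
Pscore-derived association, 10 columns) and, because predicted connectivity
drops, its degree cutoff adapts to the 75th percentile of observed degrees.
Tabular baselines consume symmetric edge features [x_i ⊙ x_j, |x_i − x_j|]
under the identical splits.

## The synthetic study conditions

The generator emulates the full input bundle with a planted ground truth.
Defaults (the study conditions): 60 herbs, 4–10 compounds each from a
shared 120-compound pool, 300 targets in a preferential-attachment PPI
(m = 3) with an 8-gene disease module densified to 0.8, 2–6 targets per
compound, docking affinities N(−4, 1.5) with 95 % of rows shifted by −2
kcal/mol, and co-prescriptions as the top 20 % of pairs by the true synergy
score

    s(i,j) = 0.3·(u_i·u_j) + 1.25·(a_i + a_j) + 1.25·(c_i + c_j) + ε,
    ε ~ N(0, 0.25²),

with frequencies 1–30 proportional to the score. Latent factors u come
from 4 archetype directions plus jitter (co-prescription data is
community-structured); a is a disease-affinity trait that biases a herb
toward compounds whose targets fall in the disease module; c is a chemical
coherence trait: a herb's tight-compound count saturates at 1.8·c of its
compound slots, tight compounds cycle through three structural SMILES
families (within-family Tanimoto ≈ 0.7–0.9, between ≈ 0.05–0.25), and
incoherent herbs draw structurally diverse singletons. The weights were
set so that the planted signal is recoverable by the classifier under the
reported training configuration (mean held-out AUC ≥ 0.85 over seeds) while
a label-shuffled control stays at chance, and so that both the clustering
feature and the clinical-usage features carry real, removable signal — the
property the ablation ordering tests exercise.

What the generator does **not** emulate: real chemistry (SMILES are
structural placeholders), realistic PPI biology, dosage, direction of
effect, or prescription context. Passing tests therefore demonstrate that
the pipeline recovers signal that is present in the stated form — not that
the scores are clinically valid on real data.

## Numerical choices and degenerate inputs

- Tanimoto of two all-zero fingerprints is defined as 1.
- The decoder computes w·(h_i ⊙ h_j) with the commutative product first, so
  score(i,j) = score(j,i) exactly in floating point.
- Score-table CSV round-trips at full repr precision (≤ 1e-9); missing
  values are empty cells.
- Cluster labels are canonicalised by first appearance and fitting is done
  in sorted-compound order, so partitions are invariant to input order.
- σ = 0 in the permutation null raises (suggesting a larger n_perm/graph);
  herbs absent from the co-prescription table score Pscore/Mscore 0 with a
  warning rather than erroring, so the cascade can proceed.
- Pipeline problem sizes (n_perm = 200 for per-herb z features, 300-node
  PPIs, 60 herbs) were chosen so a complete run takes a few seconds on one
  CPU; the reference calibration of the null itself uses n_perm = 1000.

## Known limitations

- The exact printed formulas for the overlap-rate denominator, Hscore,
  Pscore and "average drug association" are not recoverable from the source
  tables; the reconstructions above are documented and isolated so
  alternates can be swapped in.
- With lr 1e-4 and ≤ 100 epochs the GCN's accuracy at the 0.5 threshold
  lags its AUC (probabilities are weakly calibrated near 0.5); ranking
  quality, which drives degree/association and the benchmark comparisons,
  is unaffected.
- The E-variant threshold adaptation (75th percentile) is one reasonable
  choice among several; the source only states that thresholds were
  adjusted.
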