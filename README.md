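# optisyn

Multilayer network-pharmacology screening and herb-pair synergy prediction.

Traditional-medicine formulas combine many herbs, each a mixture of
compounds hitting many protein targets. Choosing a small set of herbs whose
targets sit close to a disease's hub-gene module *and* that act
synergistically in pairs is a combinatorial screening problem. `optisyn`
implements that screen end-to-end on a typed multilayer network
(disease genes – herbs – compounds – targets):

1. **Target-level triage** — overlap rate |T_h ∩ D|/|T_h| and a two-step
   random-walk score Hscore(h) = (1/|C_h|) Σ_{c∈C_h} |T_c ∩ D|/|T_c|.
2. **Network proximity** — the closest distance d_AB on the PPI, the
   separation s_AB = d_AB − (d_AA + d_BB)/2, and a z-score of d_AB against a
   degree-preserving permutation null (z < 0 ⇒ non-random closeness to the
   disease module). PageRank prioritisation with a retention cutoff.
3. **Empirical co-usage** — pairwise Pscore (frequency-normalised
   co-prescription weight scaled by ε, the herb's maximum absolute factor
   loading) and Mscore (mean co-occurrence frequency over regularly used
   pairs).
4. **Docking effectiveness** — representative compounds (occurrence ≥ 5),
   effective pairs (affinity < −5 kcal/mol) and
   Ec(j) = (1/N_eff) · n_jRc/n_j.
5. **Structural clustering** — hashed path fingerprints, Tanimoto
   similarity, per-herb K-means (k = 3) with Dunn-index and silhouette
   validity; herbs are retained when their mean silhouette is ≥ 0.45.
6. **GCN synergy classifier** — a two-layer graph convolution
   H^(l+1) = ReLU(Â H^(l) G^(l)), Â = D^{-1/2}(A+I)D^{-1/2}, over a
   12-feature node matrix, with a diagonal inner-product edge decoder
   score(i,j) = h_iᵀ diag(w) h_j, sigmoid probability and a 0.5 decision
   rule; trained with Adam (lr 1e-4), binary cross-entropy, dropout 0.5,
   gradient clipping at norm 1.0 and early stopping.
7. **SVD ranking** — truncated SVD of the feature matrix, cosine herb
   associations, per-herb GCN degree (predicted partners) and average drug
   association; the final formula keeps herbs with degree > 10 and
   association > 0.5 and splits the ranking into core (top 25 %) and
   auxiliary components.

A first-class synthetic-data generator (`optisyn.synthetic`) emulates every
input — scale-free PPI with a planted disease module, herbs as compound
sets, docking tables, SMILES, co-prescription pairs from latent herb
factors — with a known ground-truth synergy rule, so the whole pipeline is
testable without any external database.

## Worked example

```python
from optisyn import SyntheticSpec, PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=1, synthetic=SyntheticSpec(seed=1))
res = run_pipeline(cfg)
print(len(res.ranking), res.core)
print(round(res.metrics["holdout"]["auc"], 3))
```

prints

```
28 ['H014', 'H058', 'H041', 'H048', 'H001', 'H010', 'H034']
0.894
```

Of 60 simulated herbs, 45 pass the association/usage filters
(overlap > 0, Hscore > 0.001, Mscore > 5), 28 pass the silhouette ≥ 0.45
clustering filter, and all 28 clear the final GCN-degree/association
thresholds; the top quarter (7 herbs) are the core components. The held-out
edge classification AUC of the trained synergy model is 0.894 on this seed.

The same run from a shell:

```bash
optisyn simulate --seed 1 --out inputs/          # write the input bundle
optisyn run --config config.yaml --out results/  # full pipeline
optisyn benchmark --seed 1 --out bench.csv       # compare with DT/RF/GBDT/SVM/KNN/XGBoost/LightGBM
```

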