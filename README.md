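# hemadr

Evaluation of dimension-reduction methods on routine haematology data.

A complete blood count (CBC) from a modern haemocytometer carries ~70
continuous cell characteristics per sample, and a hospital archive holds
millions of samples. Dimension reduction (DR) makes such data visualisable
and tractable — but only if the low-dimensional representation still
resembles the original data. `hemadr` is a tested pipeline for asking
exactly that question: it reduces CBC-like data with PCA, Gaussian Random
Projection (GRP), UMAP, TriMap and PaCMAP under one contract, scores the
reductions with rank-based structure-preservation metrics, and checks
whether biological signal (clusters, diurnal rhythm, sex/age
predictability, a divergent leukemia-like population) survives the
reduction. It is aimed at clinical-laboratory data scientists deciding
whether a DR stage belongs in an analysis or diagnostic pipeline.

Because real haemocytometer archives cannot be shared, the package includes
a first-class synthetic cohort generator that reproduces the statistical
structure the evaluation relies on: ~70 correlated parameters with
per-lineage latent factors, log-normal white-cell counts, granulocyte
diurnality, a haemoglobin sex effect at ages 20-50, age trends, repeated
samples per patient, a CLL-like subpopulation with very high lymphocyte
counts, and missing-at-random reticulocyte-mode parameters.

## The metrics at the core

With `N(i)`/`N'(i)` the k-nearest neighbours of point *i* in the original
and reduced space, and ρ(i,j)/r(i,j) the corresponding distance ranks:

* **Neighbourhood-kept-ratio** (local): mean of |N(i) ∩ N'(i)| / k.
* **Trustworthiness** (local), from the co-ranking matrix Q with
  Q[a,b] = #{(i,j) : ρ(i,j)=a, r(i,j)=b}:
  `T(k) = 1 − 2/(nk(2n−3k−1)) · Σ_{r(i,j)≤k, ρ(i,j)>k} (ρ(i,j) − k)`.
* **Random triplet score** (global): fraction of triplets (i, j, k) whose
  order of d(i,j) vs d(i,k) agrees between spaces (5 triplets per point).
* **Distance correlation** (global): Spearman rank correlation of pairwise
  distances between the two spaces.

Distances are Manhattan by default: the Johnson-Lindenstrauss bound
`k ≥ 4 ln n / (ε²/2 − ε³/3)` makes low-dimensional *Euclidean* distance
preservation impossible at millions of samples — which is also why GRP at
low dimension serves as the evaluation's negative control. Metrics are
computed in 10 disjoint seeded folds and methods are compared with Welch's
t-test on the fold values.

## Worked example

```python
import numpy as np
from hemadr import *
from hemadr.preprocess import preprocess_pipeline

panel = build_default_panel()
cohort = sample_cohort(panel, CohortConfig(n_samples=5_000, seed=7))
scaled, scaler, _ = preprocess_pipeline(cohort, panel, regressor="ridge", seed=7)
X = scaled.values.to_numpy()

for emb in (pca_fit_transform(X, 6), grp_fit_transform(X, 6, seed=7)):
    rep = kfold_quality_assessment(X, emb, k_neighbours=25, folds=5, seed=7)
    m = rep.means
    print(f"{emb.config.method}: NKR={m['neighbourhood_kept_ratio']:.3f} "
          f"trust={m['trustworthiness']:.3f} triplet={m['random_triplet_score']:.3f} "
          f"dist-corr={m['distance_correlation']:.3f}")

fit = cosinor_fit(cohort.draw_hour, cohort.values["neutrophil_fraction"].to_numpy())
print(f"neutrophil fraction cosinor: amplitude={fit.amplitude:.2f}, "
      f"acrophase={fit.acrophase_h:.1f} h, p={fit.p_amplitude:.2e}")
```

prints

```
pca: NKR=0.179 trust=0.814 triplet=0.722 dist-corr=0.628
grp: NKR=0.069 trust=0.641 triplet=0.595 dist-corr=0.292
neutrophil fraction cosinor: amplitude=4.53, acrophase=16.1 h, p=2.06e-81
```

Read: 6-component PCA keeps ~18% of each point's 25-neighbourhood and
ranks distances at Spearman 0.63, while the GRP negative control is much
worse on every metric, as it must be at a dimension far below its JL bound.
The cosinor fit recovers the injected neutrophil-fraction rhythm (true
amplitude 4.5 at acrophase 16:00) with an overwhelmingly significant
zero-amplitude test.

The same analyses are scriptable from the shell: `hemadr synth`,
`preprocess`, `reduce`, `quality`, `clusters`, `diurnal`, `predict`,
`cll`, and `hemadr study --out DIR` for the full run (CSV tables plus a
manifest with config hash, seeds and versions).

## Layout

```
src/hemadr/
  synth_cohort.py             # synthetic CBC cohort generator
  preprocess.py               # log -> clip -> impute -> scale
  reducers.py                 # PCA, GRP + JL bound, manifold adapters
  dr_quality.py               # co-ranking, 4 metrics, k-fold comparison
  cluster_preservation.py     # k-means, HDBSCAN adapter, NMI/ARI
  biological_preservation.py  # cosinor, sex/age tasks, CLL divergence
  pipeline.py, cli.py         # orchestration and shell interface
docs/methods.md               # models, defaults, design decisions
```
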