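# Methods

`hemadr` evaluates how well dimension-reduction (DR) methods preserve the
structure and the biological content of routine complete-blood-count (CBC)
data. Real haemocytometer archives of this kind cannot be redistributed, so
the package pairs the evaluation machinery with a synthetic cohort generator
that reproduces the statistical features the evaluation depends on. This
note documents the models, the defaults and the judgement calls.

## Synthetic cohort generator

### Generative model

Each of the 70 panel parameters is generated on a latent scale as

    y = mu + sigma * (w . z + eps),     z_f, eps ~ N(0, 1)

where `w` are per-parameter loadings on 4 latent factors (one per lineage:
red-cell/reticulocyte, white-cell counts, white-cell morphology, platelet),
and `eps` is independent noise. Each factor splits into a patient-level and
a sample-level half (50/50 in variance), so repeated samples from the same
patient are correlated — the minimal emulation of repeated measures in
routine care. Parameters marked log-normal (all white-cell counts) are
generated on the log scale and exponentiated, which keeps them strictly
positive and right-skewed, as real leukocyte counts are. Deterministic
terms are added on the latent scale before exponentiation:

* diurnal: `A * sigma * cos(2*pi*(t - phi)/24)` with `t` the draw hour;
  the neutrophil and eosinophil fractions carry the largest amplitudes
  (0.5 and 0.45 of their SD, peaking at 16:00 and 01:00), matching the
  well-known granulocyte diurnality;
* sex: an additive shift for males aged 20-50 on the haemoglobin-like
  parameter (+1.0 native unit, roughly the known male-female haemoglobin
  gap) and smaller shifts on haematocrit, erythrocyte and platelet counts;
* age: linear slopes per decade on a few parameters, giving the young-old
  contrast the age classifier exploits.

### Cohort-level defaults

| quantity | default | rationale |
|---|---|---|
| male fraction | 0.528 | composition of the tertiary-care population emulated |
| age anchors | Q1 27, median 51, Q3 66 (min 0, max 95) | piecewise-linear inverse CDF: the quantiles hold by construction |
| samples/patient | ~8.6 | ratio of samples to unique patients in that population |
| draw times | 85% uniform 06:00-18:00, 15% night | day-care vs night-care split of routine draws |
| years | uniform 2005-2020 | archive span |
| CLL fraction | 0.001 of patients, lymphocyte x30 | ~1e-3 prevalence of samples; "very high lymphocyte counts" with leukocytes incremented consistently |
| reticulocyte-mode missingness | 70% of pre-2013 samples | reticulocyte mode became the default protocol in 2013; missingness depends only on the observed year (MAR by construction) |

All randomness flows from one seed through named substreams (metadata,
draw times, factors, noise, CLL, missingness), so a cohort is bit-reproducible
and injections are independent of the base draws.

### What the generator does not emulate

Marginals are Gaussian or log-normal; real CBC parameters have heavier
tails, hard detection limits and machine-specific quantisation. Fractions
are modelled marginally and do not sum to 100%. There is no drift across
analyser software versions, no within-day case-mix change beyond the cosine
term, and disease enters only as the single CLL-like contrast. Passing
tests therefore show that the *evaluation machinery* is correct and that
the pipeline detects structure it is told exists — not that any particular
DR method would score identically on real haemocytometer data.

## Preprocessing

Order: log -> clip -> impute -> scale. Natural log on the white-cell count
columns (the base only rescales z-scored columns). Clipping defaults to the
0.1%/99.9% empirical quantiles when no explicit bounds are supplied; bounds
are configurable per parameter. Imputation is single-dataset (m = 1)
chained-equation regression via scikit-learn's IterativeImputer,
median-initialised, with a pluggable per-column regressor: gradient-boosted
trees by default, ridge as the fast linear option. Observed cells are never
altered. Scaling is columnwise z-scoring with NaNs ignored during fitting;
a zero-variance column is an error, not a silent divide-by-zero.

## Reducers

PCA is an exact SVD projection with a fixed sign convention (each
component's largest-|loading| entry is made positive) so results are
bit-stable across runs. GRP multiplies by a seeded iid Gaussian matrix
scaled by 1/sqrt(k), making projected squared Euclidean distances unbiased;
`jl_min_dimensions` implements the Johnson-Lindenstrauss bound
ceil(4 ln n / (eps^2/2 - eps^3/3)). For ~3 million samples the bound
exceeds 10 for every eps in (0,1), which is exactly why GRP serves as the
negative control at low target dimension. UMAP, TriMap and PaCMAP are
adapters behind one contract: hyperparameters are forwarded verbatim,
initialisation stays at each backend's default (PCA), and a missing backend
raises a dependency error that pipelines record and skip, so the native
PCA/GRP path always runs. Defaults: 6 components, 50 neighbours, 50
inliers / 15 outliers, Manhattan metric.

## Structure-preservation metrics

Ranks are computed from the full within-fold distance matrix with a stable
argsort: rank 1 = nearest non-self, ties broken toward the smaller index.
This one exact path doubles as the oracle path; fold sizes (~2,000 points)
keep it cheap. The co-ranking matrix is the joint histogram of the two rank
matrices.

* Neighbourhood-kept-ratio: mean over points of |N(i) ∩ N'(i)|/k.
* Trustworthiness: `1 - 2/(n k (2n-3k-1)) * sum (r - k)` over pairs
  entering the low-space k-neighbourhood from high-space rank r > k,
  evaluated from the co-ranking matrix. This is the standard Venna-Kaski
  rank-penalty form — the single most consequential formula interpretation
  in the package, cross-checked against scikit-learn's implementation.
* Random triplet score: 5 sampled (j, k) pairs per anchor i by default;
  exhaustive enumeration is available as the test oracle. A distance tie
  counts as disagreement unless tied in both spaces (conservative choice;
  ties are measure-zero for continuous data).
* Spearman distance correlation: all pairs for folds up to 2,000 points,
  a seeded uniform pair sample (default 10^6) beyond; tie-corrected ranks
  via scipy.

Fold protocol: rows are partitioned into 10 disjoint seeded folds and all
four metrics are computed within-fold, so neighbour graphs never cross fold
boundaries; fold partitions depend only on the seed, making comparisons
between methods paired. Method comparisons use Welch's t-test on fold
values (the unequal-variance form is the safer default when only "t-test"
is specified); two identical fold vectors return (t, p) = (0, 1) rather
than the 0/0 NaN.

k = 50 neighbours is the metric default, matching the reducers' neighbour
count; trustworthiness requires k < n_fold/2.

## Cluster preservation

Ground truth is the clustering of the scaled original data, computed once
per seed and reused across every method; each embedding is clustered with
the same model and compared by NMI and ARI, both implemented from their
contingency-table definitions (NMI uses the arithmetic-mean normaliser;
conventions: 1 for two single-cluster partitions, 0 when one entropy is
zero and the partitions differ). HDBSCAN noise points form one
pseudo-cluster by default (droppable by flag). k-means is a native Lloyd
implementation with k-means++ seeding and a documented empty-cluster rule
(re-seed at the farthest point); k defaults to the HDBSCAN ground-truth
cluster count, since no principled k is otherwise given.

## Biological preservation

Cosinor: `y = M + beta_c cos(wt) + beta_s sin(wt)` by least squares at a
fixed 24 h period; amplitude and acrophase follow from the coefficients,
and the zero-amplitude p-value is the 2-df F-test of the harmonic terms
against the intercept-only model. The fit is exact linear algebra —
machine-precision on noiseless harmonics — and the null p-value is
uniform, which the suite checks by KS test.

Classification: sex within ages 20-50 and young (< 20) vs old (> 60), with
the 20-60 band dropped. The harness draws a seeded disjoint
train/validation split (capped at 170,000/30,000, scaled down at the same
17:3 ratio for smaller cohorts), runs stratified 10-fold CV on the training
pool and scores the dedicated validation set with a model trained on the
whole pool. Accuracy and MCC come from the package's own confusion-matrix
formulas (MCC = 0 when a denominator factor vanishes). The classifier is
an adapter — gradient-boosted trees by default — because the harness, not
the learner, is the contribution. Performance changes between
representations are Welch-tested on the fold vectors.

Divergent population: per-dimension unpaired Welch t-tests of flagged
(CLL-like) vs unflagged samples, significant at p < 0.001, with group
medians/IQRs reported. On preprocessed (log-scaled) data the test is well
calibrated, which the suite verifies on ~14,000 null tests.

## Numerical choices and degenerate inputs

* Distance ties: stable argsort ⇒ smaller index wins, deterministically.
* Degenerate distance sets (all pairwise distances equal within 1e-12
  relative) make the Spearman correlation undefined — an error, not a 0.
* PCA refuses n_components above the numerical rank (tolerance
  max(n,p)·eps·s_max).
* GRP at k = 1 is computable; the recorded config floors at the pipeline's
  2-component minimum while coordinates keep the true dimension.
* All-identical input points are one cluster for the density clusterer
  (the backend would call them noise).
* Cosinor needs ≥ 4 distinct time points and more observations than the
  3 parameters.

## Problem sizes used in the shipped checks

The package's own acceptance checks run the negative-control and
monotonicity comparisons on a 20,000-sample default cohort (10 folds of
2,000, k = 50), divergence detection on 100,000 samples, cosinor recovery
on 50,000, and the metric-oracle equivalences on 50 random datasets of up
to ~90 points — sizes at which the exhaustive oracles are exact and cheap.
Ridge is used as the imputation regressor inside these fixtures; the
compared quantities do not depend on the imputation model.

## Known limitations

* TriMap and PaCMAP are exercised only through the adapter contract when
  their packages are installed; the shipped test environment covers UMAP.
* The neighbour-grid sweep treats TriMap's inlier count as its neighbour
  axis, as the outlier count showed little effect in the design this
  package follows.
* NMI/ARI on HDBSCAN output depend on the noise convention; both
  conventions are implemented but only the pseudo-cluster default is used
  in reports.
* The generator's CLL contrast is a pure location shift on two counts;
  real CLL also distorts morphology parameters.
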