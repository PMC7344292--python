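# Methods

`confact` discovers cancer subtypes from multi-omics data (mRNA expression,
DNA methylation, miRNA expression measured on the same patients) and
predicts per-patient survival risk scores. Everything below is computed by
the package itself; the test suite and `scripts/acceptance.py` re-derive
every number quoted here.

## Model overview

The pipeline rests on three ideas:

1. **Noise filtering.** Most features play no role in differentiating
   patients. A one-hidden-layer autoencoder with non-negative encoder
   weights is trained to reconstruct the omics matrix; the variance of each
   feature's encoder weights across hidden units scores how much distinct
   information the feature contributes, and only the top `n_keep` features
   are retained.
2. **Consensus factor representations.** Rather than factor-analyzing the
   (huge) feature–feature correlation matrix, we fit the n × n
   patient–patient Pearson correlation matrix with minimum-residual (MINRES)
   factor analysis: find Λ (n × k) minimizing Σ_{i≠j} (C_ij − (ΛΛᵀ)_ij)².
   The rows of Λ are a k-dimensional patient embedding that preserves
   patient–patient relationships; the cost depends on the number of
   patients (hundreds), not features (tens of thousands). Because any
   single k may misrepresent noisy data, the analysis is repeated over a
   grid of factor counts, yielding an ensemble of representations per data
   type.
3. **Ensemble integration.** For subtyping, each representation is
   clustered (k-means, best of many starts, cluster count chosen by an
   explained-variance plateau) into a binary connectivity matrix, and a
   weighted meta-clustering merges all connectivity matrices from all data
   types into final subtypes. For risk, each representation carries a Cox
   proportional-hazards model with an elastic-net penalty; a patient's
   score is the geometric mean of the relative hazards exp(Σ β_i x_i)
   across all representations of all data types.

### Assumptions

- Subtype signal is *shared* across data types: each omics expresses the
  same latent patient grouping through its own features.
- Patient similarity is adequately captured by Pearson correlation of
  standardized feature profiles (linear, scale-free).
- Hazards are proportional: a patient's risk is a time-constant multiplier
  of a baseline hazard.

## Stage-by-stage choices

### Autoencoder feature filter

Architecture: linear encoder p → `hidden_dim` (default 50) and linear
decoder back to p; mean-squared reconstruction loss; minibatch SGD with
momentum 0.9, learning rate 0.1, batch 32, `epochs` 50; encoder weights
clamped ≥ 0 after every step. Inputs are min-max scaled per feature to
[0, 1] rather than z-scored: under unit-variance standardization every
feature receives the same gradient budget and the MSE-optimal non-negative
encoding actually assigns the *highest* weight variability to
non-redundant noise features, inverting the intended ranking. Min-max
scaling preserves each feature's dynamic structure, so features with real
between-patient contrasts earn larger, more concentrated weights. The
encoder starts at exactly zero, which guarantees that a constant feature
(zero input after scaling, hence zero gradient) ends with exactly zero
weight variability. SGD is used instead of an adaptively normalized
optimizer for the same reason: per-parameter step normalization would
equalize signal and noise gradient magnitudes and erase the ranking the
score relies on.

Default `n_keep` = min(2000, p): factor analysis on the patient
correlation matrix is cheap, so filtering exists to remove noise at
genomic scale, not to make small matrices smaller. When `n_keep ≥ p`
selection is the identity and training is skipped. A `variance` method
(top features by raw variance) is available as a fast deterministic
alternative.

The filter's contract, and what the tests enforce, is asymmetric: constant
features rank in the bottom decile, a small planted signal block outranks
noise on average, and — the property the pipeline actually needs —
filtering never costs more than 0.05 ARI of downstream subtype recovery.
It is *not* guaranteed to enrich a large, highly redundant signal block,
where reconstruction spreads weights thinly across duplicates.

### Patient-correlation MINRES factor analysis

Features are standardized (mean 0, sd 1 across patients) before computing
patient correlations so no platform or feature dominates. The MINRES
objective excludes the diagonal (communalities are free). Initialization
takes the k leading eigenpairs, Λ₀ = V √λ₊, with the sign convention that
each eigenvector's largest-magnitude element is positive; L-BFGS-B
(analytic gradient −4RΛ) refines it with `max_iter` 1000 and `tol` 1e-6.
The fit is fully deterministic and the returned residual never exceeds the
initialization's — which also yields the nested-model property that the
off-diagonal RMSE is non-increasing in k from the shared eigenbasis.

The embedding handed downstream is the loading matrix Λ itself, not
regression-estimated factor scores: the patients are the *variables* of
this factor model, so their loadings are their coordinates in the latent
space. No rotation is applied; k-means and Cox models consume Λ as
returned, and the downstream analyses are insensitive to the orthogonal
indeterminacy in any case. Factor-count grid: {2, …, 10} capped at n − 1.
Nine representations per data type balance ensemble diversity against
runtime.

### Cluster-count selection and consensus

For each k in [`k_min`, `k_max`] = [2, 10], r_k = BSS/TSS of the best of
`n_starts` = 20 seeded k-means runs. The chosen count is the smallest k
with r_{k+1} − r_k < δ (default δ = 0.05) — the point where adding a
cluster stops buying explained variance, which is simultaneously the
"increase of within sum of squares" criterion since r_{k+1} − r_k =
(WSS_k − WSS_{k+1})/TSS. If no plateau occurs, `k_max` is returned. Note
the plateau rule is dimension-aware only through the data: an unstructured
*low*-dimensional blob genuinely has r-gains above 0.05 for small k (WSS
of k-means on d-dimensional noise scales roughly as k^(−2/d)), so the
"one blob → k_min" behavior holds for the higher-dimensional
representations typical here, not for d ≤ 10 noise.

The meta-clustering concretizes the weighted ensemble merge as: consensus
matrix = mean of connectivity matrices; patient weight v_i = Σ_{j≠i} s_ij;
cluster–cluster similarity = patient-weighted Jaccard
sim(A,B) = Σ_{i∈A∩B} v_i / Σ_{i∈A∪B} v_i over the pooled clusters of all
partitions; average-linkage hierarchical clustering on 1 − sim cut into
`k_final` meta-clusters (default: the mode of the per-representation
optimal counts, ties to the smaller k); patients join the meta-cluster
holding the plurality of their source clusters, ties resolved by summed
similarity. These choices make every step testable and reduce exactly to
plain consensus clustering when all partitions agree. Average linkage was
chosen for its robustness to chaining on similarity matrices. Every
representation counts once, so a data type contributes in proportion to
its number of representations (equal under the default grid).

### Cox elastic-net ensemble

Per representation, a penalized Cox model is fitted on the training rows
(glmnet-style coordinate descent, `l1_ratio` = `alpha_mix` = 0.5 — the
penalty mix is a free choice and 0.5 weights Lasso and Ridge equally). The
λ path (20 values, `alpha_min_ratio` 0.01) is scored by summed held-out
Breslow partial log-likelihood over 5 event-stratified folds; ties go to
the stronger penalty; the model is refitted on all training rows at the
winning λ. Stratifying folds by event status keeps every fold fittable on
small cohorts. Representations whose CV fails (e.g. a degenerate fold)
are dropped from the ensemble with a logged warning — prediction degrades
gracefully instead of failing the run. An all-constant design returns the
null model (β = 0) directly.

Train and test cohorts are *merged* before filtering and factor analysis,
then only training rows enter the Cox fit (the embedding, being
unsupervised, sees test covariates but never test outcomes). The
config switch `risk.fit_fa_on_train_only` provides a strictly leakage-free
variant that embeds only training patients and places test patients by
least-squares projection of their test-to-train correlations onto Λ; it is
off by default to match the merged design the subtyping path assumes.

The final score is the flat geometric mean over all representations of all
data types — flat rather than nested (per-omics first) because every
representation is an equally valid view of the same patients.

### Evaluation metrics

- Cox subtype p-value: likelihood-ratio test of a Cox model with subtype
  as a categorical covariate (Efron ties). The LRT is more stable than
  Wald for small groups with large effects.
- Concordance index: Harrell's C by exhaustive pair enumeration. A pair is
  comparable when the strictly earlier observed time belongs to an event;
  tied observed times are never comparable (with both events there is no
  "earlier" patient; with one event the censored patient's ordering is
  unknown); tied risks score 0.5.
- ARI (permutation-model, contingency table) and NMI (arithmetic-mean
  normalization; defined as 0 when both partitions are constant, since
  two constant partitions share no *information*).

## Synthetic cohorts

The generator emulates the statistical structure the model assumes, and
its defaults are the study conditions used throughout the tests: 150
patients, 3 balanced subtypes, 3 data types with 500 features each of
which 100 are informative, subtype mean shifts of `effect_size` = 5 noise
standard deviations on a log-like continuous scale, exponential survival
with subtype hazard ratios (4, 2, 1), baseline scale 365 days, and 20%
independent exponential censoring (rate solved so the expected censored
fraction is exact). Subtype counts follow largest-remainder rounding of
the requested proportions, so every subtype is present whenever n ≥ G.
Each data type draws an independent informative feature set; with
`signal_split` each data type elevates only one subtype, so no single
omics can separate all subtypes and integration is required.

Deliberately not modeled: negative-binomial counts, batch effects,
missing-data patterns, within-subtype risk heterogeneity. Passing tests
therefore demonstrate that the machinery recovers the structure it
assumes, at realistic sizes — not robustness to the full messiness of
platform data.

## What the numbers can and cannot reach

Under proportional hazards, P(T_i < T_j) = h_i/(h_i + h_j) regardless of
the baseline hazard. With three equal subtypes at hazards (4, 2, 1), even
the *oracle* risk score (the true hazard) has expected concordance ≈
0.64–0.65 (between-subtype pair concordances 2/3, 4/5, 2/3; within-subtype
pairs 1/2), and censoring barely moves this. No model can beat the oracle
on average, so test C-indices near 0.65 on these cohorts indicate the
ensemble has extracted essentially *all* available risk information — the
risk-recovery test accordingly asserts closeness to the oracle;
subtype-level C-indices in the low 0.6s are also what real cancer cohorts
typically allow. Larger C-indices would require continuous
within-subtype risk variation expressed in the features, which the
generator deliberately does not plant.

## Numerical and engineering notes

- All randomness derives from one master seed via CRC32-tagged
  `SeedSequence` children (`stage name` + index), so any stage can be
  reproduced in isolation; every pipeline is byte-deterministic given a
  config.
- k-means label canonicalization (cluster ids by first patient
  occurrence) makes partitions comparable across runs.
- Degenerate inputs are rejected with named-offender messages: duplicate
  IDs, zero-variance patient profiles, non-positive times, subtypes
  without events, k out of range.
- Matrices are written as TSV with 6-significant-digit floats; reading
  drops rows/columns > 20% missing, imputes the rest by feature median,
  and drops constant features (all logged).

## Known limitations

- The weight-variability filter dilutes very large redundant signal
  blocks (see above); the pipeline-level guarantee is non-destruction,
  not enrichment.
- The merged-embedding risk design shares unlabeled test covariates with
  the embedding step; use `risk.fit_fa_on_train_only` when strict
  separation matters.
- The plateau rule can over-segment unstructured low-dimensional
  embeddings (d ≲ 10), which is visible in null cohorts; the consensus
  step absorbs much of this but k_final under the null is not meaningful.
- Cox CV uses Breslow tie handling (as does the coordinate-descent
  solver); with heavily tied (discretized) survival times Efron would be
  preferable, and only the evaluation LRT uses it here.
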