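# confact

Multi-omics cancer subtyping and survival risk prediction via **con**sensus
**fact**or analysis.

Molecular cancer subtypes — patient subgroups with genuinely different
survival — are hard to find from any single assay: mRNA expression, DNA
methylation and miRNA each see part of the picture, and all of them are
noisy and very high-dimensional. `confact` integrates several
patients × features matrices measured on the same cohort into (i) consensus
subtypes and (ii) per-patient risk scores, for bioinformaticians analyzing
cohort studies of the TCGA kind.

## Method

For each data type *X* (patients × features):

1. **Filter** — a non-negative autoencoder is trained to reconstruct *X*;
   features whose encoder weights vary little across hidden units carry no
   patient-discriminating information and are dropped.
2. **Embed** — minimum-residual (MINRES) factor analysis is applied to the
   n × n patient-correlation matrix *C*: find Λ ∈ ℝ^{n×k} minimizing
   Σ_{i≠j} (C_ij − (ΛΛᵀ)_ij)², initialized from the k leading
   eigencomponents. The rows of Λ are a k-dimensional patient embedding;
   repeating over k ∈ {2,…,10} gives an ensemble of representations per
   data type.
3. **Cluster** — each representation is partitioned by k-means (best of 20
   starts; cluster count from a BSS/TSS plateau rule) into a binary
   connectivity matrix; a weighted meta-clustering (consensus matrix →
   patient weights → weighted-Jaccard cluster similarity →
   average-linkage cut) merges all representations of all data types into
   the final subtypes.
4. **Risk** — per representation, a Cox proportional-hazards model with an
   elastic-net penalty (λ by 5-fold cross-validated partial likelihood) is
   fitted on training patients; a test patient's score is the geometric
   mean of exp(Σᵢ βᵢxᵢ) — the relative hazard h(t)/h₀(t) — across all
   representations.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

No external data is needed — the package generates cohorts with planted
subtypes and survival structure:

```python
import confact

cohort = confact.generate_cohort(n_patients=150, seed=7)  # 3 subtypes, 3 omics
result = confact.subtype(cohort.omics, confact.RunConfig(seed=7))

print(confact.adjusted_rand_index(result.labels, cohort.true_labels))
print(confact.cox_subtype_pvalue(result.labels, cohort.survival))
```

prints

```
1.0
1.43e-08
```

an adjusted Rand index of 1.0 (the three planted subtypes were recovered
exactly) and a Cox likelihood-ratio p-value of ~10⁻⁸ (the discovered
subtypes have sharply different survival, as planted: hazard ratios 4:2:1).
The scripts in `examples/` walk through each capability — simulation,
subtyping, risk prediction, and the value of integrating several data
types — and print what each number means.

The same pipelines are available from the shell:

```bash
confact simulate --n-patients 150 --out data/
confact subtype --omics data/mRNA.tsv --omics data/methylation.tsv \
    --omics data/miRNA.tsv --seed 7 --out results/
confact evaluate --subtypes results/subtypes.tsv --survival data/survival.tsv \
    --truth data/truth.tsv --out report.json
```

Omics files are TSV with patient IDs in the first column; survival files
have `patient_id`, `time` (days), `event` (1 = death observed, 0 =
censored) columns. Patient alignment is always by ID, never by row order.

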