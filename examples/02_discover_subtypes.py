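"""Consensus subtyping of a multi-omics cohort.

Runs the full unsupervised pipeline — factor representations of each data
type, per-representation k-means, weighted meta-clustering — and compares
the discovered subtypes with the planted truth and with survival.
"""

import numpy as np

import confact

cohort = confact.generate_cohort(
    n_patients=100,
    omics_specs=[confact.OmicsSpec(300, 60, "mRNA"), confact.OmicsSpec(300, 60, "methylation")],
    seed=42,
)

result = confact.subtype(cohort.omics, confact.RunConfig(seed=42))

ari = confact.adjusted_rand_index(result.labels, cohort.true_labels)
nmi = confact.normalized_mutual_information(result.labels, cohort.true_labels)
p = confact.cox_subtype_pvalue(result.labels, cohort.survival)

print(f"discovered {result.k_final} subtypes from {len(result.partitions)} partitions")
print(f"agreement with planted labels: ARI = {ari:.3f}, NMI = {nmi:.3f}")
print(f"survival separation: Cox LRT p = {p:.2e}")
# ARI/NMI of 1.0 mean the planted subtypes were recovered exactly; a tiny
# Cox p-value means the discovered groups have clearly different survival.
off = result.consensus[~np.eye(len(result.labels), dtype=bool)]
print(f"consensus matrix: {np.mean((off == 0) | (off == 1)):.0%} of off-diagonal "
      "entries are unanimous across representations")
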