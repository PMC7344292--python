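"""Generate a synthetic multi-omics cohort with planted subtypes.

Builds 100 patients in 3 subtypes measured on two data types, with
exponential survival whose hazard is 4:2:1 across subtypes, and prints the
planted structure.
"""

import numpy as np

import confact

cohort = confact.generate_cohort(
    n_patients=100,
    omics_specs=[confact.OmicsSpec(300, 60, "mRNA"), confact.OmicsSpec(300, 60, "methylation")],
    hazard_ratios=(4.0, 2.0, 1.0),
    censor_rate=0.2,
    seed=42,
)

counts = np.bincount(cohort.true_labels)[1:]
print(f"patients: {len(cohort.true_labels)}, subtype sizes: {counts.tolist()}")
for m in cohort.omics:
    print(f"  {m.data_type}: {m.n_patients} × {m.p_features} matrix")
surv = cohort.survival
print(f"survival: {surv.n_events} events, {len(surv) - surv.n_events} censored")
for g in (1, 2, 3):
    med = np.median(surv.time[cohort.true_labels == g])
    print(f"  subtype {g}: median observed time {med:.0f} days")
# Higher-hazard subtypes should show shorter median follow-up times:
# subtype 1 (hazard ×4) dies roughly 4× faster than subtype 3 (×1).
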