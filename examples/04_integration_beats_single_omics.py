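"""Why integrate? Each data type alone sees only part of the risk signal.

With `signal_split`, each omics separates only one subtype from the rest,
so no single data type can order all three hazard groups — but the
integrated ensemble can.
"""

import confact
from confact.simulate import split_cohort

cohort = confact.generate_cohort(n_patients=150, seed=7, signal_split=True)
train, surv_train, test, surv_test, *_ = split_cohort(cohort, seed=7)
cfg = confact.RunConfig(seed=7)

integrated = confact.predict_risk(train, surv_train, test, cfg)
c_int = confact.concordance_index(integrated.risk, surv_test)
print(f"integration (3 omics): C-index = {c_int:.3f}")

for j, m in enumerate(train):
    single = confact.predict_risk([train[j]], surv_train, [test[j]], cfg)
    c = confact.concordance_index(single.risk, surv_test)
    print(f"  {m.data_type} alone:      C-index = {c:.3f}")
# Each single data type distinguishes one subtype at best, capping its
# C-index; combining them recovers the full 4:2:1 hazard ordering.
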