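"""Covariate selection on a synthetic cohort.

Screens the full candidate grammar (renal function, body size, age, sex,
stage, albumin, procedure) by forward inclusion at p<0.01 and backward
deletion at p<0.001 on a 200-subject cohort generated from the final
model. The search should rediscover exactly the generating structure:
creatinine clearance driving CL and body weight driving Vd. Runs a
dozen mixed-effects fits (~2-3 min).
"""

import cmzpk
from cmzpk import CohortConfig
from cmzpk.estimation import covariate_search
from cmzpk.structural import default_candidates

dataset = cmzpk.simulate_dataset(CohortConfig(n_subjects=200, seed=11))
search = covariate_search(dataset, default_candidates())

cols = ["stage", "model", "delta_obj", "p", "significant"]
print(search.audit[cols].to_string(index=False))
print(f"\nselected covariates: {sorted(search.selected_pairs)}")
print(f"final model: {search.final_model.label()}")
print("(the generating structure is CL ~ Ccr, Vd ~ Bw; the audit table's",
      "delta_obj column is the OBJ drop each candidate buys, judged",
      "against chi-square(1): 6.635 forward, 10.828 backward)")
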