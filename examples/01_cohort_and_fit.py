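"""Simulate a study-like cohort and refit the population model.

Builds a 23-subject virtual colorectal-surgery cohort (event-driven
surgical sampling, 1 g cefmetazole q3h) from the published population
parameters, then re-estimates those parameters with the mixed-effects
engine. With only 23 subjects the fixed effects come back within a few
percent while variance components are noticeably less precise — the
expected behaviour at the original study size.
"""

import numpy as np

import cmzpk

dataset = cmzpk.simulate_dataset(cmzpk.study_cohort_config(seed=1))
print(f"cohort: {len(dataset)} subjects, {dataset.n_observations} observations")

result = cmzpk.fit(dataset, cmzpk.final_model())
est = result.estimates
truth = cmzpk.CEFMETAZOLE_COLORECTAL
print(f"converged: {result.converged}   OBJ = {result.objective:.2f}")
print(f"{'parameter':<14}{'estimate':>10}{'truth':>10}")
for name, value, ref in [
    ("theta_CL", est.theta[0], truth.theta[0]),
    ("theta_Vd", est.theta[1], truth.theta[1]),
    ("omega_CL %", est.omega_cv_percent[0], truth.omega_cv_percent[0]),
    ("omega_Vd %", est.omega_cv_percent[1], truth.omega_cv_percent[1]),
    ("sigma %", est.sigma_cv_percent, truth.sigma_cv_percent),
]:
    print(f"{name:<14}{value:>10.4f}{ref:>10.4f}")

# typical-value sanity checks of the fitted model
subject = cmzpk.Subject("typical", 69, "male", 63.7, 0.84,
                        creatinine_clearance=100.0)
pk = cmzpk.structural_parameters(subject, est.theta)
print(f"\nfitted typical CL at Ccr 100 mL/min: {pk.clearance:.2f} L/h "
      "(published model: 7.04)")
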