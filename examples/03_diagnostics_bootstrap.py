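"""Goodness-of-fit diagnostics and bootstrap validation.

Fits the final model to a 23-subject study-like cohort, prints the
regression quality of population (PRED) and individual empirical-Bayes
(IPRED) predictions against the observations, checks the weighted
residuals, and runs a small subject-resampling bootstrap (use
n_replicates=200 for a report at the published scale; 40 keeps this
example under a couple of minutes).
"""

import numpy as np

import cmzpk

dataset = cmzpk.simulate_dataset(cmzpk.study_cohort_config(seed=3))
result = cmzpk.fit(dataset, cmzpk.final_model())

diag = cmzpk.compute_diagnostics(dataset, result)
r2_pred = np.corrcoef(diag["dv"], diag["pred"])[0, 1] ** 2
r2_ipred = np.corrcoef(diag["dv"], diag["ipred"])[0, 1] ** 2
print(f"r^2 observed~PRED:  {r2_pred:.4f}")
print(f"r^2 observed~IPRED: {r2_ipred:.4f}  (IPRED tracks individuals, so >= PRED)")
inside = (diag["wres"].abs() <= 3).mean()
print(f"WRES: mean {diag['wres'].mean():+.3f}, {100*inside:.1f}% within +/-3")

report = cmzpk.bootstrap(dataset, cmzpk.final_model(), n_replicates=40,
                         seed=12, original=result)
print(f"\nbootstrap convergence rate: {report.convergence_rate:.0%}")
print(report.table.round(4).to_string(index=False))
print("(percent_difference = (bootstrap mean - original)/original x 100;",
      "small values indicate a stable model)")
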