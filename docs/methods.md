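# Methods

`cmzpk` reanalyzes the population pharmacokinetics of cefmetazole (CMZ)
given for intraoperative antimicrobial prophylaxis during colorectal
surgery, and the Monte-Carlo dosing simulation built on it. This note
documents the models, the numerical machinery, the synthetic-data
conditions every experiment runs under, and the design choices made where
the published analysis left the design open.

## Structural model

Cefmetazole disposition is described by a linear one-compartment model
with intravenous input: the drug distributes instantly into an apparent
volume `Vd` (L) and is eliminated first-order with rate constant
`k = CL/Vd` (1/h). Closed forms are superposed over the dosing history:

* bolus of `D` mg at time `td`: `C(t) = (D/Vd) exp(-k (t - td))`;
* zero-order infusion at rate `R = D/T` over duration `T`:
  `C(t) = (R/CL)(1 - exp(-k tau)) exp(-k s)` with `tau = min(t - td, T)`,
  `s = max(t - td - T, 0)`.

Units are fixed package-wide: mg, L, h, mg/L (= ug/mL). Creatinine
clearance stays in mL/min; the unit conversion is absorbed into the
clearance coefficient, exactly as the published estimates are printed
(`CL` in L/h = 0.0704 x `Ccr` in mL/min). Doses in the source study were
5-10 min infusions; the package supports infusions, but the default in
both the cohort generator and the attainment simulation is bolus input,
which back-calculates cleanly against the published attainment grid. The
difference at the simulated horizons (>= 2 h, i.e. > 10 half-lives of the
infusion duration) is negligible.

The final covariate model is `CL = theta1 * Ccr` (renal elimination;
~85% of CMZ is excreted unchanged in urine) and `Vd = theta2 * Bw`.
Canonical parameter values, used as the simulation truth everywhere
(`cmzpk.CEFMETAZOLE_COLORECTAL`):

| parameter | value | meaning |
|---|---|---|
| theta1 | 0.0704 (L/h)/(mL/min) | clearance per unit creatinine clearance |
| theta2 | 0.163 L/kg | volume per kg body weight |
| omega_CL | 21.0 % | inter-individual CV of CL |
| omega_Vd | 8.4 % | inter-individual CV of Vd |
| sigma | 13.5 % | proportional residual error |

Inter-individual variability is lognormal, `P_j = P exp(eta_j)` with
`eta_j ~ N(0, omega^2)`; residual error is proportional,
`C_obs = C_pred (1 + eps)` with `eps ~ N(0, sigma^2)`. The percent
figures are interpreted as `100 * omega` (the SD of the exponential /
proportional term), the conventional pharmacometric reporting; at these
magnitudes the alternative reading `100 * sqrt(exp(omega^2) - 1)` differs
only in the third digit.

Creatinine clearance is derived by Cockcroft-Gault,
`(140 - age) * Bw / (72 * Scr)`, with the conventional 0.85 factor for
women (the source analysis names the equation but not the factor).

## Estimation

The marginal likelihood integrates each subject's conditional likelihood
over `eta = (eta_CL, eta_Vd)`. The integral is approximated by the
Laplace method at the per-subject conditional mode (the empirical-Bayes
estimate), i.e. a first-order-conditional-class approximation: with
`g(eta) = -log[p(y | eta) N(eta; 0, Omega)]`,

    -2 log L_j ~= 2 g(eta_hat) + log det H_g(eta_hat) - q log(2 pi),

`q` the number of active random-effect dimensions. The objective OBJ is
the sum over subjects, a full -2 log marginal likelihood including
normalizing constants, so nested-model differences are chi-square
distributed. Random effects with zero variance drop out of the integral;
with both variances zero the objective is the exact -2 log density at
`eta = 0`.

Numerical design:

* **Inner problem.** The mode search runs as a damped Newton iteration
  vectorized across all subjects at once. For bolus dosing the gradient
  and Hessian of `g` are exact analytic expressions (the derivatives of
  the superposed exponentials close over two weighted sums); mixed
  bolus/infusion histories fall back to a finite-difference stencil.
  Convergence: gradient below 1e-8, at most 60 iterations.
  `g` is bounded below with an interior minimum, but `eta = 0` can sit at
  a *saddle* (zero gradient, indefinite Hessian) for unfavourable outer
  parameters. A point with a non-positive-definite Hessian is not a mode
  and would corrupt the log-determinant, so such subjects incur a large
  positive penalty and are re-descended after a kick along the
  negative-curvature eigenvector; this matters in practice (an early
  version without it let the outer optimizer chase spurious
  log-determinant holes and fabricate a covariate effect on null data).
* **Outer problem.** `(theta, log omega, log sigma)` by L-BFGS-B with
  forward-difference gradients; positivity of variance components by the
  log transform, boxed to SD in [1e-3, 3]; theta components are
  log-transformed except linear covariate slopes, which may be negative.
  The inner search restarts from `eta = 0` on every evaluation so the
  objective is a deterministic, history-free function of the parameters
  (a warm-start cache makes re-evaluations path-dependent and derails the
  line search). Because residual inner noise (~1e-7) or extreme curvature
  anisotropy (near-noise-free data pushing sigma to its bound) can stall
  L-BFGS-B, the result is checked with a central-difference gradient and,
  when needed, finished with a bounded derivative-free Powell search,
  which handles curved ravines well.
* **Starting values.** Naive two-stage: per-subject nonlinear least
  squares on (log CL, log Vd), then block-wise regression of the
  individual estimates on the covariates; omega and sigma start at 0.3.
* **Standard errors.** Inverse of the finite-difference Hessian of OBJ/2
  at the optimum, delta-method transformed to the natural scale.
* **Accuracy.** The implementation is an exact Laplace approximation: on
  tiny instances it agrees with an independent construction of the same
  quantity (simplex mode search + finite-difference Hessian) to ~1e-7.
  Against *exact* integration (dense Gauss-Hermite quadrature) the
  approximation error at the study's error magnitudes is a few
  hundredths of an OBJ unit per subject with 1-5 observations, shrinking
  roughly like 1/n_obs. This is the intrinsic cost of Laplace-class
  estimators, shared by production tools that default to FOCE; it is far
  below the chi-square thresholds (6.635, 10.828) the covariate decisions
  are made against.

### Covariate selection

Candidates mirror the published hypothesis grid: linear terms
(`P = theta_p + theta_c x`) for Ccr, 1/Scr, body weight and a stage
score `1 + (4 - stage)`; power indicators (`P = theta_p theta_c^x`) for
sex (male = 1) and procedure (open = 1); dichotomies with separate theta
per stratum for age (cut at 65 y) and albumin (cut at 3.8 g/dL). Each
candidate is screened univariately against the covariate-free base model
(forward inclusion at p < 0.01 on the chi-square of the OBJ drop); all
significant covariates form the full model; backward deletion then
removes any covariate whose deletion does not worsen OBJ at p < 0.001.
The audit table (model, OBJ, delta OBJ, p) is emitted alongside the final
refit. Non-converged candidate fits are logged and treated as not
significant. The published final model drops the intercept of the
selected linear terms (pure proportionality); the package mirrors this by
keeping selection (which covariate enters which parameter) separate from
the canonical proportional final model used for simulation.

## Synthetic cohorts

The raw 23-patient dataset is not public, so all estimation experiments
run on virtual cohorts emulating the study conditions. Continuous
covariates are truncated normals clipped to the observed ranges — age
69 +/- 10 (41-84) y, body weight 63.7 +/- 9.9 (47.5-89.0) kg, creatinine
clearance 73.9 +/- 21.7 (47.2-126.3) mL/min, albumin 3.8 +/- 0.4
(3.3-4.6) g/dL — and categorical covariates use the observed proportions
(18/23 male, stage 10/6/6/1, 13/23 laparoscopic). Covariate draws are
independent (no correlation structure was published); serum creatinine is
back-solved from the drawn clearance so the Cockcroft-Gault identity
holds exactly. Dosing is 1 g at time zero with 1 g redoses every 3 h.

Two observation designs:

* `grid` (default for estimation experiments): all subjects sampled at
  0.25, 1.5, 2.95 (pre-redose trough), 3.25 and 5.0 h;
* `surgical` (the study-emulating fixture): event-driven times — incision
  (~0.5 h after the pre-operative dose), anastomosis completion (~60%
  through the operation), immediately before each intra-operative redose,
  and shortly after abdominal closure — with operation duration drawn
  from 238 +/- 73 (140-430) min. This yields ~4 samples/subject, i.e.
  around 90 observations for 23 subjects, bracketing the study's 86
  serum samples; the exact published count is not reproducible because
  the event clock times were not reported.

Concentrations below the assay detection limit of 0.5 ug/mL are dropped
by default (`blq_rule="drop"`); the study did not state its rule, so
`"keep"` is available. At the default design the troughs sit far above
the limit and the rule is inert.

What the generator does **not** emulate: intra-operative physiology
(blood loss, fluid shifts, hemodilution), covariate correlations, and
assay-specific error structure beyond the proportional term. Passing
recovery tests therefore demonstrate estimator correctness under the
stated generating model, not robustness to those real-data features.

## Diagnostics and bootstrap

PRED is the population prediction at `eta = 0`; IPRED the prediction at
the empirical-Bayes mode. WRES follows the classic first-order
definition: per subject, residuals `y - PRED` decorrelated by
`F Omega F' + diag(sigma^2 PRED^2)`, `F` the sensitivity of the
prediction to `eta` at zero. Under the generating model WRES is
approximately standard normal; the first-order linearization under
lognormal truth leaves it slightly heavy-tailed (SD ~1.03), so the
+/- 3 band captures ~99% rather than the Gaussian 99.7%.

The bootstrap resamples *subjects* (the exchangeable unit in longitudinal
data) with replacement to the original count, refits each replicate
starting from the original estimates, and reports per-parameter replicate
mean +/- SE, percent difference from the original fit, and the
convergence rate; non-converged replicates are excluded from summaries
and counted against the rate. Refitting an identity resample returns the
original optimum to optimizer precision (~1e-5 in OBJ, ~1e-4 relative in
parameters) — "exact" up to the iterative tolerance.

## Attainment simulation and redosing

For surgical prophylaxis the pharmacodynamic target is serum
concentration above the MIC of the dominant colorectal pathogen,
*Bacteroides fragilis*, throughout the procedure. Per cell of the grid —
body-weight bins 40-50/50-60/60-70 kg by creatinine-clearance bins
10-50/50-90/90-130 mL/min — the simulator draws covariates uniformly
within the bin and `eta` from the inter-individual distribution, computes
the concentration profile after a single 1 g bolus, and reports the
fraction above the MIC at 2, 3, 4, 5 and 6 h (1000 draws by default).

* **MIC threshold.** The source cites a 2004 Japanese anaerobe
  surveillance for the MIC80 without printing the value. The default of
  16 mg/L is back-derived: it is the unique power-of-two threshold for
  which the analytic attainment oracle reproduces the published grid
  (neighbouring values miss by tens of points); it is configurable.
* **Within-bin distribution.** Uniform. Midpoint-only sampling fails the
  wide low-Ccr bin badly (~83% predicted where ~66% is published at 6 h);
  uniform sampling lands within a few points everywhere the published
  narrative quotes.
* **Residual error** is excluded from the draws by default: attainment
  concerns the true concentration, not an assay replicate. A switch is
  provided since the original spreadsheet procedure is not described.
* **Common random numbers** are shared across cells, making attainment
  exactly monotone along the time axis and in renal function, and
  removing between-cell Monte-Carlo jitter from comparisons.

`recommend_redosing` turns the grid into an interval per renal-function
bin: the largest simulated horizon at which attainment stays at or above
a floor (default 0.5) in *every* body-weight bin; if no horizon
qualifies, the shortest simulated interval is returned and flagged. On
the published grid this yields 2 h for Ccr 90-130 and 3 h for 50-90. For
the 10-50 bin the published grid itself stays above 50% through 6 h
(66-79%), so the 0.5 floor yields 6 h; the published recommendation of
4-5 h for that bin reflects clinical caution (a single study patient had
Ccr < 50), equivalent to demanding roughly 80% attainment there. The
floor is a parameter precisely because this judgment is not a single
threshold.

## Problem sizes and tolerances

Recovery experiments use 200-subject cohorts (10 replicate seeds) for the
fixed effects and 500-subject cohorts for variance components, sizes at
which the estimator's sampling error is comfortably inside the published
reporting precision while a full replicate set fits in minutes on one
core. The attainment grid uses the published 1000 draws (binomial SE
<= 1.6 points). Oracle comparisons: closed form vs ODE integration at
relative 1e-6; Monte-Carlo attainment vs quadrature tail within two
binomial SEs; Laplace vs exact quadrature at its intrinsic approximation
scale (see above). Chi-square critical values for 1 df: 6.635 (p < 0.01)
forward, 10.828 (p < 0.001) backward.

## Known limitations

* Laplace-class approximation, not exact likelihood; bias in variance
  components at small n (the 23-subject fixture recovers omega_CL only
  within ~30%).
* Diagonal Omega only (no CL-Vd random-effect correlation), matching the
  published model.
* Single-dose attainment profiles; no accumulation across redoses and no
  cumulative %fT>MIC target.
* The attainment grid's non-narrative cells (2 h column of the middle
  renal bin) sit up to ~7 points from the published print under uniform
  within-bin sampling; the original within-bin distribution and MIC80
  value are unpublished, so this residual discrepancy is not resolvable
  from the source.
* No protein-binding correction, multi-compartment structure, or
  nonlinear elimination.
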