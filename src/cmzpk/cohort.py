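"""Synthetic study cohorts.

The raw study data (23 colorectal-surgery patients, 86 serum samples) are
not public, so every experiment in this package runs on virtual cohorts
that emulate the study conditions: demographic covariates drawn from the
published summary distributions (truncated normals clipped to the observed
ranges, categorical draws at the observed proportions), 1 g IV cefmetazole
at time 0 with 1 g redoses every 3 h, and concentrations generated from
the population model with lognormal inter-individual variability and
proportional residual error.

Two observation schemes are provided:

* ``grid`` — a fixed sampling-time grid shared by all subjects (default
  ``[0.25, 1.5, 2.95, 3.25, 5.0]`` h: early distribution, mid-interval,
  pre-redose trough, post-redose and late sample);
* ``surgical`` — event-driven times emulating the study's protocol
  (incision, anastomosis completion, immediately before each redose,
  abdominal closure), with a per-subject operation duration drawn from
  the published 238 +/- 73 min distribution.

What the generator does *not* emulate: intra-operative physiology (blood
loss, fluid shifts), covariate correlations (none were published; draws
are independent, with serum creatinine back-solved from the drawn
creatinine clearance so the Cockcroft-Gault identity holds exactly).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .dataset import PKDataset, SubjectRecord
from .errors import ConfigError
from .parameters import CEFMETAZOLE_COLORECTAL, PopPKParameters
from .pk_core import DoseEvent, IndividualPK, Subject, concentration_profile

__all__ = ["CovariateRange", "CohortConfig", "generate_cohort",
           "simulate_observations", "simulate_dataset", "study_cohort_config"]


@dataclass(frozen=True)
class CovariateRange:
    """Mean, SD and truncation bounds for one continuous covariate."""

    mean: float
    sd: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.mean <= self.high):
            raise ConfigError(
                f"infeasible truncation: need low <= mean <= high, got {self}"
            )
        if self.sd < 0:
            raise ConfigError("sd must be >= 0")

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.sd == 0:
            return np.full(n, np.clip(self.mean, self.low, self.high))
        a = (self.low - self.mean) / self.sd
        b = (self.high - self.mean) / self.sd
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                                   size=n, random_state=rng)


def _default_covariates() -> dict:
    # published cohort summaries: mean +/- SD and observed range
    return {
        "age": CovariateRange(69.0, 10.0, 41.0, 84.0),
        "bw": CovariateRange(63.7, 9.9, 47.5, 89.0),
        "ccr": CovariateRange(73.9, 21.7, 47.2, 126.3),
        "alb": CovariateRange(3.8, 0.4, 3.3, 4.6),
    }


@dataclass
class CohortConfig:
    """Virtual-cohort generation settings.

    Defaults reproduce the study conditions; ``observation_scheme`` may be
    ``"grid"`` (shared sampling times) or ``"surgical"`` (event-driven).
    ``blq_rule`` controls concentrations below the assay detection limit
    (0.5 ug/mL): ``"drop"`` removes them from the dataset, ``"keep"``
    retains the raw simulated value.
    """

    n_subjects: int = 23
    seed: int | None = None
    covariate_ranges: dict = field(default_factory=_default_covariates)
    sex_male_p: float = 18 / 23
    stage_p: tuple = (10 / 23, 6 / 23, 6 / 23, 1 / 23)
    laparoscopic_p: float = 13 / 23
    dosing_regimen: list = field(default_factory=lambda: [DoseEvent(0.0, 1000.0),
                                                          DoseEvent(3.0, 1000.0)])
    observation_times: list = field(default_factory=lambda: [0.25, 1.5, 2.95, 3.25, 5.0])
    observation_scheme: str = "grid"
    operation_minutes: CovariateRange = field(
        default_factory=lambda: CovariateRange(238.0, 73.0, 140.0, 430.0))
    redose_interval: float = 3.0
    generating_parameters: PopPKParameters = field(
        default_factory=lambda: CEFMETAZOLE_COLORECTAL)
    blq_rule: str = "drop"
    detection_limit: float = 0.5

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.observation_scheme not in ("grid", "surgical"):
            raise ConfigError(f"unknown observation scheme {self.observation_scheme!r}")
        if self.observation_scheme == "grid":
            if len(self.observation_times) == 0:
                raise ConfigError("observation_times must be nonempty")
            if any(t < 0 for t in self.observation_times):
                raise ConfigError("observation times must be >= 0")
        if self.blq_rule not in ("drop", "keep"):
            raise ConfigError(f"unknown blq_rule {self.blq_rule!r}")
        for key in ("age", "bw", "ccr", "alb"):
            if key not in self.covariate_ranges:
                raise ConfigError(f"covariate_ranges missing {key!r}")


def study_cohort_config(seed: int | None = None, **overrides) -> CohortConfig:
    """The default study-emulating fixture: 23 subjects, event-driven
    sampling, q3h redosing while the operation is ongoing."""
    cfg = CohortConfig(seed=seed, observation_scheme="surgical")
    return replace(cfg, **overrides) if overrides else cfg


def _rng(config: CohortConfig, rng: np.random.Generator | None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(config.seed)


def generate_cohort(config: CohortConfig, rng: np.random.Generator | None = None) -> list[Subject]:
    """Draw ``n_subjects`` virtual patients.

    Continuous covariates come from the configured truncated normals;
    sex, stage and procedure are categorical at the study proportions.
    Creatinine clearance is drawn directly and serum creatinine is
    back-solved through Cockcroft-Gault, so the derived-Ccr invariant
    holds by construction.
    """
    rng = _rng(config, rng)
    n = config.n_subjects
    cr = config.covariate_ranges
    age = cr["age"].draw(n, rng)
    bw = cr["bw"].draw(n, rng)
    ccr = cr["ccr"].draw(n, rng)
    alb = cr["alb"].draw(n, rng)
    sex = np.where(rng.random(n) < config.sex_male_p, "male", "female")
    stage = rng.choice([1, 2, 3, 4], size=n, p=np.asarray(config.stage_p) /
                       np.sum(config.stage_p))
    proc = np.where(rng.random(n) < config.laparoscopic_p, "laparoscopic", "open")
    subjects = []
    for i in range(n):
        factor = 0.85 if sex[i] == "female" else 1.0
        scr = (140.0 - age[i]) * bw[i] * factor / (72.0 * ccr[i])
        subjects.append(Subject(
            id=i + 1, age=float(age[i]), sex=str(sex[i]), body_weight=float(bw[i]),
            serum_creatinine=float(scr), creatinine_clearance=float(ccr[i]),
            stage=int(stage[i]), procedure=str(proc[i]), albumin=float(alb[i]),
        ))
    return subjects


def _surgical_schedule(config: CohortConfig, rng: np.random.Generator):
    """Event-driven sampling times and per-subject dosing for one subject.

    Time origin is the first dose, given ~0.5 h before incision.  Samples:
    incision, anastomosis completion (~60% through the operation), just
    before each scheduled redose that falls within the operation, and
    shortly after abdominal closure.  Redoses are given every
    ``redose_interval`` hours while surgery is ongoing.
    """
    op_h = float(config.operation_minutes.draw(1, rng)[0]) / 60.0
    incision = 0.5
    closure = incision + op_h + 0.3
    anastomosis = incision + 0.6 * op_h
    tau = config.redose_interval
    dose_times = [0.0]
    t = tau
    while t < closure:
        dose_times.append(t)
        t += tau
    samples = {round(incision, 2), round(anastomosis, 2), round(closure, 2)}
    for dt in dose_times[1:]:
        samples.add(round(dt - 0.05, 2))
    doses = [DoseEvent(dt, config.dosing_regimen[0].amount,
                       config.dosing_regimen[0].infusion_duration) for dt in dose_times]
    return doses, np.array(sorted(samples))


def simulate_observations(
    subjects: list[Subject],
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> PKDataset:
    """Generate the longitudinal dataset for given subjects.

    Per subject, CL and Vd are the structural typical values times
    ``exp(eta)`` with ``eta ~ N(0, omega2)``; concentrations at the
    scheduled times are the one-compartment predictions times
    ``(1 + eps)``, ``eps ~ N(0, sigma2)``.  Values below the assay
    detection limit are handled per ``config.blq_rule``.
    """
    rng = _rng(config, rng)
    p = config.generating_parameters
    if p.theta.shape != (2,):
        raise ConfigError("generating_parameters must carry the 2-theta final model")
    n = len(subjects)
    eta = rng.normal(0.0, 1.0, size=(n, 2)) * p.omega  # omega may be 0
    records = []
    for i, s in enumerate(subjects):
        if config.observation_scheme == "surgical":
            doses, times = _surgical_schedule(config, rng)
        else:
            doses = list(config.dosing_regimen)
            times = np.asarray(config.observation_times, float)
        cl = p.theta[0] * s.creatinine_clearance * np.exp(eta[i, 0])
        vd = p.theta[1] * s.body_weight * np.exp(eta[i, 1])
        pred = concentration_profile(
            np.array([cl]), np.array([vd]),
            np.array([[d.time for d in doses]]),
            np.array([[d.amount for d in doses]]),
            np.array([[d.infusion_duration for d in doses]]),
            times[None, :],
        )[0]
        eps = rng.normal(0.0, p.sigma, size=times.size) if p.sigma > 0 else 0.0
        dv = pred * (1.0 + eps)
        if config.blq_rule == "drop":
            keep = dv >= config.detection_limit
            times, dv = times[keep], dv[keep]
        records.append(SubjectRecord(s, doses, times, dv,
                                     individual_pk=IndividualPK(cl, vd)))
    return PKDataset(records)


def simulate_dataset(config: CohortConfig, rng: np.random.Generator | None = None) -> PKDataset:
    """Convenience: ``generate_cohort`` then ``simulate_observations``
    under a single RNG stream (fully deterministic given ``config.seed``)."""
    rng = _rng(config, rng)
    subjects = generate_cohort(config, rng)
    return simulate_observations(subjects, config, rng)
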