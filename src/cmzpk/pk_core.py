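"""One-compartment intravenous pharmacokinetic model.

The drug distributes instantly into a single apparent volume ``Vd`` and is
eliminated first-order with rate constant ``k = CL/Vd``.  Closed-form
solutions for bolus and zero-order (constant-rate) infusion input are
superposed over an arbitrary dosing history; the model is linear in dose.

Units are fixed package-wide: mg, L, h, mg/L (== ug/mL).  Creatinine
clearance stays in mL/min, with the unit conversion absorbed into the
clearance coefficient, matching how the published covariate model is
printed (CL in L/h = 0.0704 * Ccr in mL/min).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidInputError, InvalidModelError

__all__ = [
    "Subject",
    "DoseEvent",
    "IndividualPK",
    "cockcroft_gault",
    "structural_parameters",
    "concentration",
    "concentration_profile",
]


@dataclass(frozen=True)
class Subject:
    """One patient's covariates.

    ``sex`` is ``"male"`` or ``"female"``; ``stage`` is the clinical
    pathological stage encoded 1-4; ``procedure`` is ``"open"`` or
    ``"laparoscopic"``.
    """

    id: object
    age: float
    sex: str
    body_weight: float
    serum_creatinine: float
    creatinine_clearance: float | None = None
    stage: int = 2
    procedure: str = "open"
    albumin: float = 4.0

    def __post_init__(self) -> None:
        if not (self.body_weight > 0 and self.serum_creatinine > 0 and self.age > 0):
            raise InvalidInputError("age, body_weight and serum_creatinine must be > 0")
        if self.sex not in ("male", "female"):
            raise InvalidInputError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.procedure not in ("open", "laparoscopic"):
            raise InvalidInputError(f"unknown procedure {self.procedure!r}")
        if int(self.stage) not in (1, 2, 3, 4):
            raise InvalidInputError("stage must be 1-4")
        if self.creatinine_clearance is None:
            object.__setattr__(
                self,
                "creatinine_clearance",
                cockcroft_gault(self.age, self.body_weight, self.serum_creatinine, self.sex),
            )


@dataclass(frozen=True)
class DoseEvent:
    """A timed intravenous dose.

    ``time`` is hours since the first dose; ``infusion_duration`` of 0
    means an instantaneous bolus, otherwise the dose is given at constant
    rate ``amount / infusion_duration``.
    """

    time: float
    amount: float
    infusion_duration: float = 0.0

    def __post_init__(self) -> None:
        if not self.amount > 0:
            raise InvalidInputError("dose amount must be > 0")
        if self.infusion_duration < 0:
            raise InvalidInputError("infusion duration must be >= 0")


@dataclass(frozen=True)
class IndividualPK:
    """A subject's realized clearance (L/h) and volume (L)."""

    clearance: float
    volume: float

    def __post_init__(self) -> None:
        if not (self.clearance > 0 and np.isfinite(self.clearance)):
            raise InvalidModelError(f"clearance must be finite and > 0, got {self.clearance}")
        if not (self.volume > 0 and np.isfinite(self.volume)):
            raise InvalidModelError(f"volume must be finite and > 0, got {self.volume}")

    @property
    def elimination_rate(self) -> float:
        """First-order elimination rate constant k = CL/Vd (1/h)."""
        return self.clearance / self.volume


def cockcroft_gault(age: float, body_weight: float, serum_creatinine: float, sex: str) -> float:
    """Creatinine clearance (mL/min) by the Cockcroft-Gault equation.

    ``(140 - age) * Bw / (72 * Scr)``, multiplied by 0.85 for females.
    The result is clipped at 0 (an age of 140 or more gives 0).
    """
    if not (body_weight > 0 and serum_creatinine > 0):
        raise InvalidInputError("body weight and serum creatinine must be > 0")
    if not age > 0:
        raise InvalidInputError("age must be > 0")
    ccr = (140.0 - age) * body_weight / (72.0 * serum_creatinine)
    if sex == "female":
        ccr *= 0.85
    elif sex != "male":
        raise InvalidInputError(f"sex must be 'male' or 'female', got {sex!r}")
    return max(ccr, 0.0)


def structural_parameters(
    subject: Subject, theta: Sequence[float] | np.ndarray
) -> IndividualPK:
    """Typical-value CL and Vd under the final covariate model.

    The final model is proportional in the renal and size covariates:
    ``CL = theta[0] * Ccr`` and ``Vd = theta[1] * Bw``.  No random effects
    are applied.  A non-positive resulting parameter (e.g. Ccr of 0)
    raises :class:`InvalidModelError`.
    """
    theta = np.asarray(theta, float)
    if theta.shape != (2,):
        raise InvalidInputError("final model expects theta = (theta_CL, theta_Vd)")
    cl = theta[0] * subject.creatinine_clearance
    vd = theta[1] * subject.body_weight
    if not cl > 0:
        raise InvalidModelError(f"typical clearance {cl} is not positive")
    if not vd > 0:
        raise InvalidModelError(f"typical volume {vd} is not positive")
    return IndividualPK(clearance=cl, volume=vd)


def concentration_profile(
    cl: np.ndarray,
    vd: np.ndarray,
    dose_time: np.ndarray,
    dose_amt: np.ndarray,
    dose_dur: np.ndarray,
    t: np.ndarray,
    dose_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized multi-subject concentration at requested times.

    Parameters are arrays: ``cl``, ``vd`` of shape (n,); dose arrays of
    shape (n, D) (ragged histories padded, with ``dose_mask`` marking real
    doses); ``t`` of shape (n, T).  Returns concentrations (n, T) in mg/L.

    Per dose the contribution is the one-compartment IV solution with
    ``dt = t - dose_time``:

    * bolus: ``(amt/Vd) * exp(-k*dt)``
    * infusion at rate R = amt/dur:
      ``(R/CL)*(1 - exp(-k*min(dt, dur))) * exp(-k*max(dt - dur, 0))``

    Times before a dose contribute 0.
    """
    cl = np.asarray(cl, float)
    vd = np.asarray(vd, float)
    k = (cl / vd)[:, None, None]
    dt = t[:, :, None] - dose_time[:, None, :]
    started = dt >= 0
    dtc = np.maximum(dt, 0.0)
    dur = np.broadcast_to(dose_dur[:, None, :], dt.shape)
    amt = dose_amt[:, None, :]
    bolus = dur <= 0

    c_bolus = (amt / vd[:, None, None]) * np.exp(-k * dtc)
    safe_dur = np.where(bolus, 1.0, dur)
    rate = amt / safe_dur
    c_inf = (
        (rate / cl[:, None, None])
        * (1.0 - np.exp(-k * np.minimum(dtc, safe_dur)))
        * np.exp(-k * np.maximum(dtc - safe_dur, 0.0))
    )
    contrib = np.where(bolus, c_bolus, c_inf)
    contrib = np.where(started, contrib, 0.0)
    if dose_mask is not None:
        contrib = np.where(dose_mask[:, None, :], contrib, 0.0)
    return contrib.sum(axis=2)


def concentration(pk: IndividualPK, doses: Iterable[DoseEvent], t) -> float | np.ndarray:
    """Serum concentration (mg/L) for one subject.

    ``t`` may be a scalar or array of hours since the first dose; times
    before the first dose return 0 by convention.
    """
    doses = list(doses)
    if not doses:
        raise InvalidInputError("at least one dose event is required")
    times = sorted(d.time for d in doses)
    if any(b < a for a, b in zip(times, times[1:])):  # pragma: no cover - sorted()
        raise InvalidInputError("dose events must be sorted by time")
    t_arr = np.atleast_1d(np.asarray(t, float))
    if np.any(t_arr < 0):
        raise InvalidInputError("time must be >= 0 (hours since first dose)")
    out = concentration_profile(
        np.array([pk.clearance]),
        np.array([pk.volume]),
        np.array([[d.time for d in doses]]),
        np.array([[d.amount for d in doses]]),
        np.array([[d.infusion_duration for d in doses]]),
        t_arr[None, :],
    )[0]
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out
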