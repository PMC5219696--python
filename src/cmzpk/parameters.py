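"""Population pharmacokinetic parameter container.

The population model separates three levels of variability:

* fixed effects ``theta`` — coefficients of the structural (typical-value)
  model, e.g. the proportionality constants of CL on creatinine clearance
  and Vd on body weight;
* inter-individual variability ``omega2`` — variances of the lognormal
  random effects eta on (CL, Vd): ``P_j = P_typ * exp(eta_j)``,
  ``eta_j ~ N(0, omega2)``;
* residual variability ``sigma2`` — variance of the proportional
  intra-individual error: ``C_obs = C_pred * (1 + eps)``,
  ``eps ~ N(0, sigma2)``.

Percent CVs reported for omega and sigma follow the usual pharmacometric
convention 100*omega (the SD of the lognormal/proportional term).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

__all__ = ["PopPKParameters", "CEFMETAZOLE_COLORECTAL"]


@dataclass(frozen=True)
class PopPKParameters:
    """Fixed effects, inter-individual variances and residual variance.

    Parameters
    ----------
    theta
        Fixed-effect vector of the structural model, in the order defined
        by the :class:`~cmzpk.structural.StructuralModel` in use (clearance
        block first, then volume).
    omega2
        Length-2 array of inter-individual variances ``(omega2_CL,
        omega2_Vd)`` of the lognormal random effects.
    sigma2
        Proportional residual-error variance.  Zero is allowed for
        noise-free simulation; estimation requires a positive value.
    """

    theta: np.ndarray
    omega2: np.ndarray
    sigma2: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", np.atleast_1d(np.asarray(self.theta, float)))
        object.__setattr__(self, "omega2", np.atleast_1d(np.asarray(self.omega2, float)))
        if self.omega2.shape != (2,):
            raise InvalidInputError("omega2 must have two entries (CL, Vd)")
        if np.any(self.omega2 < 0):
            raise InvalidInputError("inter-individual variances must be >= 0")
        if self.sigma2 < 0:
            raise InvalidInputError("residual variance must be >= 0")

    @classmethod
    def from_sd(cls, theta, omega, sigma) -> "PopPKParameters":
        """Build from standard deviations rather than variances."""
        omega = np.asarray(omega, float)
        return cls(theta=np.asarray(theta, float), omega2=omega**2, sigma2=float(sigma) ** 2)

    @property
    def omega(self) -> np.ndarray:
        """Inter-individual SDs ``(omega_CL, omega_Vd)``."""
        return np.sqrt(self.omega2)

    @property
    def sigma(self) -> float:
        """Residual proportional-error SD."""
        return float(np.sqrt(self.sigma2))

    @property
    def omega_cv_percent(self) -> np.ndarray:
        """Inter-individual variability as percent CV (100*omega)."""
        return 100.0 * self.omega

    @property
    def sigma_cv_percent(self) -> float:
        """Residual variability as percent CV (100*sigma)."""
        return 100.0 * self.sigma

    def replace(self, **kwargs) -> "PopPKParameters":
        data = {"theta": self.theta, "omega2": self.omega2, "sigma2": self.sigma2}
        data.update(kwargs)
        return PopPKParameters(**data)


#: Published population estimates for cefmetazole in adult colorectal-surgery
#: patients: CL (L/h) = 0.0704 * Ccr (mL/min), Vd (L) = 0.163 * Bw (kg),
#: with 21.0% / 8.4% inter-individual CV on CL / Vd and 13.5% proportional
#: residual error.  Used as the canonical simulation truth throughout.
CEFMETAZOLE_COLORECTAL: PopPKParameters = PopPKParameters.from_sd(
    theta=[0.0704, 0.163], omega=[0.210, 0.084], sigma=0.135
)
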