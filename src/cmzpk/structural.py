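"""Covariate-to-parameter structural models.

A structural model maps per-subject covariates to typical values of
clearance and volume through one functional form per covariate:

* ``none``           P = theta_p                       (1 parameter)
* ``proportional``   P = theta_c * x                   (1 parameter)
* ``linear``         P = theta_p + theta_c * x         (2 parameters)
* ``power``          P = theta_p * theta_c ** x        (2 parameters)
* ``dichotomous``    P = theta_hi if x >= threshold else theta_lo

Covariates are referenced by registry key: ``ccr`` (creatinine clearance,
mL/min), ``bw`` (body weight, kg), ``age`` (years), ``scr`` / ``inv_scr``
(serum creatinine and its reciprocal), ``alb`` (albumin, g/dL),
``sex_male`` (1 = male), ``procedure_open`` (1 = open surgery) and
``stage_score`` (1 + (4 - stage), increasing for earlier stages).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ConfigError, InvalidModelError

__all__ = [
    "CovariateModelSpec",
    "StructuralModel",
    "final_model",
    "base_model",
    "default_candidates",
    "COVARIATE_KEYS",
]

COVARIATE_KEYS = (
    "ccr", "bw", "age", "scr", "inv_scr", "alb",
    "sex_male", "procedure_open", "stage", "stage_score",
)
_FORMS = ("none", "proportional", "linear", "power", "dichotomous")


@dataclass(frozen=True)
class CovariateModelSpec:
    """One covariate's entry into one structural parameter."""

    target: str                      # "CL" or "Vd"
    form: str = "none"
    covariate: str | None = None
    threshold: float | None = None   # required for dichotomous

    def __post_init__(self) -> None:
        if self.target not in ("CL", "Vd"):
            raise ConfigError(f"target must be 'CL' or 'Vd', got {self.target!r}")
        if self.form not in _FORMS:
            raise ConfigError(f"unknown form {self.form!r}")
        if self.form == "none":
            if self.covariate is not None:
                raise ConfigError("form 'none' takes no covariate")
        else:
            if self.covariate not in COVARIATE_KEYS:
                raise ConfigError(f"unknown covariate {self.covariate!r}")
        if self.form == "dichotomous" and self.threshold is None:
            raise ConfigError("dichotomous form requires a threshold")

    @property
    def n_theta(self) -> int:
        return 1 if self.form in ("none", "proportional") else 2

    def label(self) -> str:
        if self.form == "none":
            return "base"
        if self.form == "dichotomous":
            return f"{self.covariate}>={self.threshold}"
        return f"{self.form}({self.covariate})"


def _eval_specs(specs, theta, cov):
    """Typical value for one target from its spec list."""
    if len(specs) == 1:
        s, th = specs[0], theta
        if s.form == "none":
            n = len(next(iter(cov.values())))
            return np.full(n, th[0])
        x = cov[s.covariate]
        if s.form == "proportional":
            return th[0] * x
        if s.form == "linear":
            return th[0] + th[1] * x
        if s.form == "power":
            return th[0] * th[1] ** x
        return np.where(x >= s.threshold, th[0], th[1])
    # multi-covariate composition: additive linear terms on a common intercept
    if any(s.form != "linear" for s in specs):
        raise ConfigError("multiple covariates on one parameter must all be linear")
    out = np.full(len(cov[specs[0].covariate]), theta[0])
    for i, s in enumerate(specs):
        out = out + theta[1 + i] * cov[s.covariate]
    return out


class StructuralModel:
    """A pair of spec lists (clearance block first, then volume).

    The fixed-effect vector ``theta`` is laid out CL block then Vd block;
    each block is one parameter for ``none``/``proportional`` forms, two
    for the others, or ``1 + n_covariates`` for a composed multi-linear
    block.
    """

    def __init__(self, cl_specs: Sequence[CovariateModelSpec],
                 vd_specs: Sequence[CovariateModelSpec]):
        cl_specs = list(cl_specs) or [CovariateModelSpec("CL")]
        vd_specs = list(vd_specs) or [CovariateModelSpec("Vd")]
        if any(s.target != "CL" for s in cl_specs) or any(s.target != "Vd" for s in vd_specs):
            raise ConfigError("spec target does not match its block")
        for specs in (cl_specs, vd_specs):
            if len(specs) > 1 and any(s.form != "linear" for s in specs):
                raise ConfigError("multiple covariates per parameter require linear form")
        self.cl_specs = cl_specs
        self.vd_specs = vd_specs

    # -- layout ----------------------------------------------------------
    def _block_size(self, specs) -> int:
        if len(specs) == 1:
            return specs[0].n_theta
        return 1 + len(specs)

    @property
    def n_theta(self) -> int:
        return self._block_size(self.cl_specs) + self._block_size(self.vd_specs)

    def _block_names(self, specs, tag):
        if len(specs) == 1:
            s = specs[0]
            if s.form == "none":
                return [f"theta_{tag}"]
            if s.form == "proportional":
                return [f"theta_{tag}_{s.covariate}"]
            if s.form == "dichotomous":
                return [f"theta_{tag}_hi", f"theta_{tag}_lo"]
            return [f"theta_{tag}", f"theta_{tag}_{s.covariate}"]
        return [f"theta_{tag}"] + [f"theta_{tag}_{s.covariate}" for s in specs]

    @property
    def theta_names(self) -> list[str]:
        return self._block_names(self.cl_specs, "CL") + self._block_names(self.vd_specs, "Vd")

    def _block_transforms(self, specs):
        if len(specs) == 1:
            s = specs[0]
            if s.form == "linear":
                return ["log", "id"]
            return ["log"] * s.n_theta
        return ["log"] + ["id"] * len(specs)

    @property
    def theta_transforms(self) -> list[str]:
        """Per-theta optimizer transform: 'log' for positive-only, 'id' free."""
        return self._block_transforms(self.cl_specs) + self._block_transforms(self.vd_specs)

    # -- evaluation ------------------------------------------------------
    def typical_values(self, theta, covariates: dict) -> tuple[np.ndarray, np.ndarray]:
        """Typical (CL, Vd) arrays for all subjects; raises if non-positive."""
        theta = np.asarray(theta, float)
        if theta.shape != (self.n_theta,):
            raise ConfigError(
                f"theta has length {theta.size}, model expects {self.n_theta}"
            )
        ncl = self._block_size(self.cl_specs)
        tvcl = _eval_specs(self.cl_specs, theta[:ncl], covariates)
        tvvd = _eval_specs(self.vd_specs, theta[ncl:], covariates)
        if np.any(tvcl <= 0) or np.any(tvvd <= 0):
            raise InvalidModelError("structural model produced a non-positive CL or Vd")
        return tvcl, tvvd

    # -- editing ---------------------------------------------------------
    def specs(self) -> list[CovariateModelSpec]:
        return [s for s in self.cl_specs + self.vd_specs if s.form != "none"]

    def with_spec(self, spec: CovariateModelSpec) -> "StructuralModel":
        """Add one covariate spec, replacing a 'none' block if present."""
        if spec.target == "CL":
            block = [s for s in self.cl_specs if s.form != "none"] + [spec]
            return StructuralModel(block, self.vd_specs)
        block = [s for s in self.vd_specs if s.form != "none"] + [spec]
        return StructuralModel(self.cl_specs, block)

    def without_spec(self, spec: CovariateModelSpec) -> "StructuralModel":
        if spec.target == "CL":
            return StructuralModel([s for s in self.cl_specs if s != spec], self.vd_specs)
        return StructuralModel(self.cl_specs, [s for s in self.vd_specs if s != spec])

    def nests(self, other: "StructuralModel") -> bool:
        """True if ``other``'s covariate specs are a subset of this model's."""
        return set(other.specs()) <= set(self.specs())

    def label(self) -> str:
        cl = "+".join(s.label() for s in self.cl_specs)
        vd = "+".join(s.label() for s in self.vd_specs)
        return f"CL[{cl}] Vd[{vd}]"

    def __eq__(self, other) -> bool:
        return (isinstance(other, StructuralModel)
                and self.cl_specs == other.cl_specs and self.vd_specs == other.vd_specs)

    def __repr__(self) -> str:  # pragma: no cover
        return f"StructuralModel({self.label()})"


def final_model() -> StructuralModel:
    """The published final model: CL = theta1*Ccr, Vd = theta2*Bw."""
    return StructuralModel(
        [CovariateModelSpec("CL", "proportional", "ccr")],
        [CovariateModelSpec("Vd", "proportional", "bw")],
    )


def base_model() -> StructuralModel:
    """Covariate-free model: CL = theta1, Vd = theta2."""
    return StructuralModel([CovariateModelSpec("CL")], [CovariateModelSpec("Vd")])


def default_candidates() -> list[CovariateModelSpec]:
    """The screened covariate grammar: linear renal/size/stage terms,
    power indicators for sex and procedure, and age/albumin dichotomies."""
    return [
        CovariateModelSpec("CL", "linear", "ccr"),
        CovariateModelSpec("CL", "linear", "inv_scr"),
        CovariateModelSpec("CL", "power", "sex_male"),
        CovariateModelSpec("CL", "dichotomous", "age", 65.0),
        CovariateModelSpec("CL", "dichotomous", "alb", 3.8),
        CovariateModelSpec("CL", "linear", "stage_score"),
        CovariateModelSpec("CL", "power", "procedure_open"),
        CovariateModelSpec("CL", "linear", "bw"),
        CovariateModelSpec("Vd", "power", "sex_male"),
        CovariateModelSpec("Vd", "dichotomous", "age", 65.0),
        CovariateModelSpec("Vd", "linear", "bw"),
    ]
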