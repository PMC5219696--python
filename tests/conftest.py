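"""Shared fixtures and independent numerical oracles.

The oracles deliberately avoid the package's fast computational paths:
concentrations are re-derived by direct ODE integration, marginal
likelihoods by dense Gauss-Hermite quadrature, and attainment
probabilities by a lognormal-tail integral, so each test compares two
independent routes to the same quantity.
"""

from __future__ import annotations

import numpy as np
import pytest
from numpy.polynomial.hermite_e import hermegauss
from scipy import stats
from scipy.integrate import solve_ivp

import cmzpk
from cmzpk import CEFMETAZOLE_COLORECTAL, CohortConfig, final_model, fit


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def ode_concentration(pk, doses, times):
    """One-compartment concentration by direct ODE integration.

    dC/dt = rate_in/Vd - k*C, integrated segment-wise between dose
    boundaries; bolus doses add D/Vd to the state instantaneously.
    """
    times = np.atleast_1d(np.asarray(times, float))
    k = pk.clearance / pk.volume
    breaks = {0.0}
    for d in doses:
        breaks.add(d.time)
        if d.infusion_duration > 0:
            breaks.add(d.time + d.infusion_duration)
    breaks |= set(times.tolist())
    grid = sorted(breaks)
    c = 0.0
    t_cur = grid[0]
    out = {}
    for d in doses:
        if d.infusion_duration == 0 and d.time == t_cur:
            c += d.amount / pk.volume
    if t_cur in times:
        out[t_cur] = c
    for t_next in grid[1:]:
        mid = 0.5 * (t_cur + t_next)
        rate = sum(d.amount / d.infusion_duration for d in doses
                   if d.infusion_duration > 0
                   and d.time <= mid < d.time + d.infusion_duration)
        sol = solve_ivp(lambda t, y: [rate / pk.volume - k * y[0]],
                        (t_cur, t_next), [c], rtol=1e-12, atol=1e-14)
        c = float(sol.y[0, -1])
        for d in doses:
            if d.infusion_duration == 0 and abs(d.time - t_next) < 1e-12:
                c += d.amount / pk.volume
        if np.any(np.isclose(times, t_next)):
            out[t_next] = c
        t_cur = t_next
    return np.array([out[t] for t in times])


def quadrature_objective(record, params, nodes=150):
    """-2 log marginal likelihood of one subject by dense 2-d
    Gauss-Hermite quadrature over the random effects."""
    x, w = hermegauss(nodes)
    tvcl = params.theta[0] * record.subject.creatinine_clearance
    tvvd = params.theta[1] * record.subject.body_weight
    o = np.sqrt(params.omega2)
    ll = np.full((nodes, nodes), -np.inf)
    for i, e1 in enumerate(x * o[0]):
        for j, e2 in enumerate(x * o[1]):
            pk = cmzpk.IndividualPK(tvcl * np.exp(e1), tvvd * np.exp(e2))
            f = np.maximum(
                np.array([cmzpk.concentration(pk, record.doses, t) for t in record.times]),
                1e-12)
            var = params.sigma2 * f**2
            ll[i, j] = -0.5 * np.sum(np.log(2 * np.pi * var)
                                     + (record.conc - f)**2 / var)
    m = ll.max()
    lik = (w[:, None] * w[None, :] * np.exp(ll - m)).sum() / (2 * np.pi)
    return -2.0 * (m + np.log(lik))


def pta_tail_oracle(params, dose, bw, ccr, t, mic):
    """P(C(t) > mic) for fixed covariates under lognormal (CL, Vd):
    1-d quadrature over eta_Vd of the conditional normal tail in eta_CL."""
    c0 = dose / (params.theta[1] * bw)
    k_typ = params.theta[0] * ccr / (params.theta[1] * bw)
    a = np.log(c0 / mic)
    x, w = hermegauss(80)
    eta2 = x * params.omega[1]
    arg = a - eta2
    inner = np.where(
        arg > 0,
        stats.norm.cdf((eta2 + np.log(np.maximum(arg, 1e-300) / (k_typ * t)))
                       / params.omega[0]),
        0.0)
    return float((w * inner).sum() / np.sqrt(2 * np.pi))


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def canonical_params():
    return CEFMETAZOLE_COLORECTAL


@pytest.fixture(scope="session")
def cohort200():
    """A 200-subject synthetic cohort from the canonical parameters."""
    return cmzpk.simulate_dataset(CohortConfig(n_subjects=200, seed=7))


@pytest.fixture(scope="session")
def fit200(cohort200):
    """Final-model fit of the 200-subject cohort (shared: ~10 s)."""
    result = fit(cohort200, final_model())
    assert result.converged
    return result
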