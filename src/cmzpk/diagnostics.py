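"""Goodness-of-fit diagnostics and bootstrap model validation.

* ``compute_diagnostics`` — per-observation population predictions (PRED,
  at eta = 0), individual empirical-Bayes predictions (IPRED, at the
  conditional eta mode) and weighted residuals.  WRES follows the classic
  first-order definition: residuals (Cp - PRED) decorrelated by the
  per-subject covariance ``F Omega F' + diag(sigma2 * PRED^2)``, where F
  is the sensitivity of the prediction to eta at eta = 0.  Under the
  generating model WRES is approximately standard normal.

* ``bootstrap`` — nonparametric subject-level resampling: each replicate
  draws the original number of subjects with replacement, refits, and the
  report compares replicate means and SEs against the original fit
  (percent difference = (bootstrap - final)/final * 100).  Non-converged
  replicates are excluded from the summaries and counted against the
  convergence rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import PKDataset
from .errors import ConfigError, DataError
from .estimation import FitResult, fit
from .pk_core import concentration_profile
from .structural import StructuralModel

__all__ = ["compute_diagnostics", "bootstrap", "BootstrapReport", "plot_diagnostics"]

_H = 1e-5


def _predictions(packed, model: StructuralModel, params, eta):
    tvcl, tvvd = model.typical_values(params.theta, packed.covariates)
    cl = tvcl * np.exp(eta[:, 0])
    vd = tvvd * np.exp(eta[:, 1])
    return concentration_profile(cl, vd, packed.dose_t, packed.dose_amt,
                                 packed.dose_dur, packed.obs_t, packed.dose_mask)


def compute_diagnostics(dataset: PKDataset, fit_result: FitResult) -> pd.DataFrame:
    """Per-observation diagnostics table.

    Columns: ``id``, ``time``, ``dv`` (observed), ``pred``, ``ipred``,
    ``wres``.  Rows align one-to-one with the dataset's observations.
    """
    if not fit_result.converged:
        raise ConfigError("diagnostics require a converged fit")
    packed = dataset.packed()
    if list(packed.ids) != list(fit_result.ids):
        raise DataError("fit result does not match this dataset's subjects")
    params = fit_result.estimates
    model = fit_result.model
    zero = np.zeros((packed.n_subjects, 2))
    pred = _predictions(packed, model, params, zero)
    ipred = _predictions(packed, model, params, fit_result.ebe)

    # FO sensitivities of the prediction to eta at eta = 0
    F = np.empty((packed.n_subjects, packed.obs_t.shape[1], 2))
    for k in range(2):
        d = np.zeros((packed.n_subjects, 2))
        d[:, k] = _H
        F[:, :, k] = (_predictions(packed, model, params, d)
                      - _predictions(packed, model, params, -d)) / (2 * _H)

    omega2 = params.omega2
    rows = []
    for i, sid in enumerate(packed.ids):
        m = packed.obs_mask[i]
        yi = packed.obs_y[i][m]
        pi = pred[i][m]
        Fi = F[i][m]
        cov = (Fi * omega2) @ Fi.T + np.diag(params.sigma2 * pi**2)
        L = np.linalg.cholesky(cov)
        wres = np.linalg.solve(L, yi - pi)
        for j, t in enumerate(packed.obs_t[i][m]):
            rows.append({"id": sid, "time": float(t), "dv": float(yi[j]),
                         "pred": float(pi[j]), "ipred": float(ipred[i][m][j]),
                         "wres": float(wres[j])})
    return pd.DataFrame(rows)


@dataclass
class BootstrapReport:
    """Summary of subject-resampled refits.

    ``table`` has one row per parameter with the original estimate and SE,
    the bootstrap mean and SE (SD across converged replicates), and the
    percent difference of the means.
    """

    table: pd.DataFrame
    convergence_rate: float
    n_replicates: int
    estimates: np.ndarray      # (n_converged, n_params)
    seed: int | None


def bootstrap(dataset: PKDataset, model: StructuralModel,
              n_replicates: int = 200, seed: int | None = None,
              original: FitResult | None = None, **fit_kwargs) -> BootstrapReport:
    """Subject-level bootstrap of the population fit.

    Subjects (not rows) are resampled with replacement to the original
    subject count; each replicate is refit starting from the original
    estimates.  Deterministic under a fixed ``seed``.
    """
    if len(dataset) < 2:
        raise ConfigError("bootstrap requires at least two subjects")
    rng = np.random.default_rng(seed)
    if original is None:
        original = fit(dataset, model, **fit_kwargs)
    n = len(dataset)
    reps = []
    n_conv = 0
    for _ in range(n_replicates):
        idx = rng.integers(0, n, size=n)
        ds = dataset.resample(idx)
        f = fit(ds, model, init=original.estimates, compute_se=False,
                **{k: v for k, v in fit_kwargs.items() if k not in ("init", "compute_se")})
        if f.converged:
            n_conv += 1
            reps.append(f.param_values)
    est = np.array(reps) if reps else np.empty((0, original.param_values.size))
    names = original.param_names
    final_vals = original.param_values
    final_se = [original.standard_errors.get(nm, np.nan) for nm in names]
    boot_mean = est.mean(axis=0) if est.size else np.full(final_vals.size, np.nan)
    boot_se = est.std(axis=0, ddof=1) if est.shape[0] > 1 else np.zeros(final_vals.size)
    if est.shape[0] <= 1:
        boot_se = np.full(final_vals.size, 0.0 if est.shape[0] == 1 else np.nan)
    pct = (boot_mean - final_vals) / final_vals * 100.0
    table = pd.DataFrame({
        "parameter": names,
        "final_estimate": final_vals,
        "final_se": final_se,
        "bootstrap_mean": boot_mean,
        "bootstrap_se": boot_se,
        "percent_difference": pct,
    })
    return BootstrapReport(table=table, convergence_rate=n_conv / n_replicates,
                           n_replicates=n_replicates, estimates=est, seed=seed)


def plot_diagnostics(diag: pd.DataFrame, outdir) -> list:
    """Scatter plots: observed vs PRED, observed vs IPRED, WRES vs PRED.

    Returns the list of files written.  Matplotlib is imported lazily so
    headless library use never touches a plotting backend.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = []
    for xcol, ycol, name in (("pred", "dv", "obs_vs_pred"),
                             ("ipred", "dv", "obs_vs_ipred")):
        figf = outdir / f"{name}.png"
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.scatter(diag[xcol], diag[ycol], s=12, alpha=0.6)
        lim = max(diag[xcol].max(), diag[ycol].max()) * 1.05
        ax.plot([0, lim], [0, lim], "k--", lw=1)
        ax.set_xlabel(f"{xcol.upper()} (mg/L)")
        ax.set_ylabel("observed (mg/L)")
        fig.tight_layout()
        fig.savefig(figf, dpi=120)
        plt.close(fig)
        files.append(figf)
    figf = outdir / "wres_vs_pred.png"
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.scatter(diag["pred"], diag["wres"], s=12, alpha=0.6)
    ax.axhline(0, color="k", lw=1)
    for y in (-3, 3):
        ax.axhline(y, color="grey", lw=0.8, ls=":")
    ax.set_xlabel("PRED (mg/L)")
    ax.set_ylabel("WRES")
    fig.tight_layout()
    fig.savefig(figf, dpi=120)
    plt.close(fig)
    files.append(figf)
    return files
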