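"""End-to-end analysis pipeline and YAML run configuration.

A single config drives the reproducible chain

    simulate -> fit / search -> diagnose -> bootstrap -> pta

writing every artifact (dataset, estimates, audit trail, diagnostics,
bootstrap report, attainment grid, redosing table) as CSV under one
output directory, with the seed and parameter provenance recorded in a
JSON run log.  Stages can be run individually; a stage that needs an
upstream artifact reads it from the output directory.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import CohortConfig, study_cohort_config, simulate_dataset
from .dataset import PKDataset, read_dataset, write_dataset
from .diagnostics import bootstrap, compute_diagnostics
from .errors import ConfigError
from .estimation import covariate_search, fit
from .parameters import CEFMETAZOLE_COLORECTAL, PopPKParameters
from .pta import PTAConfig, recommend_redosing, simulate_pta
from .structural import default_candidates, final_model

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = ("simulate", "fit", "search", "diagnose", "bootstrap", "pta")


@dataclass
class RunConfig:
    """Declarative pipeline run.

    ``stages`` is an ordered subset of :data:`STAGES` (or ``["all"]``).
    ``dataset_path`` may point at an existing NONMEM-style CSV; otherwise
    the simulate stage writes one.
    """

    outdir: str = "cmzpk_run"
    seed: int = 0
    stages: list = field(default_factory=lambda: list(STAGES))
    dataset_path: str | None = None
    cohort: dict = field(default_factory=dict)
    pta: dict = field(default_factory=dict)
    bootstrap_replicates: int = 200
    parameters: dict | None = None     # {"theta": [...], "omega": [...], "sigma": x}

    def __post_init__(self) -> None:
        if self.stages == ["all"] or self.stages == "all":
            self.stages = list(STAGES)
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ConfigError(
                f"unknown stage(s) {unknown}; valid stages: {', '.join(STAGES)} or 'all'"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - allowed
        if unknown:
            raise ConfigError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**raw)

    def resolve_parameters(self) -> PopPKParameters:
        if self.parameters is None:
            return CEFMETAZOLE_COLORECTAL
        p = self.parameters
        return PopPKParameters.from_sd(theta=p["theta"], omega=p["omega"],
                                       sigma=p["sigma"])


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages in canonical order.

    Returns a dict of in-memory artifacts (dataset, fit, search, diag,
    bootstrap, grid, redosing) for the stages that ran.  A stage failure
    raises immediately, halting downstream stages.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log = {"version": __version__, "seed": config.seed,
           "stages": list(config.stages), "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
           "events": []}
    artifacts: dict = {}
    rng = np.random.default_rng(config.seed)

    def note(msg, **kw):
        log["events"].append({"msg": msg, **kw})

    dataset: PKDataset | None = None
    if "simulate" in config.stages:
        cfg = study_cohort_config(seed=None, **config.cohort)
        dataset = simulate_dataset(cfg, rng)
        write_dataset(dataset, outdir / "dataset.csv")
        note("simulate", n_subjects=len(dataset), n_obs=dataset.n_observations,
             path=str(outdir / "dataset.csv"))
        artifacts["dataset"] = dataset
    elif config.dataset_path:
        dataset = read_dataset(config.dataset_path)
        note("load", path=config.dataset_path, n_subjects=len(dataset))
        artifacts["dataset"] = dataset
    elif (outdir / "dataset.csv").exists():
        dataset = read_dataset(outdir / "dataset.csv")
        artifacts["dataset"] = dataset

    def need_dataset(stage):
        if dataset is None:
            raise ConfigError(f"stage '{stage}' needs a dataset: run 'simulate' "
                              "first or set dataset_path")
        return dataset

    fit_result = None
    if "fit" in config.stages:
        ds = need_dataset("fit")
        fit_result = fit(ds, final_model())
        est = fit_result.estimates
        table = pd.DataFrame({
            "parameter": fit_result.param_names,
            "estimate": fit_result.param_values,
            "se": [fit_result.standard_errors.get(n, np.nan)
                   for n in fit_result.param_names],
        })
        table.to_csv(outdir / "fit_estimates.csv", index=False)
        note("fit", converged=fit_result.converged, obj=fit_result.objective,
             theta=[float(v) for v in est.theta])
        artifacts["fit"] = fit_result

    if "search" in config.stages:
        ds = need_dataset("search")
        search = covariate_search(ds, default_candidates())
        search.audit.to_csv(outdir / "search_audit.csv", index=False)
        note("search", final=search.final_model.label(),
             obj=search.final_fit.objective)
        artifacts["search"] = search

    if "diagnose" in config.stages:
        ds = need_dataset("diagnose")
        if fit_result is None:
            fit_result = fit(ds, final_model())
            artifacts["fit"] = fit_result
        diag = compute_diagnostics(ds, fit_result)
        diag.to_csv(outdir / "diagnostics.csv", index=False)
        note("diagnose", n_rows=len(diag), wres_mean=float(diag["wres"].mean()))
        artifacts["diagnostics"] = diag

    if "bootstrap" in config.stages:
        ds = need_dataset("bootstrap")
        if fit_result is None:
            fit_result = fit(ds, final_model())
            artifacts["fit"] = fit_result
        boot_seed = int(rng.integers(0, 2**31 - 1))
        report = bootstrap(ds, final_model(), n_replicates=config.bootstrap_replicates,
                           seed=boot_seed, original=fit_result)
        report.table.to_csv(outdir / "bootstrap.csv", index=False)
        note("bootstrap", convergence_rate=report.convergence_rate, seed=boot_seed)
        artifacts["bootstrap"] = report

    if "pta" in config.stages:
        params = (fit_result.estimates if fit_result is not None
                  else config.resolve_parameters())
        pta_cfg = PTAConfig(**config.pta)
        grid = simulate_pta(params, pta_cfg, rng)
        grid.to_frame().to_csv(outdir / "pta_grid.csv")
        recs = recommend_redosing(grid)
        pd.DataFrame([
            {"ccr_bin": f"{lo:g}-{hi:g}", "interval_h": r.interval_h,
             "meets_floor": r.meets_floor}
            for (lo, hi), r in recs.items()
        ]).to_csv(outdir / "redosing.csv", index=False)
        note("pta", mic=pta_cfg.mic, n_draws=pta_cfg.n_draws,
             intervals={f"{lo:g}-{hi:g}": r.interval_h for (lo, hi), r in recs.items()})
        artifacts["pta"] = grid
        artifacts["redosing"] = recs

    log["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    log["converged"] = bool(fit_result.converged) if fit_result is not None else None
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)
    artifacts["log"] = log
    return artifacts
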