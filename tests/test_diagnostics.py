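"""PRED/IPRED/WRES diagnostics and bootstrap validation."""

import numpy as np
import pytest
from scipy import stats

import cmzpk
from cmzpk import CohortConfig, PopPKParameters, bootstrap, compute_diagnostics, final_model, fit
from cmzpk.errors import ConfigError
from cmzpk.estimation import FitResult


def _truth_fit(dataset, params):
    """FitResult holding the generating parameters (no estimation), for
    diagnostics checks against the known truth."""
    return FitResult(model=final_model(), estimates=params,
                     objective=0.0, converged=True,
                     ebe=np.zeros((len(dataset), 2)),
                     ids=[r.subject.id for r in dataset])


class TestDiagnostics:
    def test_noise_free_residuals_vanish(self):
        gen = PopPKParameters.from_sd([0.0704, 0.163], [0.0, 0.0], 0.0)
        cfg = CohortConfig(n_subjects=5, seed=31, generating_parameters=gen,
                           blq_rule="keep")
        ds = cmzpk.simulate_dataset(cfg)
        at_truth = PopPKParameters.from_sd([0.0704, 0.163], [0.0, 0.0], 0.01)
        diag = compute_diagnostics(ds, _truth_fit(ds, at_truth))
        np.testing.assert_allclose(diag["pred"], diag["dv"], rtol=1e-12)
        np.testing.assert_allclose(diag["ipred"], diag["dv"], rtol=1e-12)
        np.testing.assert_allclose(diag["wres"], 0.0, atol=1e-9)

    def test_wres_standard_normal_under_generating_model(self):
        """FO-decorrelated residuals on data simulated from the evaluated
        model are approximately N(0,1): KS test at 800 observations."""
        cfg = CohortConfig(n_subjects=160, seed=32, blq_rule="keep")
        ds = cmzpk.simulate_dataset(cfg)
        diag = compute_diagnostics(ds, _truth_fit(ds, cmzpk.CEFMETAZOLE_COLORECTAL))
        assert len(diag) == 800
        assert abs(diag["wres"].mean()) < 0.1
        _, p = stats.kstest(diag["wres"], "norm")
        assert p > 0.01

    def test_wres_mostly_within_three(self, cohort200, fit200):
        # FO-linearized WRES under lognormal truth is slightly heavier-
        # tailed than exact N(0,1) (SD ~1.03), so the +/-3 band captures
        # ~99% rather than the Gaussian 99.7%
        diag = compute_diagnostics(cohort200, fit200)
        assert (np.abs(diag["wres"]) <= 3.0).mean() >= 0.98

    def test_ipred_correlates_better_than_pred(self, cohort200, fit200):
        """Empirical-Bayes individual predictions track observations more
        closely than population predictions (shrinkage property)."""
        diag = compute_diagnostics(cohort200, fit200)
        r2_pred = np.corrcoef(diag["dv"], diag["pred"])[0, 1] ** 2
        r2_ipred = np.corrcoef(diag["dv"], diag["ipred"])[0, 1] ** 2
        assert r2_ipred >= r2_pred
        assert r2_ipred > 0.9

    def test_plot_files_written(self, tmp_path):
        gen = cmzpk.CEFMETAZOLE_COLORECTAL
        ds = cmzpk.simulate_dataset(CohortConfig(n_subjects=8, seed=37))
        diag = compute_diagnostics(ds, _truth_fit(ds, gen))
        files = cmzpk.diagnostics.plot_diagnostics(diag, tmp_path)
        assert len(files) == 3 and all(f.exists() for f in files)

    def test_requires_matching_converged_fit(self, cohort200, fit200):
        other = cmzpk.simulate_dataset(CohortConfig(n_subjects=3, seed=33))
        with pytest.raises(cmzpk.DataError):
            compute_diagnostics(other, fit200)
        bad = FitResult(model=final_model(), estimates=cmzpk.CEFMETAZOLE_COLORECTAL,
                        objective=np.nan, converged=False,
                        ebe=np.zeros((3, 2)), ids=[1, 2, 3])
        with pytest.raises(ConfigError):
            compute_diagnostics(other, bad)


@pytest.fixture(scope="module")
def small_cohort():
    return cmzpk.simulate_dataset(CohortConfig(n_subjects=12, seed=34))


@pytest.fixture(scope="module")
def small_fit(small_cohort):
    return fit(small_cohort, final_model())


class TestBootstrap:
    def test_identity_resample_reproduces_fit(self, small_cohort, small_fit):
        ds = small_cohort.resample(range(len(small_cohort)))
        refit = fit(ds, final_model(), init=small_fit.estimates, compute_se=False)
        np.testing.assert_allclose(refit.param_values, small_fit.param_values,
                                   rtol=1e-4, atol=1e-6)
        assert abs(refit.objective - small_fit.objective) < 1e-5

    def test_report_shape_and_percent_difference(self, small_cohort, small_fit):
        report = bootstrap(small_cohort, final_model(), n_replicates=10,
                           seed=100, original=small_fit)
        t = report.table
        assert list(t["parameter"]) == small_fit.param_names
        np.testing.assert_allclose(
            t["percent_difference"],
            (t["bootstrap_mean"] - t["final_estimate"]) / t["final_estimate"] * 100)
        assert report.convergence_rate >= 0.9
        # replicate means within a few bootstrap SEs of the original fit
        dev = np.abs(t["bootstrap_mean"] - t["final_estimate"])
        assert np.all(dev <= 4 * np.maximum(t["bootstrap_se"],
                                            0.05 * np.abs(t["final_estimate"])))

    def test_percent_difference_arithmetic(self):
        # published example: bootstrap 0.070 vs final 0.084 -> -16.7%
        assert (0.070 - 0.084) / 0.084 * 100 == pytest.approx(-16.7, abs=0.05)

    def test_deterministic_under_seed(self, small_cohort, small_fit):
        a = bootstrap(small_cohort, final_model(), n_replicates=5, seed=7,
                      original=small_fit)
        b = bootstrap(small_cohort, final_model(), n_replicates=5, seed=7,
                      original=small_fit)
        assert a.table.equals(b.table)

    def test_identical_subjects_zero_bootstrap_se(self):
        base = cmzpk.simulate_dataset(CohortConfig(n_subjects=1, seed=35))
        ds = base.resample([0, 0, 0, 0])
        original = fit(ds, final_model(), compute_se=False)
        report = bootstrap(ds, final_model(), n_replicates=4, seed=1,
                           original=original)
        np.testing.assert_allclose(report.table["bootstrap_se"], 0.0, atol=1e-9)

    def test_requires_two_subjects(self):
        ds = cmzpk.simulate_dataset(CohortConfig(n_subjects=1, seed=36))
        with pytest.raises(ConfigError):
            bootstrap(ds, final_model(), n_replicates=2, seed=1)
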