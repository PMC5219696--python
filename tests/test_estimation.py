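"""Mixed-effects objective, fitting, LRT and covariate search."""

import numpy as np
import pytest

import cmzpk
from cmzpk import (CohortConfig, CovariateModelSpec, PopPKParameters,
                   base_model, final_model, fit, lrt_covariate_test,
                   objective_function)
from cmzpk.dataset import PKDataset, SubjectRecord
from cmzpk.errors import ConfigError
from cmzpk.estimation import FitResult, covariate_search
from cmzpk.pk_core import DoseEvent, IndividualPK, Subject, concentration_profile
from cmzpk.structural import default_candidates

from conftest import quadrature_objective

CANON = cmzpk.CEFMETAZOLE_COLORECTAL
SUBJ = Subject(1, 69, "male", 63.7, 0.84, creatinine_clearance=100.0)
BOLUS = [DoseEvent(0.0, 1000.0)]


def _single_record(times, conc, sid=1):
    subj = Subject(sid, 69, "male", 63.7, 0.84, creatinine_clearance=100.0)
    return SubjectRecord(subj, BOLUS, np.asarray(times, float),
                         np.asarray(conc, float))


class TestObjectiveFunction:
    def test_no_random_effects_closed_form(self):
        """With omega2 = 0 the integral collapses to the exact normal
        -2 log density at eta = 0."""
        params = PopPKParameters(theta=CANON.theta, omega2=[0.0, 0.0],
                                 sigma2=CANON.sigma2)
        ds = PKDataset([_single_record([2.0], [25.0])])
        pk = IndividualPK(7.04, 0.163 * 63.7)
        f = cmzpk.concentration(pk, BOLUS, 2.0)
        var = CANON.sigma2 * f**2
        closed = np.log(2 * np.pi * var) + (25.0 - f) ** 2 / var
        assert objective_function(ds, final_model(), params) == \
            pytest.approx(closed, abs=1e-9)

    def test_matches_independent_laplace_construction(self):
        """The value equals a from-scratch Laplace at the mode of the same
        integrand (mode by Nelder-Mead, Hessian by finite differences)."""
        from scipy import optimize

        rec = _single_record([1.0, 3.0], [40.0, 12.0])
        ds = PKDataset([rec])
        tvcl, tvvd = 7.04, 0.163 * 63.7

        def g(eta):
            pk = IndividualPK(tvcl * np.exp(eta[0]), tvvd * np.exp(eta[1]))
            f = np.array([cmzpk.concentration(pk, BOLUS, t) for t in rec.times])
            var = CANON.sigma2 * f**2
            ll = -0.5 * np.sum(np.log(2 * np.pi * var) + (rec.conc - f) ** 2 / var)
            lp = -0.5 * np.sum(np.log(2 * np.pi * CANON.omega2)
                               + eta**2 / CANON.omega2)
            return -(ll + lp)

        res = optimize.minimize(g, [0, 0], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        h = 1e-5
        H = np.zeros((2, 2))
        for i in range(2):
            for j in range(2):
                ei = np.zeros(2); ei[i] = h
                ej = np.zeros(2); ej[j] = h
                H[i, j] = (g(res.x + ei + ej) - g(res.x + ei - ej)
                           - g(res.x - ei + ej) + g(res.x - ei - ej)) / (4 * h * h)
        ref = 2 * g(res.x) - 2 * np.log(2 * np.pi) + np.log(np.linalg.det(H))
        ours = objective_function(ds, final_model(), CANON)
        assert ours == pytest.approx(ref, abs=1e-4)

    def test_near_quadrature_on_tiny_instances(self):
        """Laplace vs dense Gauss-Hermite quadrature: agreement at the
        approximation's intrinsic accuracy (a few hundredths of an OBJ
        unit for 1-3 sparse observations at the study's error levels)."""
        for times, conc in ([[1.0, 3.0], [40.0, 12.0]],
                            [[0.5, 2.0, 4.0], [70.0, 25.0, 6.0]]):
            rec = _single_record(times, conc)
            lap = objective_function(PKDataset([rec]), final_model(), CANON)
            quad = quadrature_objective(rec, CANON)
            assert lap == pytest.approx(quad, abs=0.06)

    def test_likelihood_factorizes_over_subjects(self):
        rec1 = _single_record([1.0, 3.0], [40.0, 12.0], sid=1)
        rec2 = _single_record([1.0, 3.0], [40.0, 12.0], sid=2)
        obj1 = objective_function(PKDataset([rec1]), final_model(), CANON)
        obj2 = objective_function(PKDataset([rec1, rec2]), final_model(), CANON)
        assert obj2 == pytest.approx(2 * obj1, abs=1e-8)

    def test_zero_sigma_rejected(self):
        params = PopPKParameters(theta=CANON.theta, omega2=CANON.omega2, sigma2=0.0)
        ds = PKDataset([_single_record([2.0], [25.0])])
        with pytest.raises(ConfigError):
            objective_function(ds, final_model(), params)


class TestFit:
    def test_noise_free_recovery_to_four_digits(self):
        params = PopPKParameters.from_sd(CANON.theta, [0.0, 0.0], 0.0)
        cfg = CohortConfig(n_subjects=10, seed=21, generating_parameters=params,
                           blq_rule="keep")
        ds = cmzpk.simulate_dataset(cfg)
        res = fit(ds, final_model(), compute_se=False)
        assert res.converged
        np.testing.assert_allclose(res.estimates.theta, CANON.theta, rtol=1e-4)

    def test_refit_is_a_fixed_point(self, cohort200, fit200):
        res2 = fit(cohort200, final_model(), init=fit200.estimates,
                   compute_se=False)
        assert abs(res2.objective - fit200.objective) < 1e-5

    def test_recovery_on_synthetic_cohort(self, fit200):
        est = fit200.estimates
        assert est.theta[0] == pytest.approx(0.0704, rel=0.10)
        assert est.theta[1] == pytest.approx(0.163, rel=0.05)
        assert est.sigma == pytest.approx(0.135, rel=0.15)
        ses = fit200.standard_errors
        assert all(np.isfinite(v) for v in ses.values())

    def test_relabeling_and_order_invariance(self):
        cfg = CohortConfig(n_subjects=30, seed=22)
        ds = cmzpk.simulate_dataset(cfg)
        perm = np.random.default_rng(1).permutation(len(ds))
        shuffled = PKDataset([ds.records[i] for i in perm])
        a = fit(ds, final_model(), compute_se=False)
        b = fit(shuffled, final_model(), compute_se=False)
        # summation-order float noise is amplified along flat directions
        # (variance components near their bound), hence the mixed tolerance
        np.testing.assert_allclose(a.estimates.theta, b.estimates.theta, rtol=1e-3)
        np.testing.assert_allclose(a.param_values, b.param_values,
                                   rtol=1e-2, atol=5e-3)
        assert a.objective == pytest.approx(b.objective, abs=1e-2)

    def test_nesting_monotonicity(self):
        ds = cmzpk.simulate_dataset(CohortConfig(n_subjects=25, seed=23))
        base = fit(ds, base_model(), compute_se=False)
        ext = fit(ds, base_model().with_spec(
            CovariateModelSpec("CL", "linear", "ccr")), compute_se=False)
        assert ext.objective <= base.objective + 1e-6


class TestLRT:
    def _fit_stub(self, model, obj):
        return FitResult(model=model, estimates=CANON, objective=obj,
                         converged=True, ebe=np.zeros((1, 2)), ids=[1])

    def test_published_forward_step_is_significant(self):
        # base OBJ 491.305 vs Ccr-on-CL OBJ 476.461: drop of 14.844
        base = self._fit_stub(base_model(), 491.305)
        ext = self._fit_stub(base_model().with_spec(
            CovariateModelSpec("CL", "linear", "ccr")), 476.461)
        res = lrt_covariate_test(base, ext, alpha=0.001)
        assert res.delta_obj == pytest.approx(-14.844)
        assert res.p < 0.001 and res.significant

    def test_zero_drop_never_significant(self):
        base = self._fit_stub(base_model(), 100.0)
        ext = self._fit_stub(base_model().with_spec(
            CovariateModelSpec("Vd", "linear", "bw")), 100.0)
        assert not lrt_covariate_test(base, ext, alpha=0.5).significant

    def test_chi_square_critical_value_one_df(self):
        # chi2(1) 0.99-quantile = 6.635: a drop of 6.64 is just significant
        base = self._fit_stub(base_model(), 50.0)
        ext = self._fit_stub(base_model().with_spec(
            CovariateModelSpec("CL", "linear", "ccr")), 50.0 - 6.64)
        assert lrt_covariate_test(base, ext, alpha=0.01).significant
        ext2 = self._fit_stub(ext.model, 50.0 - 6.63)
        assert not lrt_covariate_test(base, ext2, alpha=0.01).significant

    def test_non_nested_pair_is_an_error(self):
        a = self._fit_stub(base_model().with_spec(
            CovariateModelSpec("CL", "linear", "ccr")), 10.0)
        b = self._fit_stub(base_model().with_spec(
            CovariateModelSpec("Vd", "linear", "bw")), 9.0)
        with pytest.raises(ConfigError):
            lrt_covariate_test(a, b)


class TestCovariateSearch:
    def test_empty_candidate_list_returns_base(self):
        ds = cmzpk.simulate_dataset(CohortConfig(n_subjects=10, seed=24))
        res = covariate_search(ds, [])
        assert res.final_model == base_model()
        assert res.selected == []

    def test_null_data_selects_no_covariates(self):
        """Concentrations generated with covariate-independent CL and Vd:
        the forward p<0.01 / backward p<0.001 procedure keeps the base
        model (type-I error control)."""
        cfg = CohortConfig(n_subjects=50, seed=25)
        rng = np.random.default_rng(25)
        subjects = cmzpk.generate_cohort(cfg, rng)
        records = []
        times = np.asarray(cfg.observation_times)
        for s in subjects:
            eta = rng.normal(0, 1, 2) * CANON.omega
            cl, vd = 5.2 * np.exp(eta[0]), 10.4 * np.exp(eta[1])
            f = concentration_profile(
                np.array([cl]), np.array([vd]),
                np.array([[0.0, 3.0]]), np.array([[1000.0, 1000.0]]),
                np.array([[0.0, 0.0]]), times[None, :])[0]
            dv = f * (1 + rng.normal(0, CANON.sigma, times.size))
            records.append(SubjectRecord(s, [DoseEvent(0, 1000), DoseEvent(3, 1000)],
                                         times, dv))
        res = covariate_search(PKDataset(records), default_candidates())
        assert res.selected_pairs == set()
        assert res.final_model == base_model()
        # audit trail covers base + every candidate
        assert (res.audit["stage"] == "forward").sum() == len(default_candidates())
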