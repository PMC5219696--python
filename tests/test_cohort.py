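"""Synthetic cohort generator: covariate structure and error model."""

import numpy as np
import pytest

import cmzpk
from cmzpk import CohortConfig, CovariateRange, PopPKParameters
from cmzpk.cohort import generate_cohort, simulate_observations, study_cohort_config
from cmzpk.errors import ConfigError


def _degenerate_ranges():
    return {
        "age": CovariateRange(69.0, 0.0, 41.0, 84.0),
        "bw": CovariateRange(63.7, 0.0, 47.5, 89.0),
        "ccr": CovariateRange(73.9, 0.0, 47.2, 126.3),
        "alb": CovariateRange(3.8, 0.0, 3.3, 4.6),
    }


class TestGenerateCohort:
    def test_sample_mean_within_standard_error(self):
        cfg = CohortConfig(n_subjects=23, seed=0)
        subjects = generate_cohort(cfg)
        bw = np.array([s.body_weight for s in subjects])
        assert len(subjects) == 23
        assert abs(bw.mean() - 63.7) <= 2 * 9.9 / np.sqrt(23)

    def test_degenerate_sd_gives_exact_means(self):
        cfg = CohortConfig(n_subjects=1, seed=1, covariate_ranges=_degenerate_ranges())
        (s,) = generate_cohort(cfg)
        assert (s.age, s.body_weight, s.creatinine_clearance, s.albumin) == \
            (69.0, 63.7, 73.9, 3.8)

    def test_same_seed_identical_cohorts(self):
        a = cmzpk.simulate_dataset(CohortConfig(n_subjects=23, seed=42))
        b = cmzpk.simulate_dataset(CohortConfig(n_subjects=23, seed=42))
        assert a.to_frame().equals(b.to_frame())

    def test_ccr_consistent_with_cockcroft_gault(self):
        for s in generate_cohort(CohortConfig(n_subjects=30, seed=3)):
            assert s.creatinine_clearance == pytest.approx(
                cmzpk.cockcroft_gault(s.age, s.body_weight, s.serum_creatinine, s.sex))

    def test_infeasible_truncation_is_config_error(self):
        with pytest.raises(ConfigError):
            CovariateRange(100.0, 5.0, 0.0, 90.0)
        with pytest.raises(ConfigError):
            CohortConfig(n_subjects=0)


class TestSimulateObservations:
    def test_noise_free_limit_equals_predictions(self):
        params = PopPKParameters.from_sd([0.0704, 0.163], [0.0, 0.0], 0.0)
        cfg = CohortConfig(n_subjects=4, seed=5, generating_parameters=params,
                           blq_rule="keep")
        ds = cmzpk.simulate_dataset(cfg)
        for rec in ds:
            pk = cmzpk.structural_parameters(rec.subject, params.theta)
            expected = cmzpk.concentration(pk, rec.doses, rec.times)
            np.testing.assert_allclose(rec.conc, expected, rtol=1e-12)

    def test_median_concentration_matches_typical_value(self):
        # fixed covariates Ccr 110 / Bw 65; typical C(2h) = (1000/10.595)
        # * exp(-2*7.744/10.595) = 21.88 mg/L; the median (not the mean) of
        # the lognormal-eta concentration equals the typical value
        ranges = _degenerate_ranges()
        ranges["ccr"] = CovariateRange(110.0, 0.0, 110.0, 110.0)
        ranges["bw"] = CovariateRange(65.0, 0.0, 65.0, 65.0)
        cfg = CohortConfig(n_subjects=4000, seed=8, covariate_ranges=ranges,
                           observation_times=[2.0])
        ds = cmzpk.simulate_dataset(cfg)
        conc = np.concatenate([r.conc for r in ds])
        typical = (1000 / (0.163 * 65)) * np.exp(-2 * (0.0704 * 110) / (0.163 * 65))
        assert np.median(conc) == pytest.approx(typical, rel=0.02)

    def test_clearance_cv_converges_to_omega(self):
        cfg = CohortConfig(n_subjects=10_000, seed=9, observation_times=[1.0])
        ds = cmzpk.simulate_dataset(cfg)
        cl = np.array([r.individual_pk.clearance for r in ds])
        ccr = np.array([r.subject.creatinine_clearance for r in ds])
        ratio = cl / (0.0704 * ccr)          # exp(eta_CL)
        cv = ratio.std(ddof=1) / ratio.mean()
        assert cv == pytest.approx(0.210, rel=0.03)

    def test_residual_scatter_sd_matches_sigma(self):
        cfg = CohortConfig(n_subjects=2000, seed=10, observation_times=[1.0, 3.25])
        ds = cmzpk.simulate_dataset(cfg)
        ratios = []
        for r in ds:
            pred = cmzpk.concentration(r.individual_pk, r.doses, r.times)
            ratios.append(r.conc / pred - 1.0)
        sd = np.concatenate(ratios).std(ddof=1)
        assert sd == pytest.approx(0.135, rel=0.05)

    def test_blq_rule_drop_removes_low_concentrations(self):
        # long horizon so troughs fall below the 0.5 ug/mL detection limit
        cfg_drop = CohortConfig(n_subjects=20, seed=11,
                                dosing_regimen=[cmzpk.DoseEvent(0, 1000)],
                                observation_times=[0.25, 2.0, 12.0, 18.0])
        cfg_keep = CohortConfig(n_subjects=20, seed=11,
                                dosing_regimen=[cmzpk.DoseEvent(0, 1000)],
                                observation_times=[0.25, 2.0, 12.0, 18.0],
                                blq_rule="keep")
        ds_drop = cmzpk.simulate_dataset(cfg_drop)
        ds_keep = cmzpk.simulate_dataset(cfg_keep)
        assert ds_keep.n_observations == 80
        assert ds_drop.n_observations < ds_keep.n_observations
        assert all(c >= 0.5 for r in ds_drop for c in r.conc)

    def test_missing_variances_rejected(self):
        cfg = CohortConfig(n_subjects=2, seed=1)
        cfg.generating_parameters = PopPKParameters.from_sd(
            [0.0704], [0.21, 0.084], 0.135)
        with pytest.raises(ConfigError):
            cmzpk.simulate_dataset(cfg)


class TestSurgicalScheme:
    def test_study_fixture_shape(self):
        """23 subjects sampled at surgical events: ~4 samples each, in the
        neighbourhood of the study's 86 serum measurements."""
        ds = cmzpk.simulate_dataset(study_cohort_config(seed=12))
        ids = {r.subject.id for r in ds}
        assert len(ids) == 23
        assert 70 <= ds.n_observations <= 115
        # redoses only while surgery is ongoing: every subject has >= 1 dose
        # and doses are 3 h apart
        for r in ds:
            dose_times = [d.time for d in r.doses]
            assert dose_times[0] == 0.0
            assert np.allclose(np.diff(dose_times), 3.0)
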