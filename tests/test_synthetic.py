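"""Synthetic cohort generator: frequencies, noise models, determinism."""

import dataclasses

import numpy as np
import pytest

from vpapkpd.dataset import flag_noncompliance
from vpapkpd.pd_model import AUC_SCALE, DEFAULT_PD_TRUTH, PDParameters
from vpapkpd.pk_model import (
    DEFAULT_PK_TRUTH,
    DEFAULT_PK_VARIANCE,
    PKVariance,
    Regimen,
    concentration,
    individual_parameters,
)
from vpapkpd.synthetic import (
    GeneratorConfig,
    generate_cohort,
    pd_cohort_config,
    pk_cohort_config,
    simulate_concentrations,
    simulate_ggt_events,
)


def _se(p, n):
    return np.sqrt(p * (1 - p) / n)


class TestGenerateCohort:
    def test_genotype_frequencies_match_targets(self):
        n = 10_000
        cohort = generate_cohort(dataclasses.replace(pd_cohort_config(),
                                                     n_subjects=n), seed=11)
        valval = np.mean([s.sod2 == "ValVal" for s in cohort.subjects])
        assert abs(valval - 0.776) < 3 * _se(0.776, n)
        gstm1_null = np.mean([s.gstm1 == "null" for s in cohort.subjects])
        assert abs(gstm1_null - 0.568) < 3 * _se(0.568, n)
        cyp2c9_var = np.mean([s.cyp2c9 != "*1/*1" for s in cohort.subjects])
        expected = 1 - (1 - 0.032) ** 2  # HWE carrier frequency
        assert abs(cyp2c9_var - expected) < 3 * _se(expected, n)

    def test_degenerate_frequency_generates_nothing(self):
        cfg = dataclasses.replace(pd_cohort_config(), n_subjects=500,
                                  sod2=(1.0, 0.0, 0.0))
        cohort = generate_cohort(cfg, seed=1)
        assert all(s.sod2 == "ValVal" for s in cohort.subjects)

    def test_dose_within_clinical_range(self):
        cohort = generate_cohort(pk_cohort_config(), seed=2)
        doses = np.array([s.daily_dose for s in cohort.subjects])
        assert doses.min() >= 100.0 and doses.max() <= 2600.0
        assert np.all(doses % 100 == 0)

    def test_inducer_comedication_enriched_with_disability(self):
        cfg = dataclasses.replace(pd_cohort_config(), n_subjects=20_000)
        cohort = generate_cohort(cfg, seed=3)
        dis = np.array([s.intellectual_disability for s in cohort.subjects])
        cbz = np.array(["CBZ" in s.comeds for s in cohort.subjects])
        assert cbz[dis].mean() > 1.5 * cbz[~dis].mean()
        # marginal frequency still matches the configured target
        assert abs(cbz.mean() - 0.199) < 3 * _se(0.199, len(cbz))

    def test_determinism(self):
        cfg = pd_cohort_config()
        assert generate_cohort(cfg, seed=9) == generate_cohort(cfg, seed=9)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GeneratorConfig(n_subjects=0)
        with pytest.raises(ValueError):
            GeneratorConfig(sod2=(0.5, 0.2, 0.2))
        with pytest.raises(ValueError):
            GeneratorConfig(dose_mean=5000.0)  # outside truncation range


class TestSimulateConcentrations:
    def test_noise_free_limit_reproduces_typical_curve(self):
        cfg = dataclasses.replace(pd_cohort_config(), n_subjects=5)
        cohort = generate_cohort(cfg, seed=4)
        novar = PKVariance(omega2={}, sigma2=0.0)
        records, _ = simulate_concentrations(cohort, DEFAULT_PK_TRUTH, novar,
                                             seed=5, config=cfg)
        for rec in records:
            subject = cohort.subject(rec.subject_id)
            ind = individual_parameters(DEFAULT_PK_TRUTH, subject)
            regimen = Regimen(rec.dose_per_administration, rec.dosing_interval)
            expected = concentration(rec.time_after_last_dose, regimen, ind)
            assert rec.value == pytest.approx(expected, rel=1e-12)

    def test_mean_concentration_in_reported_neighbourhood(self):
        """At the published generating values the synthetic TDM data sit near
        the cohort-summary mean of 68.15 mg/L (checked across seeds)."""
        cfg = pk_cohort_config()
        means = []
        for seed in (21, 22, 23):
            cohort = generate_cohort(cfg, seed)
            recs, _ = simulate_concentrations(cohort, DEFAULT_PK_TRUTH,
                                              DEFAULT_PK_VARIANCE, seed + 100, cfg)
            kept, _ = flag_noncompliance(recs)
            means.append(np.mean([r.value for r in kept]))
        assert abs(np.mean(means) - 68.15) < 8.0
        assert np.std(means) < 5.0

    def test_sample_count_expectation(self):
        cfg = pk_cohort_config()
        lo, hi = cfg.conc_samples
        assert (lo + hi) / 2 == pytest.approx(827 / 237, abs=0.1)
        cohort = generate_cohort(cfg, seed=6)
        recs, _ = simulate_concentrations(cohort, DEFAULT_PK_TRUTH,
                                          DEFAULT_PK_VARIANCE, 7, cfg)
        per_subject = len(recs) / cfg.n_subjects
        assert abs(per_subject - 3.5) < 3 * np.sqrt(1.25 / cfg.n_subjects)

    def test_truth_auc_consistent_with_realised_clearance(self):
        cfg = pd_cohort_config()
        cohort = generate_cohort(cfg, seed=8)
        _, truth = simulate_concentrations(cohort, DEFAULT_PK_TRUTH,
                                           DEFAULT_PK_VARIANCE, 9, cfg)
        for s in cohort.subjects[:10]:
            t = truth[s.subject_id]
            assert t["auc"] == pytest.approx(s.daily_dose / t["cl_i"], rel=1e-12)


class TestSimulateGGTEvents:
    def test_floor_intercept_gives_no_events(self):
        cfg = dataclasses.replace(pd_cohort_config(), n_subjects=50)
        cohort = generate_cohort(cfg, seed=10)
        auc = {s.subject_id: 1500.0 for s in cohort.subjects}
        params = PDParameters(base=-50.0, omega2_logit=0.0)
        records = simulate_ggt_events(cohort, params, auc, seed=11, config=cfg)
        assert records and all(r.elevated == 0 for r in records)

    def test_visit_count_expectation(self):
        cfg = pd_cohort_config()
        n, p = cfg.ggt_visits_binom
        assert cfg.ggt_visits_base + n * p == pytest.approx(472 / 169, abs=0.05)

    def test_visits_respect_six_month_floor(self):
        cfg = dataclasses.replace(pd_cohort_config(), n_subjects=40)
        cohort = generate_cohort(cfg, seed=12)
        auc = {s.subject_id: 1500.0 for s in cohort.subjects}
        records = simulate_ggt_events(cohort, DEFAULT_PD_TRUTH, auc, seed=13,
                                      config=cfg)
        assert all(r.months_since_vpa_start >= 6.0 - 1e-9 for r in records)

    def test_marginal_event_rate_matches_numerical_integration(self):
        """Monte-Carlo event fraction vs Gauss-Hermite integration of the
        random intercept, within binomial error."""
        cfg = dataclasses.replace(pd_cohort_config(), n_subjects=400)
        cohort = generate_cohort(cfg, seed=14)
        rng = np.random.default_rng(15)
        auc = {s.subject_id: float(rng.uniform(800, 2500))
               for s in cohort.subjects}
        records = simulate_ggt_events(cohort, DEFAULT_PD_TRUTH, auc, seed=16,
                                      config=cfg)
        observed = np.mean([r.elevated for r in records])

        x, w = np.polynomial.hermite.hermgauss(64)
        sd = np.sqrt(DEFAULT_PD_TRUTH.omega2_logit)
        expected_by_subject = []
        for s in cohort.subjects:
            logit0 = (DEFAULT_PD_TRUTH.base
                      + DEFAULT_PD_TRUTH.coef_id * s.intellectual_disability
                      + DEFAULT_PD_TRUTH.coef_sod2_valval * s.sod2_valval
                      + DEFAULT_PD_TRUTH.slope * auc[s.subject_id] * AUC_SCALE)
            p = 1 / (1 + np.exp(-(logit0 + np.sqrt(2) * sd * x)))
            expected_by_subject.append(float(np.sum(w * p) / np.sqrt(np.pi)))
        expected = np.mean(expected_by_subject)
        n_obs = len(records)
        # subject-level clustering inflates the binomial error
        assert abs(observed - expected) < 5 * np.sqrt(expected * (1 - expected) / cfg.n_subjects)

    def test_ggt_values_consistent_with_elevation_flag(self, uln):
        cfg = dataclasses.replace(pd_cohort_config(), n_subjects=60)
        cohort = generate_cohort(cfg, seed=17)
        auc = {s.subject_id: 1500.0 for s in cohort.subjects}
        records = simulate_ggt_events(cohort, DEFAULT_PD_TRUTH, auc, seed=18,
                                      config=cfg, uln=uln)
        for r in records:
            s = cohort.subject(r.subject_id)
            limit = uln.lookup(s.sex, s.age)
            assert (r.value > limit) == bool(r.elevated)
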