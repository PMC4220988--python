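"""Bootstrap, VPC and goodness-of-fit diagnostics."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from sklearn.base import BaseEstimator

from vpapkpd.dataset import Cohort, filter_early_ggt
from vpapkpd.pd_model import DEFAULT_PD_TRUTH, GGTElevationModel, build_pd_table
from vpapkpd.pk_model import (
    DEFAULT_PK_TRUTH,
    DEFAULT_PK_VARIANCE,
    PKVariance,
    PopulationPKModel,
)
from vpapkpd.synthetic import (
    generate_cohort,
    pd_cohort_config,
    pk_cohort_config,
    simulate_concentrations,
    simulate_ggt_events,
)
from vpapkpd.validation import bootstrap, gof_diagnostics, vpc


class MeanEstimator(BaseEstimator):
    """Trivial per-table estimator used to exercise the bootstrap machinery."""

    def fit(self, X, y=None):
        self.mean_ = float(X["y"].mean())
        self.n_subjects_ = X["subject_id"].nunique()
        self.subject_ids_ = sorted(X["subject_id"].str.split("_").str[-1].unique())
        self.converged_ = True
        return self

    def fitted_params(self):
        return {"mean": self.mean_}


def _table(values_by_subject):
    rows = []
    for sid, values in values_by_subject.items():
        for v in values:
            rows.append({"subject_id": sid, "y": v})
    return pd.DataFrame(rows)


class TestBootstrapMachinery:
    def test_single_replicate_gives_degenerate_interval(self):
        table = _table({"A": [1.0, 2.0], "B": [3.0]})
        res = bootstrap(table, MeanEstimator(), n=1, seed=0)
        assert res.n_successful == 1
        row = res.summary.loc["mean"]
        assert row["ci_low"] == row["median"] == row["ci_high"]

    def test_interval_shrinks_with_clone_multiplicity(self):
        """Resampling a population made of k copies of the same subjects
        concentrates the bootstrap distribution as k grows."""
        base = {"A": [0.0], "B": [2.0], "C": [4.0], "D": [6.0]}
        widths = []
        for k in (1, 8):
            table = _table({f"{sid}{j}": v for sid, v in base.items()
                            for j in range(k)})
            res = bootstrap(table, MeanEstimator(), n=60, seed=1)
            row = res.summary.loc["mean"]
            widths.append(row["ci_high"] - row["ci_low"])
        assert widths[1] < widths[0]

    def test_stratum_sizes_preserved(self):
        table = _table({"A": [1.0], "B": [2.0], "C": [3.0], "D": [4.0],
                        "E": [5.0], "F": [6.0]})
        strata = {"A": "x", "B": "x", "C": "x", "D": "y", "E": "y", "F": "y"}

        class CountingEstimator(MeanEstimator):
            seen = []

            def fit(self, X, y=None):
                originals = X["subject_id"].str.split("_").str[-1]
                CountingEstimator.seen.append(
                    originals.map(strata).value_counts().to_dict()
                )
                return super().fit(X)

        CountingEstimator.seen = []
        bootstrap(table, CountingEstimator(), n=10, strata=strata, seed=2)
        for counts in CountingEstimator.seen:
            assert counts == {"x": 3, "y": 3}

    def test_deterministic_under_seed(self):
        table = _table({"A": [1.0, 5.0], "B": [2.0], "C": [9.0]})
        r1 = bootstrap(table, MeanEstimator(), n=25, seed=7)
        r2 = bootstrap(table, MeanEstimator(), n=25, seed=7)
        pd.testing.assert_frame_equal(r1.estimates, r2.estimates)

    def test_unreliable_flag(self):
        class FailingEstimator(MeanEstimator):
            def fit(self, X, y=None):
                super().fit(X)
                self.converged_ = False
                return self

        table = _table({"A": [1.0], "B": [2.0]})
        res = bootstrap(table, FailingEstimator(), n=4, seed=3)
        assert res.n_successful == 0 and res.unreliable

    def test_cohort_resampling_keeps_records_with_subjects(self):
        cfg = dataclasses.replace(pk_cohort_config(), n_subjects=15)
        cohort = generate_cohort(cfg, 30)
        recs, _ = simulate_concentrations(cohort, DEFAULT_PK_TRUTH,
                                          DEFAULT_PK_VARIANCE, 31, cfg)
        full = Cohort(cohort.subjects, recs, [])
        from vpapkpd.validation import _resample_cohort

        rng = np.random.default_rng(0)
        sample = _resample_cohort(full, rng, None)
        assert sample.n_subjects == full.n_subjects
        by_original = {}
        for r in full.pk_records:
            by_original.setdefault(r.subject_id, 0)
            by_original[r.subject_id] += 1
        for s in sample.subjects:
            original = s.subject_id.split("_", 1)[1]
            n_here = sum(r.subject_id == s.subject_id for r in sample.pk_records)
            assert n_here == by_original.get(original, 0)


@pytest.fixture(scope="module")
def fitted_pd():
    cfg = dataclasses.replace(pd_cohort_config(), n_subjects=120)
    cohort = generate_cohort(cfg, 800)
    _, truth = simulate_concentrations(cohort, DEFAULT_PK_TRUTH,
                                       DEFAULT_PK_VARIANCE, 801, cfg)
    auc = {sid: v["auc"] for sid, v in truth.items()}
    ggt = filter_early_ggt(simulate_ggt_events(cohort, DEFAULT_PD_TRUTH, auc,
                                               802, cfg))
    table = build_pd_table(Cohort(cohort.subjects, [], ggt), auc)
    return table, GGTElevationModel().fit(table)


class TestVPC:
    def test_degenerate_outcomes_inside_zero_band(self, fitted_pd):
        table, model = fitted_pd
        dead = table.copy()
        dead["elevated"] = 0
        silent = GGTElevationModel(omega2_fixed=1e-8)
        silent.fit_ = None  # not used by vpc
        silent.omega2_ = 1e-8
        silent.base_ = -50.0
        silent.coefs_ = {"intellectual_disability": 0.0, "sod2_valval": 0.0}
        silent.slope_ = 0.0
        result = vpc(dead, silent, n_sim=100, seed=4)
        assert (result["observed"] == 0).all()
        assert (result["pi_low"] == 0).all() and (result["pi_high"] == 0).all()
        assert result["inside"].all()

    def test_bands_deterministic_and_ordered(self, fitted_pd):
        table, model = fitted_pd
        r1 = vpc(table, model, n_sim=150, seed=5,
                 strata=("intellectual_disability",))
        r2 = vpc(table, model, n_sim=150, seed=5,
                 strata=("intellectual_disability",))
        pd.testing.assert_frame_equal(r1, r2)
        assert (r1["pi_low"] <= r1["pi_high"]).all()
        assert r1["n_obs"].sum() == len(table)

    def test_stratification_matches_figure_layout(self, fitted_pd):
        """Panels stratified by pooled SOD2 group and by disability, on the
        young-subject usual-dose subset used for the published check."""
        table, model = fitted_pd
        result = vpc(table, model, n_sim=100, seed=6,
                     strata=("sod2_valval", "intellectual_disability"),
                     n_bins=2)
        assert set(result["stratum"].str.split("|").str[0]) <= {"0", "1"}


class TestGOF:
    def _noise_free_cohort(self):
        cfg = dataclasses.replace(pk_cohort_config(), n_subjects=12)
        cohort = generate_cohort(cfg, 900)
        novar = PKVariance(omega2={}, sigma2=0.0)
        recs, _ = simulate_concentrations(cohort, DEFAULT_PK_TRUTH, novar, 901, cfg)
        return Cohort(cohort.subjects, recs, [])

    def test_noise_free_data_give_null_residuals(self):
        cohort = self._noise_free_cohort()
        init = {"ka": DEFAULT_PK_TRUTH.ka, "cl": DEFAULT_PK_TRUTH.cl,
                "vd": DEFAULT_PK_TRUTH.vd, "cl:dose": 0.596, "vd:dose": 1.52,
                "cl:female": 0.917, "cl:CBZ": 1.19, "cl:CLB": 0.906,
                "cl:PB": 1.12, "cl:PHT": 1.43, "omega2": 1e-8, "sigma2": 1e-6}
        model = PopulationPKModel(init=init, maxiter=0).fit(cohort)
        gof = gof_diagnostics(cohort, model)
        np.testing.assert_allclose(gof["pred_population"], gof["observed"],
                                   rtol=1e-6)
        assert np.nanmax(np.abs(gof["cwres"])) < 0.05

    def test_cwres_standardised_on_model_true_data(self):
        cfg = dataclasses.replace(pk_cohort_config(), n_subjects=120)
        cohort = generate_cohort(cfg, 902)
        recs, _ = simulate_concentrations(cohort, DEFAULT_PK_TRUTH,
                                          DEFAULT_PK_VARIANCE, 903, cfg)
        data = Cohort(cohort.subjects, recs, [])
        model = PopulationPKModel().fit(data)
        gof = gof_diagnostics(data, model)
        assert abs(gof["cwres"].mean()) < 0.2
        assert 0.6 < gof["cwres"].std() < 1.4

    def test_individual_predictions_dominate_population(self):
        cfg = dataclasses.replace(pk_cohort_config(), n_subjects=60)
        cohort = generate_cohort(cfg, 904)
        recs, _ = simulate_concentrations(cohort, DEFAULT_PK_TRUTH,
                                          DEFAULT_PK_VARIANCE, 905, cfg)
        data = Cohort(cohort.subjects, recs, [])
        model = PopulationPKModel().fit(data)
        gof = gof_diagnostics(data, model)
        w = 1.0 / gof["pred_population"] ** 2  # proportional-error weights
        err_ind = float((w * (gof["observed"] - gof["pred_individual"]) ** 2).sum())
        err_pop = float((w * (gof["observed"] - gof["pred_population"]) ** 2).sum())
        assert err_ind <= err_pop
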