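"""Tests for occasion splitting and occasion-to-occasion forecasting."""

import dataclasses
import math

import numpy as np
import pytest

import vancoforecast as vf
from vancoforecast.bayes import FlattenSpec
from vancoforecast.forecaster import (
    ALL_SELECTIONS,
    BAYES_SELECTIONS,
    ForecastTask,
    run_forecast,
    select_samples,
    split_occasions,
)


def make_ledger(eta=(0.3, -0.1), n_doses=20, amount=150.0, prior=None, cov=None,
                occ_doses=(4, 12), sample_offsets=(2.0, 4.5, 5.5)):
    """Noise-free ledger: samples generated from the model itself."""
    prior = prior if prior is not None else vf.default_prior()
    cov = cov if cov is not None else vf.PatientCovariates(
        age_months=24.0, weight_kg=10.0, scr=0.34
    )
    doses = [vf.DosingEvent(i * 6.0, amount, 1.0, interval_hint=6.0)
             for i in range(n_doses)]
    ind = vf.IndividualPK.from_prior(prior, cov, eta)
    obs = []
    for k in occ_doses:
        for off in sample_offsets:
            t = k * 6.0 + off
            obs.append(
                vf.ObservationRecord(t, float(vf.concentration(ind, doses, t)))
            )
    return vf.PatientLedger("T1", doses, obs, cov), ind


class TestSplitOccasions:
    def test_groups_by_covering_interval(self):
        doses = [vf.DosingEvent(i * 6.0, 150.0, 1.0) for i in range(12)]
        obs = [
            vf.ObservationRecord(5 * 6.0 + 2.0, 20.0),
            vf.ObservationRecord(5 * 6.0 + 5.5, 8.0),
            vf.ObservationRecord(9 * 6.0 + 2.0, 18.0),
        ]
        occs = split_occasions(obs, doses)
        assert [len(o.obs) for o in occs] == [2, 1]
        assert [o.dose_index for o in occs] == [5, 9]

    def test_empty_observation_set(self):
        doses = [vf.DosingEvent(0.0, 150.0, 1.0)]
        assert split_occasions([], doses) == []

    def test_half_open_interval_assignment(self):
        doses = [vf.DosingEvent(0.0, 150.0, 1.0), vf.DosingEvent(6.0, 150.0, 1.0)]
        eps = 1e-9
        occs = split_occasions([vf.ObservationRecord(6.0 - eps, 5.0),
                                vf.ObservationRecord(6.0, 5.0)], doses)
        assert [o.dose_index for o in occs] == [0, 1]

    def test_uncovered_observation_rejected(self):
        doses = [vf.DosingEvent(6.0, 150.0, 1.0)]
        with pytest.raises(ValueError, match="not covered"):
            split_occasions([vf.ObservationRecord(2.0, 5.0)], doses)

    def test_window_labels_assigned(self):
        doses = [vf.DosingEvent(0.0, 150.0, 1.0), vf.DosingEvent(6.0, 150.0, 1.0)]
        occs = split_occasions([vf.ObservationRecord(2.5, 5.0),
                                vf.ObservationRecord(5.5, 2.0)], doses)
        assert [o.window for o in occs[0].obs] == ["peak", "trough"]


class TestSelectSamples:
    def test_selections(self):
        doses = [vf.DosingEvent(0.0, 150.0, 1.0), vf.DosingEvent(6.0, 150.0, 1.0)]
        occ = split_occasions(
            [vf.ObservationRecord(2.5, 5.0), vf.ObservationRecord(4.0, 3.0),
             vf.ObservationRecord(5.5, 2.0)], doses
        )[0]
        assert [o.window for o in select_samples(occ, "peak+trough")] == ["peak", "trough"]
        assert len(select_samples(occ, "two_post_dose")) == 2
        assert select_samples(occ, "mid")[0].window == "mid"

    def test_absent_sample_yields_none(self):
        doses = [vf.DosingEvent(0.0, 150.0, 1.0), vf.DosingEvent(6.0, 150.0, 1.0)]
        occ = split_occasions([vf.ObservationRecord(2.5, 5.0)], doses)[0]
        assert select_samples(occ, "trough") is None
        assert select_samples(occ, "two_post_dose") is None


class TestRunForecast:
    def test_noise_free_self_consistency(self):
        # zero residual error, no IOV, unchanged covariates: the generating
        # model is self-consistent, so a near-noiseless analysis prior makes
        # the two-sample Bayes forecast reproduce the observation
        prior = vf.PopPrior(sigma=vf.ResidualModel(prop_cv=1e-4))
        ledger, _ = make_ledger(prior=prior)
        task = ForecastTask("T1", 0, 1, "conventional", "peak+trough")
        pairs = run_forecast(task, ledger, prior)
        assert len(pairs) == 3
        for p in pairs:
            assert p.c_forecast == pytest.approx(p.c_observed, rel=1e-5)

    def test_dose_change_in_lead_time_honored(self):
        prior = vf.PopPrior(sigma=vf.ResidualModel(prop_cv=1e-4))
        ledger, ind = make_ledger(prior=prior)
        # double every dose from dose 8 onward and regenerate target obs
        doses2 = [
            d if d.start_time < 48.0 else dataclasses.replace(d, amount=2 * d.amount)
            for d in ledger.doses
        ]
        obs2 = [o for o in ledger.obs if o.time < 48.0] + [
            vf.ObservationRecord(o.time, float(vf.concentration(ind, doses2, o.time)))
            for o in ledger.obs
            if o.time >= 48.0
        ]
        ledger2 = vf.PatientLedger("T1", doses2, obs2, ledger.covariates)
        task = ForecastTask("T1", 0, 1, "conventional", "peak+trough")
        for p in run_forecast(task, ledger2, prior):
            assert p.c_forecast == pytest.approx(p.c_observed, rel=1e-5)

    def test_first_order_equals_pure_data_bayes_on_noise_free_data(self):
        prior = vf.default_prior()
        ledger, ind = make_ledger(prior=prior, occ_doses=(8, 14),
                                  sample_offsets=(2.0, 5.5))
        fo = run_forecast(
            ForecastTask("T1", 0, 1, "first_order", "two_post_dose"), ledger, prior
        )
        bayes = run_forecast(
            ForecastTask("T1", 0, 1, "weighted", "peak+trough"), ledger, prior,
            weight_strategy=vf.FixedWeight(1.0),
        )
        for a, b in zip(fo, bayes):
            assert a.c_forecast == pytest.approx(b.c_forecast, rel=1e-3)
            assert a.c_forecast == pytest.approx(a.c_observed, rel=1e-3)

    def test_missing_sample_type_skips_with_no_pairs(self):
        prior = vf.default_prior()
        ledger, _ = make_ledger(sample_offsets=(2.0, 5.5))  # no mid samples
        task = ForecastTask("T1", 0, 1, "conventional", "mid")
        assert run_forecast(task, ledger, prior) == []

    def test_lead_time_positive_and_in_days(self):
        prior = vf.default_prior()
        ledger, _ = make_ledger(occ_doses=(4, 12))
        pairs = run_forecast(
            ForecastTask("T1", 0, 1, "conventional", "peak+trough"), ledger, prior
        )
        # last used sample 4*6+5.5=29.5 h; first target 12*6+2=74 h
        assert pairs[0].lead_time_days == pytest.approx((74.0 - 29.5) / 24.0)

    def test_conventional_eta_between_prior_and_pure_data(self):
        # single observation: the shrinkage path is a line in eta space
        prior = vf.default_prior()
        ledger, _ = make_ledger(eta=(0.5, 0.0), sample_offsets=(5.5,))
        occs = split_occasions(ledger.obs, ledger.doses)
        sel = occs[0].obs
        conv = vf.map_estimate(sel, ledger.doses, prior, ledger.covariates)
        pure = vf.map_estimate(
            sel, ledger.doses, prior, ledger.covariates,
            FlattenSpec("weighted", weight=1.0),
        )
        for k in range(2):
            lo, hi = sorted((0.0, pure.eta[k]))
            assert lo - 1e-6 <= conv.eta[k] <= hi + 1e-6


class TestRunMatrix:
    def test_every_design_cell_exercised(self):
        from vancoforecast.cohort import CohortSpec, generate_cohort

        spec = dataclasses.replace(CohortSpec(), n_patients=3, seed=11, n_occasions=3)
        ledgers, _ = generate_cohort(spec)
        prior = vf.default_prior()
        tab = vf.run_matrix(ledgers, prior)
        cells = set(map(tuple, tab[["method", "samples_used"]].drop_duplicates().values))
        methods = ["conventional", "weighted"] + [f"flat_{c:g}" for c in vf.FLAT_COEF_GRID]
        expected = {(m, s) for m in methods for s in BAYES_SELECTIONS}
        expected |= {("first_order", "two_post_dose")}
        assert cells == expected
        # methods sharing sample availability have identical pair counts
        counts = tab.groupby(["method", "samples_used"]).size()
        bayes_counts = {
            s: {counts[(m, s)] for m in methods} for s in BAYES_SELECTIONS
        }
        assert all(len(v) == 1 for v in bayes_counts.values())
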