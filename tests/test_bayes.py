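"""Tests for the MAP objectives, estimator and weight-selection strategies."""

import math

import numpy as np
import pytest

import vancoforecast as vf
from vancoforecast.bayes import FlattenSpec, map_estimate, objective, sweep_flat_coefs


def grid_objective(etas, obs, doses, prior, cov, w_data, w_prior):
    """Independent objective evaluation, vectorized over an eta grid.

    Re-derives the infusion superposition and the two objective terms directly
    (no calls into the estimation path).
    """
    etas = np.asarray(etas, dtype=float)  # (n, 2)
    om2 = np.array([prior.omega2["cl"], prior.omega2["v"]])
    pen = np.sum(etas**2 / om2, axis=1)
    data = np.zeros(len(etas))
    for o in obs:
        clp, vp = prior.typical(cov, o.time)
        cl = clp * np.exp(etas[:, 0])
        ke = cl / (vp * np.exp(etas[:, 1]))
        f = np.zeros(len(etas))
        for d in doses:
            dt = o.time - d.start_time
            if dt <= 0:
                continue
            if dt <= d.infusion_duration:
                f += d.rate / cl * (1.0 - np.exp(-ke * dt))
            else:
                f += (
                    d.rate
                    / cl
                    * (1.0 - np.exp(-ke * d.infusion_duration))
                    * np.exp(-ke * (dt - d.infusion_duration))
                )
        sd = math.hypot(prior.sigma.prop_cv * o.conc, prior.sigma.add_sd)
        data += ((o.conc - f) / sd) ** 2
    return w_data * data + w_prior * pen


def toy_problem(rng, prior, n_obs=2, n_doses=3):
    cov = vf.PatientCovariates(
        age_months=float(rng.uniform(6, 120)),
        weight_kg=float(rng.uniform(4, 30)),
        scr=float(rng.uniform(0.15, 0.9)),
    )
    doses, t0 = [], 0.0
    for _ in range(n_doses):
        doses.append(vf.DosingEvent(t0, float(rng.uniform(50, 300)), 1.0))
        t0 += 6.0
    eta_true = rng.normal(0.0, 0.35, size=2)
    ind = vf.IndividualPK.from_prior(prior, cov, eta_true)
    obs = []
    for _ in range(n_obs):
        t = float(rng.uniform(1.5, t0))
        c = float(vf.concentration(ind, doses, t)) * float(
            np.exp(rng.normal(0.0, 0.1))
        )
        obs.append(vf.ObservationRecord(time=t, conc=c))
    return cov, doses, obs, eta_true


class TestFlattenSpec:
    def test_weight_zero_rejected(self):
        with pytest.raises(ValueError):
            FlattenSpec("weighted", weight=0.0)

    def test_flat_coef_required(self):
        with pytest.raises(ValueError):
            FlattenSpec("flattened")

    @pytest.mark.parametrize(
        "spec,expected",
        [
            (FlattenSpec("conventional"), (1.0, 1.0)),
            (FlattenSpec("flattened", flat_coef=0.2), (1.0, 0.2)),
            (FlattenSpec("weighted", weight=0.8), (0.8, 0.2)),
        ],
    )
    def test_term_weights(self, spec, expected):
        assert spec.weights() == pytest.approx(expected)


class TestObjective:
    def test_zero_at_population_truth(self, prior, cov):
        doses = [vf.DosingEvent(0.0, 150.0, 1.0)]
        ind = vf.IndividualPK.from_prior(prior, cov)
        obs = [
            vf.ObservationRecord(t, float(vf.concentration(ind, doses, t)))
            for t in (2.0, 5.5)
        ]
        for spec in (
            FlattenSpec("conventional"),
            FlattenSpec("flattened", flat_coef=0.125),
            FlattenSpec("weighted", weight=0.7),
        ):
            assert objective([0, 0], obs, doses, prior, cov, spec) == pytest.approx(
                0.0, abs=1e-18
            )

    def test_variant_algebra(self, prior):
        rng = np.random.default_rng(5)
        for _ in range(20):
            cov, doses, obs, _ = toy_problem(rng, prior)
            eta = rng.uniform(-2, 2, size=2)
            conv = objective(eta, obs, doses, prior, cov, FlattenSpec("conventional"))
            half = objective(
                eta, obs, doses, prior, cov, FlattenSpec("weighted", weight=0.5)
            )
            assert half == pytest.approx(0.5 * conv, rel=1e-12)
            f = float(rng.uniform(0.005, 0.6))
            flat = objective(
                eta, obs, doses, prior, cov, FlattenSpec("flattened", flat_coef=f)
            )
            wtd = objective(
                eta, obs, doses, prior, cov,
                FlattenSpec("weighted", weight=1.0 / (1.0 + f)),
            )
            assert flat == pytest.approx((1.0 + f) * wtd, rel=1e-12)

    def test_theta_space_penalty_literal(self, flat_prior, cov):
        prior_theta = vf.PopPrior(
            model="constant", theta={"cl": 2.5, "v": 6.36}, penalty_space="theta"
        )
        doses = [vf.DosingEvent(0.0, 150.0, 1.0)]
        ind = vf.IndividualPK(cl=2.5, v=6.36)
        obs = [vf.ObservationRecord(2.0, float(vf.concentration(ind, doses, 2.0)))]
        eta = np.array([0.4, -0.3])
        got = objective(eta, obs, doses, prior_theta, cov)
        om2 = prior_theta.omega2_vector()
        expected_pen = float(np.sum((1.0 - np.exp(eta)) ** 2 / om2))
        data = got - expected_pen
        eta_space = objective(eta, obs, doses, flat_prior, cov) - float(
            np.sum(eta**2 / om2)
        )
        assert data == pytest.approx(eta_space, rel=1e-9)  # data term unchanged

    def test_zero_omega_rejected(self, cov):
        prior = vf.PopPrior(model="constant", theta={"cl": 2.5, "v": 6.36},
                            omega2={"cl": 0.0, "v": 0.04})
        obs = [vf.ObservationRecord(2.0, 10.0)]
        with pytest.raises(ValueError, match="variance"):
            objective([0, 0], obs, [vf.DosingEvent(0.0, 150.0, 1.0)], prior, cov)


class TestMapEstimate:
    def test_matches_dense_grid_one_parameter(self, prior):
        rng = np.random.default_rng(21)
        for _ in range(5):
            cov, doses, obs, _ = toy_problem(rng, prior, n_obs=1)
            fit = map_estimate(obs, doses, prior, cov, free=("cl",))
            grid = np.linspace(-4.0, 4.0, 80001)
            vals = grid_objective(
                np.column_stack([grid, np.zeros_like(grid)]),
                obs, doses, prior, cov, 1.0, 1.0,
            )
            eta_star = grid[int(np.argmin(vals))]
            assert fit.eta[0] == pytest.approx(eta_star, abs=3e-4)

    def test_penalty_dominated_limit(self, prior, cov):
        doses = [vf.DosingEvent(0.0, 150.0, 1.0)]
        ind = vf.IndividualPK.from_prior(prior, cov, eta=(0.8, -0.5))
        obs = [vf.ObservationRecord(2.0, float(vf.concentration(ind, doses, 2.0)))]
        fit = map_estimate(
            obs, doses, prior, cov, FlattenSpec("flattened", flat_coef=1e6)
        )
        assert np.linalg.norm(fit.eta) < 1e-3
        clp, vp = prior.typical(cov, 2.0)
        assert fit.ind.cl == pytest.approx(clp, rel=1e-3)

    def test_pure_data_recovers_truth_from_two_exact_obs(self, prior, cov):
        doses = [vf.DosingEvent(i * 6.0, 150.0, 1.0) for i in range(5)]
        ind = vf.IndividualPK.from_prior(prior, cov, eta=(0.45, -0.3))
        obs = [
            vf.ObservationRecord(t, float(vf.concentration(ind, doses, t)))
            for t in (26.0, 29.5)
        ]
        fit = map_estimate(obs, doses, prior, cov, FlattenSpec("weighted", weight=1.0))
        assert fit.ind.cl == pytest.approx(ind.cl, rel=1e-5)
        assert fit.ind.v == pytest.approx(ind.v, rel=1e-5)

    def test_objective_reassembles_from_terms(self, prior):
        rng = np.random.default_rng(3)
        cov, doses, obs, _ = toy_problem(rng, prior)
        spec = FlattenSpec("weighted", weight=0.3)
        fit = map_estimate(obs, doses, prior, cov, spec)
        w_data, w_prior = spec.weights()
        assert fit.objective_value == pytest.approx(
            w_data * fit.data_misfit + w_prior * fit.prior_penalty, abs=1e-10
        )
        assert fit.converged

    def test_shrinkage_monotone_over_coefficient_grid(self, prior):
        rng = np.random.default_rng(17)
        cov, doses, obs, _ = toy_problem(rng, prior)
        fits = sweep_flat_coefs(obs, doses, prior, cov)
        coefs = sorted(fits, reverse=True)  # 0.6 -> 0.005
        data = [fits[c].data_misfit for c in coefs]
        pen = [fits[c].prior_penalty for c in coefs]
        assert all(b <= a + 1e-9 for a, b in zip(data, data[1:]))
        assert all(b >= a - 1e-9 for a, b in zip(pen, pen[1:]))


class TestSelectWeight:
    def _occasions(self, prior, cov, doses, eta):
        ind = vf.IndividualPK.from_prior(prior, cov, eta)
        out = []
        for k in (3, 7):
            ts = (doses[k].start_time + 2.0, doses[k].start_time + 5.4)
            out.append(
                [
                    vf.ObservationRecord(t, float(vf.concentration(ind, doses, t)))
                    for t in ts
                ]
            )
        return out

    def test_fixed_half_weight_matches_conventional_argmin(self, prior, cov):
        doses = [vf.DosingEvent(i * 6.0, 150.0, 1.0, interval_hint=6.0) for i in range(10)]
        hist = self._occasions(prior, cov, doses, eta=(0.4, 0.1))
        w = vf.select_weight(hist, doses, prior, cov, vf.FixedWeight(0.5))
        conv = map_estimate(hist[-1], doses, prior, cov, FlattenSpec("conventional"))
        wtd = map_estimate(
            hist[-1], doses, prior, cov, FlattenSpec("weighted", weight=w)
        )
        np.testing.assert_allclose(wtd.eta, conv.eta, atol=1e-6)

    def test_outlier_patient_gets_data_weighted(self, prior, cov):
        doses = [vf.DosingEvent(i * 6.0, 150.0, 1.0, interval_hint=6.0) for i in range(10)]
        sd_cl = math.sqrt(prior.omega2["cl"])
        hist = self._occasions(prior, cov, doses, eta=(-3 * sd_cl, 0.0))
        w = vf.select_weight(hist, doses, prior, cov, vf.RetrospectiveWeight())
        assert w > 0.5

    def test_prior_matching_patient_keeps_prior_weight(self, prior, cov):
        doses = [vf.DosingEvent(i * 6.0, 150.0, 1.0, interval_hint=6.0) for i in range(10)]
        hist = self._occasions(prior, cov, doses, eta=(0.0, 0.0))
        w = vf.select_weight(hist, doses, prior, cov, vf.RetrospectiveWeight())
        assert w <= 0.5

    def test_short_history_falls_back(self, prior, cov):
        doses = [vf.DosingEvent(0.0, 150.0, 1.0, interval_hint=6.0)]
        hist = [[vf.ObservationRecord(2.0, 12.0)]]
        assert vf.select_weight(hist, doses, prior, cov, vf.RetrospectiveWeight()) == 0.5
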