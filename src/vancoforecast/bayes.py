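"""MAP estimation of individual PK parameters with conventional, flattened and
weighted-flattened objectives.

All three variants are weighted sums of the same two terms,

    data(eta)    = sum_j (Cobs_j - f(theta(eta), t_j))^2 / sigma_j^2
    penalty(eta) = sum_k eta_k^2 / omega_k^2

with objective = w_data * data + w_prior * penalty and

    conventional:       (w_data, w_prior) = (1, 1)
    flattened:          (1, flat_coef)          flat_coef > 0
    weighted-flattened: (weight, 1 - weight)    0 < weight <= 1

so the flattened objective with coefficient f is a positive multiple
((1+f) times) of the weighted objective at weight 1/(1+f): the two share their
minimizer.  Smaller flat_coef (equivalently larger weight) trusts the observed
concentrations more and the population prior less.

Optimization runs in eta (log) space over a bounded box with multiple starts;
results carry the split objective terms and a convergence flag.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .pk import (
    DosingEvent,
    IndividualPK,
    ObservationRecord,
    PatientCovariates,
    PopPrior,
    concentration_cv,
)

__all__ = [
    "FlattenSpec",
    "MapFit",
    "objective",
    "map_estimate",
    "sweep_flat_coefs",
    "FixedWeight",
    "RetrospectiveWeight",
    "select_weight",
    "FLAT_COEF_GRID",
    "WEIGHT_CANDIDATE_COEFS",
]

logger = logging.getLogger(__name__)

#: Flattened-prior coefficients examined by the study protocol.
FLAT_COEF_GRID = (0.005, 0.02, 0.125, 0.2, 0.3, 0.6)

#: Candidate coefficients for the retrospective weight selector; mapped to
#: weights via w = 1/(1+f), so f=1 is the conventional balance (w = 0.5).
WEIGHT_CANDIDATE_COEFS = (0.005, 0.02, 0.125, 0.2, 0.3, 0.5, 0.6, 0.8, 1.0)

ETA_BOUND = 6.0


@dataclass(frozen=True)
class FlattenSpec:
    """Objective variant and its coefficient."""

    variant: str = "conventional"
    flat_coef: float | None = None
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.variant not in ("conventional", "flattened", "weighted"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "flattened":
            if self.flat_coef is None or not self.flat_coef > 0:
                raise ValueError("flattened variant requires flat_coef > 0")
        if self.variant == "weighted":
            if self.weight is None or not (0.0 < self.weight <= 1.0):
                raise ValueError(
                    "weighted variant requires 0 < weight <= 1 "
                    "(weight=0 would erase the data term)"
                )

    def weights(self) -> tuple[float, float]:
        """(w_data, w_prior) for this variant."""
        if self.variant == "conventional":
            return 1.0, 1.0
        if self.variant == "flattened":
            return 1.0, float(self.flat_coef)
        return float(self.weight), 1.0 - float(self.weight)

    def label(self) -> str:
        if self.variant == "flattened":
            return f"flat_{self.flat_coef:g}"
        return self.variant


@dataclass
class MapFit:
    """A MAP fit: the individual, the split objective and a convergence flag."""

    ind: IndividualPK
    eta: np.ndarray
    objective_value: float
    data_misfit: float
    prior_penalty: float
    converged: bool
    n_obs_used: int
    spec: FlattenSpec


def _check_prior(prior: PopPrior) -> np.ndarray:
    om2 = prior.omega2_vector()
    if np.any(om2 <= 0):
        raise ValueError("between-subject variances must be > 0 for MAP estimation")
    return om2


class _ObjectiveContext:
    """Precomputed quantities for fast repeated evaluation of one fit's objective.

    The residual sd sigma_j is evaluated at the observed concentration, giving
    fixed (eta-independent) weights: the printed two-term objective carries no
    log-sigma likelihood term, so prediction-dependent weights would reward
    overprediction.
    """

    def __init__(self, obs, doses, prior, cov):
        if not obs:
            raise ValueError("MAP estimation needs at least one observation")
        if prior.sigma.sd(1.0) <= 0:
            raise ValueError("residual-error model is degenerate (sigma = 0)")
        self.om2 = _check_prior(prior)
        self.penalty_space = prior.penalty_space
        self.obs_times = np.array([o.time for o in obs], dtype=float)
        self.obs_conc = np.array([o.conc for o in obs], dtype=float)
        self.typicals = np.array(
            [prior.typical(cov, t) for t in self.obs_times], dtype=float
        )
        self.sd = np.array([prior.sigma.sd(c) for c in self.obs_conc])
        if np.any(self.sd <= 0):
            j = int(np.argmax(self.sd <= 0))
            raise ValueError(
                f"residual sd is zero for the observation at t={self.obs_times[j]} h"
            )
        # per-observation dose terms flattened over all (obs, dose) pairs and
        # split by infusion phase at the obs time; summed back per obs with
        # bincount, so one objective evaluation is a handful of vector ops
        starts = np.array([d.start_time for d in doses], dtype=float)
        durs = np.array([d.infusion_duration for d in doses], dtype=float)
        rates = np.array([d.rate for d in doses], dtype=float)
        m = len(self.obs_times)
        d_idx, d_r, d_dt = [], [], []
        a_idx, a_r, a_dur, a_tail = [], [], [], []
        for j, t in enumerate(self.obs_times):
            dt = t - starts
            during = (dt > 0) & (dt <= durs)
            after = dt > durs
            d_idx.extend([j] * int(during.sum()))
            d_r.extend(rates[during]); d_dt.extend(dt[during])
            a_idx.extend([j] * int(after.sum()))
            a_r.extend(rates[after]); a_dur.extend(durs[after])
            a_tail.extend(dt[after] - durs[after])
        self._m = m
        self._d = (np.array(d_idx, dtype=int), np.array(d_r), np.array(d_dt))
        self._a = (
            np.array(a_idx, dtype=int), np.array(a_r),
            np.array(a_dur), np.array(a_tail),
        )

    def predict_grad(self, eta) -> tuple[np.ndarray, np.ndarray]:
        """Predictions f_j and the Jacobian df_j/deta (shape (m, 2)).

        Writing f = S(ke)/cl with S the rate-weighted superposition sum,
        df/deta_v = -S'(ke)*ke/cl and df/deta_cl = -f - df/deta_v.
        """
        e0, e1 = math.exp(eta[0]), math.exp(eta[1])
        clp = self.typicals[:, 0] * e0
        vp = self.typicals[:, 1] * e1
        ke = clp / vp
        m = self._m
        s = np.zeros(m)  # S(ke)/cl per obs
        sp = np.zeros(m)  # S'(ke)*ke/cl per obs
        d_idx, d_r, d_dt = self._d
        if d_idx.size:
            ex = np.exp(-ke[d_idx] * d_dt)
            s += np.bincount(d_idx, d_r * (1.0 - ex), minlength=m) / clp
            sp += np.bincount(d_idx, d_r * d_dt * ex * ke[d_idx], minlength=m) / clp
        a_idx, a_r, a_dur, a_tail = self._a
        if a_idx.size:
            ket = ke[a_idx]
            exT = np.exp(-ket * a_dur)
            exq = np.exp(-ket * a_tail)
            s += np.bincount(a_idx, a_r * (1.0 - exT) * exq, minlength=m) / clp
            sp += (
                np.bincount(
                    a_idx,
                    a_r * exq * (a_dur * exT - a_tail * (1.0 - exT)) * ket,
                    minlength=m,
                )
                / clp
            )
        jac = np.empty((m, 2))
        jac[:, 1] = -sp
        jac[:, 0] = -s + sp
        return s, jac

    def predict(self, eta) -> np.ndarray:
        return self.predict_grad(eta)[0]

    def parts(self, eta) -> tuple[float, float]:
        f = self.predict(eta)
        data = float(np.sum(((self.obs_conc - f) / self.sd) ** 2))
        e = np.asarray(eta, dtype=float)
        if self.penalty_space == "eta":
            pen = float(np.sum(e**2 / self.om2))
        else:  # literal typical-value deviation, omega^2 read as squared CV
            pen = float(np.sum((1.0 - np.exp(e)) ** 2 / self.om2))
        return data, pen

    def parts_grad(self, eta):
        """(data, penalty, d data/deta, d penalty/deta)."""
        f, jac = self.predict_grad(eta)
        resid = (self.obs_conc - f) / self.sd**2
        data = float(np.sum((self.obs_conc - f) ** 2 / self.sd**2))
        g_data = -2.0 * resid @ jac
        e = np.asarray(eta, dtype=float)
        if self.penalty_space == "eta":
            pen = float(np.sum(e**2 / self.om2))
            g_pen = 2.0 * e / self.om2
        else:
            ee = np.exp(e)
            pen = float(np.sum((1.0 - ee) ** 2 / self.om2))
            g_pen = -2.0 * (1.0 - ee) * ee / self.om2
        return data, pen, g_data, g_pen


def objective(
    eta: Sequence[float],
    obs: Sequence[ObservationRecord],
    doses: Sequence[DosingEvent],
    prior: PopPrior,
    cov: PatientCovariates,
    spec: FlattenSpec = FlattenSpec(),
) -> float:
    """Evaluate the MAP objective at ``eta`` (pure, deterministic)."""
    ctx = _ObjectiveContext(obs, doses, prior, cov)
    data, pen = ctx.parts(np.asarray(eta, dtype=float))
    w_data, w_prior = spec.weights()
    return w_data * data + w_prior * pen


def map_estimate(
    obs: Sequence[ObservationRecord],
    doses: Sequence[DosingEvent],
    prior: PopPrior,
    cov: PatientCovariates,
    spec: FlattenSpec = FlattenSpec(),
    free: tuple[str, ...] = ("cl", "v"),
    extra_starts: Sequence[Sequence[float]] = (),
    t_ref: float | None = None,
) -> MapFit:
    """Minimize the MAP objective over eta (bounded multi-start quasi-Newton).

    Starts are eta=0 and +/-1 prior SD along each free axis (plus any
    ``extra_starts``).  Among starts whose optima tie within tolerance the
    smallest ||eta|| wins (maximal shrinkage).  A fit that converges from no
    start is returned flagged ``converged=False`` with the best candidate.

    ``free`` restricts optimization to a parameter subset (fixing the other
    eta components at 0), used for reduced toy problems; ``t_ref`` sets the
    clock time at which the reported IndividualPK's typical values are taken
    (default: first observation time).
    """
    ctx = _ObjectiveContext(obs, doses, prior, cov)
    om2 = ctx.om2
    w_data, w_prior = spec.weights()
    free_idx = [i for i, p in enumerate(PopPrior.PARAMS) if p in free]
    if not free_idx:
        raise ValueError("at least one parameter must be free")

    def fun(x: np.ndarray) -> tuple[float, np.ndarray]:
        eta = np.zeros(2)
        eta[free_idx] = x
        data, pen, g_data, g_pen = ctx.parts_grad(eta)
        grad = w_data * g_data + w_prior * g_pen
        return w_data * data + w_prior * pen, grad[free_idx]

    sds = np.sqrt(om2)
    starts = [np.zeros(len(free_idx))]
    for axis in range(len(free_idx)):
        for sign in (1.0, -1.0):
            x0 = np.zeros(len(free_idx))
            x0[axis] = sign * sds[free_idx[axis]]
            starts.append(x0)
    for s in extra_starts:
        starts.append(np.asarray(s, dtype=float)[free_idx] if len(s) == 2 else np.asarray(s, dtype=float))

    bounds = [(-ETA_BOUND, ETA_BOUND)] * len(free_idx)
    candidates = []
    for x0 in starts:
        res = minimize(
            fun,
            np.clip(x0, -ETA_BOUND, ETA_BOUND),
            method="L-BFGS-B",
            jac=True,
            bounds=bounds,
            options={"ftol": 1e-14, "gtol": 1e-10, "maxiter": 500},
        )
        candidates.append(res)
    best_val = min(r.fun for r in candidates)
    tol = 1e-8 * max(1.0, abs(best_val))
    tied = [r for r in candidates if r.fun <= best_val + tol]
    res = min(tied, key=lambda r: float(np.linalg.norm(r.x)))
    converged = any(r.success for r in tied)
    if not converged:
        logger.warning("MAP estimation did not converge from any start; best candidate kept")

    eta = np.zeros(2)
    eta[free_idx] = res.x
    data, pen = ctx.parts(eta)
    tref = float(ctx.obs_times[0]) if t_ref is None else t_ref
    ind = IndividualPK.from_prior(prior, cov, eta, t=tref)
    return MapFit(
        ind=ind,
        eta=eta,
        objective_value=w_data * data + w_prior * pen,
        data_misfit=data,
        prior_penalty=pen,
        converged=converged,
        n_obs_used=len(obs),
        spec=spec,
    )


def sweep_flat_coefs(
    obs,
    doses,
    prior,
    cov,
    coefs: Sequence[float] = FLAT_COEF_GRID,
    **kwargs,
) -> dict[float, MapFit]:
    """MAP fits across a flat_coef grid, warm-starting each fit at its neighbors'."""
    fits: dict[float, MapFit] = {}
    warm: list[np.ndarray] = []
    for f in sorted(coefs, reverse=True):
        fit = map_estimate(
            obs, doses, prior, cov, FlattenSpec("flattened", flat_coef=f),
            extra_starts=warm, **kwargs,
        )
        fits[f] = fit
        warm = [fit.eta]
    return fits


@dataclass(frozen=True)
class FixedWeight:
    """Constant weight; the default 0.5 reproduces the conventional objective."""

    weight: float = 0.5

    def select(self, history, doses, prior, cov) -> float:
        return self.weight


@dataclass(frozen=True)
class RetrospectiveWeight:
    """Pick the candidate weight that would have forecast the last occasion best.

    With at least two prior occasions, each candidate weight w = 1/(1+f) is
    fitted to occasion i-2's observations and scored by the squared error of
    forecasting occasion i-1's observations; the best-scoring candidate wins
    (ties broken toward the smallest weight, i.e. closest to conventional).
    With fewer occasions the configured fallback is returned.
    """

    candidate_coefs: tuple[float, ...] = WEIGHT_CANDIDATE_COEFS
    fallback: float = 0.5

    def select(
        self,
        history: Sequence[Sequence[ObservationRecord]],
        doses: Sequence[DosingEvent],
        prior: PopPrior,
        cov: PatientCovariates,
    ) -> float:
        if not self.candidate_coefs:
            raise ValueError("candidate grid must be nonempty")
        usable = [occ for occ in history if occ]
        if len(usable) < 2:
            logger.info(
                "retrospective weight selection needs >= 2 prior occasions "
                "(got %d); falling back to %g", len(usable), self.fallback,
            )
            return self.fallback
        fit_obs, score_obs = usable[-2], usable[-1]
        weights = sorted({1.0 / (1.0 + f) for f in self.candidate_coefs})
        best_w, best_sse = None, math.inf
        for w in weights:  # ascending: ties keep the smallest weight
            fit = map_estimate(
                fit_obs, doses, prior, cov, FlattenSpec("weighted", weight=w)
            )
            sse = 0.0
            for o in score_obs:
                clp, vp = prior.typical(cov, o.time)
                pred = concentration_cv(
                    clp * math.exp(fit.eta[0]), vp * math.exp(fit.eta[1]), doses, o.time
                )
                sse += (pred - o.conc) ** 2
            if sse < best_sse - 1e-12:
                best_w, best_sse = w, sse
        return float(best_w)


def select_weight(
    history,
    doses,
    prior,
    cov,
    strategy: FixedWeight | RetrospectiveWeight | None = None,
) -> float:
    """Strategy interface for the per-occasion weighted-flattened coefficient."""
    strategy = strategy if strategy is not None else FixedWeight()
    w = strategy.select(history, doses, prior, cov)
    if not (0.0 < w <= 1.0):
        raise ValueError(f"selected weight must lie in (0, 1], got {w}")
    return w
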