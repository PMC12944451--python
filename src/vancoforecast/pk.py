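"""One-compartment intermittent-IV-infusion concentration engine and population prior.

The pharmacokinetic model is the standard one-compartment model with zero-order
(constant-rate) infusion input and first-order elimination.  For a single
infusion of amount ``D`` (mg) over duration ``T`` (h) starting at time ``s``,
with clearance ``CL`` (L/h), volume ``V`` (L) and ``ke = CL/V`` (1/h), the
concentration is

    C(t) = 0                                          for t <= s
    C(t) = (R/CL) (1 - exp(-ke (t-s)))                for s < t <= s+T
    C(t) = (R/CL) (1 - exp(-ke T)) exp(-ke (t-s-T))   for t > s+T

with infusion rate ``R = D/T``.  Multiple doses superpose linearly.

The population prior couples typical parameter values (covariate functions of
weight, serum creatinine and age), log-normal between-subject variability
(variances omega^2 per parameter) and a residual-error model giving the
standard deviation sigma_j for an observation with model prediction f.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DosingEvent",
    "ObservationRecord",
    "StepSeries",
    "PatientCovariates",
    "ResidualModel",
    "PopPrior",
    "IndividualPK",
    "typical_params",
    "concentration",
    "concentration_cv",
    "steady_state_auc24",
    "classify_sample",
    "schwartz_egfr",
    "PEAK_WINDOW_H",
    "TROUGH_WINDOW_H",
]

#: Peak sampling window, hours after the end of the infusion (inclusive).
PEAK_WINDOW_H = (1.0, 2.0)
#: Trough sampling window, hours before the next dose start (inclusive).
TROUGH_WINDOW_H = (0.5, 1.0)

#: Mean days per month used to convert an age in months to days.
DAYS_PER_MONTH = 30.4375


@dataclass(frozen=True)
class DosingEvent:
    """One intermittent IV infusion.

    Parameters
    ----------
    start_time : float
        Hours since the first dose (>= 0).
    amount : float
        Dose amount in mg (> 0).
    infusion_duration : float
        Infusion duration in hours (> 0); defaults to 1 h, the protocol value.
    interval_hint : float, optional
        Planned dosing interval tau in hours, used when no later dose exists.
    """

    start_time: float
    amount: float
    infusion_duration: float = 1.0
    interval_hint: float | None = None

    def __post_init__(self) -> None:
        if not self.amount > 0:
            raise ValueError(f"dose amount must be > 0, got {self.amount}")
        if not self.infusion_duration > 0:
            raise ValueError(
                f"infusion duration must be > 0, got {self.infusion_duration}"
            )
        if self.start_time < 0:
            raise ValueError(f"dose start_time must be >= 0, got {self.start_time}")

    @property
    def end_time(self) -> float:
        """Hours at which the infusion ends."""
        return self.start_time + self.infusion_duration

    @property
    def rate(self) -> float:
        """Infusion rate in mg/h."""
        return self.amount / self.infusion_duration


@dataclass(frozen=True)
class ObservationRecord:
    """A timed vancomycin concentration measurement.

    ``window`` is one of ``"peak" | "mid" | "trough"`` (or ``None`` when not yet
    classified); ``occasion`` is the chronological TDM-occasion index.
    """

    time: float
    conc: float
    window: str | None = None
    occasion: int | None = None

    def __post_init__(self) -> None:
        if not self.conc > 0:
            raise ValueError(f"observed concentration must be > 0, got {self.conc}")
        if self.time < 0:
            raise ValueError(f"observation time must be >= 0, got {self.time}")


class StepSeries:
    """Piecewise-constant, right-continuous time series defined from time 0.

    Used for serum creatinine, which is carried forward between laboratory
    measurements.
    """

    def __init__(self, times: Sequence[float], values: Sequence[float]):
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if times.size == 0 or times.size != values.size:
            raise ValueError("times and values must be equal-length and nonempty")
        if times[0] != 0.0:
            raise ValueError("a step series must be defined from time 0")
        if np.any(np.diff(times) <= 0):
            raise ValueError("step-series times must be strictly increasing")
        self.times = times
        self.values = values

    @classmethod
    def constant(cls, value: float) -> "StepSeries":
        return cls([0.0], [value])

    def at(self, t: float) -> float:
        if t < 0:
            raise ValueError(f"step series queried before time 0 (t={t})")
        idx = int(np.searchsorted(self.times, t, side="right")) - 1
        return float(self.values[idx])

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return (
            isinstance(other, StepSeries)
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.values, other.values)
        )


@dataclass
class PatientCovariates:
    """Covariates entering the typical-value model.

    ``scr`` may be a scalar (constant) or a :class:`StepSeries` in mg/dL.
    """

    age_months: float
    weight_kg: float
    scr: StepSeries | float
    egfr: float | None = None

    def __post_init__(self) -> None:
        if not self.weight_kg > 0:
            raise ValueError(f"weight must be > 0 kg, got {self.weight_kg}")
        if isinstance(self.scr, (int, float)):
            if not self.scr > 0:
                raise ValueError(f"serum creatinine must be > 0, got {self.scr}")
            self.scr = StepSeries.constant(float(self.scr))
        if np.any(self.scr.values <= 0):
            raise ValueError("serum creatinine series must be strictly positive")

    def scr_at(self, t: float) -> float:
        return self.scr.at(t)


@dataclass(frozen=True)
class ResidualModel:
    """Residual error: sd(f) = sqrt((prop_cv*f)^2 + add_sd^2) for prediction f."""

    prop_cv: float = 0.15
    add_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.prop_cv < 0 or self.add_sd < 0:
            raise ValueError("residual-error components must be >= 0")

    def sd(self, f: float) -> float:
        return math.hypot(self.prop_cv * f, self.add_sd)


# Default structural constants of the pediatric vancomycin typical-value model
# (Le et al. 2014): CL = cl_std * WT^wt_exp * (scr_ref/Scr)^scr_exp
#                        * (ln(age_days)/age_scale)^age_exp  [L/h], V = v_per_kg*WT [L].
LE2014_THETA = {
    "cl_std": 0.248,
    "wt_exp": 0.75,
    "scr_ref": 0.48,
    "scr_exp": 0.361,
    "age_scale": 7.8,
    "age_exp": 0.995,
    "v_per_kg": 0.636,
}

DEFAULT_OMEGA2 = {"cl": 0.09, "v": 0.04}


class PopPrior:
    """Population prior: typical-value model, between-subject variances, residual error.

    Parameters
    ----------
    model : {"le2014", "constant"}
        Covariate model for the typical values.  ``le2014`` is the pediatric
        vancomycin model (weight, serum creatinine, age); ``constant`` returns
        fixed ``theta["cl"]`` / ``theta["v"]`` regardless of covariates.
    theta : dict
        Structural constants (see :data:`LE2014_THETA` for the default keys).
    omega2 : dict
        Between-subject variances {"cl": w2_cl, "v": w2_v} of the log-normal
        random effects (>= 0; must be > 0 for MAP estimation).
    sigma : ResidualModel
        Residual-error model.
    iov2 : float
        Optional between-occasion variance, consumed only by the simulator.
    penalty_space : {"eta", "theta"}
        Where the MAP prior penalty is computed; "eta" (default) penalizes
        eta_k^2/omega_k^2, "theta" the literal squared typical-value deviation
        (1 - exp(eta_k))^2/omega_k^2 with omega^2 read as a squared CV.
    """

    PARAMS = ("cl", "v")

    def __init__(
        self,
        model: str = "le2014",
        theta: dict | None = None,
        omega2: dict | None = None,
        sigma: ResidualModel | None = None,
        iov2: float = 0.0,
        penalty_space: str = "eta",
    ):
        if model not in ("le2014", "constant"):
            raise ValueError(f"unknown typical-value model {model!r}")
        if penalty_space not in ("eta", "theta"):
            raise ValueError(f"penalty_space must be 'eta' or 'theta', got {penalty_space!r}")
        self.model = model
        if model == "le2014":
            self.theta = {**LE2014_THETA, **(theta or {})}
        else:
            self.theta = dict(theta or {})
            for key in ("cl", "v"):
                if key not in self.theta or not self.theta[key] > 0:
                    raise ValueError("constant model requires positive theta['cl'], theta['v']")
        self.omega2 = {**DEFAULT_OMEGA2, **(omega2 or {})}
        if any(w < 0 for w in self.omega2.values()):
            raise ValueError("between-subject variances must be >= 0")
        self.sigma = sigma if sigma is not None else ResidualModel()
        if iov2 < 0:
            raise ValueError("iov2 must be >= 0")
        self.iov2 = iov2
        self.penalty_space = penalty_space

    def typical(self, cov: PatientCovariates, t: float = 0.0) -> tuple[float, float]:
        """Typical (CL_pop [L/h], V_pop [L]) at clock time ``t`` (hours)."""
        if self.model == "constant":
            return float(self.theta["cl"]), float(self.theta["v"])
        th = self.theta
        scr = cov.scr_at(t)
        age_days = cov.age_months * DAYS_PER_MONTH
        if age_days <= 1.0:
            raise ValueError(
                f"age out of support for the le2014 model: {cov.age_months} months"
            )
        if scr <= 0:
            raise ValueError(f"serum creatinine out of support: {scr} mg/dL")
        cl = (
            th["cl_std"]
            * cov.weight_kg ** th["wt_exp"]
            * (th["scr_ref"] / scr) ** th["scr_exp"]
            * (math.log(age_days) / th["age_scale"]) ** th["age_exp"]
        )
        v = th["v_per_kg"] * cov.weight_kg
        return cl, v

    def omega2_vector(self) -> np.ndarray:
        return np.array([self.omega2[p] for p in self.PARAMS], dtype=float)


def typical_params(prior: PopPrior, cov: PatientCovariates, t: float = 0.0) -> dict:
    """Typical parameter values {"cl", "v"} at time ``t`` (pure function)."""
    cl, v = prior.typical(cov, t)
    return {"cl": cl, "v": v}


@dataclass(frozen=True)
class IndividualPK:
    """Individual parameters: cl = CL_pop*exp(eta_cl), v = V_pop*exp(eta_v)."""

    cl: float
    v: float
    eta: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.cl > 0:
            raise ValueError(f"cl must be > 0, got {self.cl}")
        if not self.v > 0:
            raise ValueError(f"v must be > 0, got {self.v}")

    @property
    def ke(self) -> float:
        """Elimination rate constant (1/h), identically cl/v."""
        return self.cl / self.v

    @classmethod
    def from_prior(
        cls,
        prior: PopPrior,
        cov: PatientCovariates,
        eta: Sequence[float] = (0.0, 0.0),
        t: float = 0.0,
    ) -> "IndividualPK":
        clp, vp = prior.typical(cov, t)
        e = tuple(float(x) for x in eta)
        return cls(cl=clp * math.exp(e[0]), v=vp * math.exp(e[1]), eta=e)


def _dose_arrays(doses: Sequence[DosingEvent]):
    starts = np.array([d.start_time for d in doses], dtype=float)
    durs = np.array([d.infusion_duration for d in doses], dtype=float)
    rates = np.array([d.rate for d in doses], dtype=float)
    return starts, durs, rates


def concentration_cv(
    cl: float, v: float, doses: Sequence[DosingEvent], t
) -> float | np.ndarray:
    """Superposition concentration (mg/L) at time(s) ``t`` for parameters (cl, v).

    Vectorized over ``t``; returns a scalar for scalar input.
    """
    if not cl > 0 or not v > 0:
        raise ValueError("cl and v must be > 0")
    tt = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.zeros_like(tt)
    if doses:
        ke = cl / v
        starts, durs, rates = _dose_arrays(doses)
        # (n_times, n_doses) broadcasting
        dt = tt[:, None] - starts[None, :]
        during = (dt > 0) & (dt <= durs[None, :])
        after = dt > durs[None, :]
        rcl = rates[None, :] / cl
        term = np.zeros_like(dt)
        term = np.where(during, rcl * (1.0 - np.exp(-ke * np.where(during, dt, 0.0))), term)
        tail = np.where(after, dt - durs[None, :], 0.0)
        term = np.where(
            after, rcl * (1.0 - np.exp(-ke * durs[None, :])) * np.exp(-ke * tail), term
        )
        out = term.sum(axis=1)
    return out if np.ndim(t) else float(out[0])


def concentration(ind: IndividualPK, doses: Sequence[DosingEvent], t) -> float | np.ndarray:
    """Concentration (mg/L) at time(s) ``t`` for an individual under ``doses``."""
    return concentration_cv(ind.cl, ind.v, doses, t)


def steady_state_auc24(ind: IndividualPK | float, daily_dose: float) -> float:
    """Steady-state 24-h AUC (mg*h/L) = daily dose / clearance."""
    cl = ind.cl if isinstance(ind, IndividualPK) else float(ind)
    if not daily_dose > 0:
        raise ValueError(f"daily dose must be > 0, got {daily_dose}")
    if not cl > 0:
        raise ValueError(f"clearance must be > 0, got {cl}")
    return daily_dose / cl


def classify_sample(sample_time: float, doses: Sequence[DosingEvent]) -> str:
    """Classify a sampling time as ``"peak"``, ``"mid"`` or ``"trough"``.

    Peak: within 1-2 h after the end of the covering dose's infusion.
    Trough: within 0.5-1 h before the next dose's start.
    Anything else is mid.  Peak takes precedence over trough when the windows
    overlap (short intervals).
    """
    if not doses:
        raise ValueError("no doses given")
    ordered = sorted(doses, key=lambda d: d.start_time)
    starts = [d.start_time for d in ordered]
    idx = int(np.searchsorted(starts, sample_time, side="right")) - 1
    if idx < 0:
        raise ValueError(
            f"sample at t={sample_time} h precedes the first dose (t={starts[0]} h)"
        )
    cover = ordered[idx]
    since_end = sample_time - cover.end_time
    if PEAK_WINDOW_H[0] <= since_end <= PEAK_WINDOW_H[1]:
        return "peak"
    if idx + 1 < len(ordered):
        next_start = ordered[idx + 1].start_time
    elif cover.interval_hint is not None:
        next_start = cover.start_time + cover.interval_hint
    else:
        next_start = None
    if next_start is not None:
        before_next = next_start - sample_time
        if TROUGH_WINDOW_H[0] <= before_next <= TROUGH_WINDOW_H[1]:
            return "trough"
    return "mid"


def schwartz_egfr(height_cm: float, scr_mgdl: float, k: float = 0.413) -> float:
    """Bedside Schwartz estimated GFR (mL/min/1.73 m^2) = k * height / Scr."""
    if not height_cm > 0 or not scr_mgdl > 0:
        raise ValueError("height and serum creatinine must be > 0")
    return k * height_cm / scr_mgdl
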