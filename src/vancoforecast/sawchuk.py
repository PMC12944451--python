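"""First-order (two-point) PK estimation: the Sawchuk-Zaske method.

Two post-infusion concentrations from the same dosing interval, assumed to be
at steady state, identify the terminal slope and hence:

    ke   = ln(c1/c2) / (t2 - t1)
    Cmax = c1 * exp(ke * (t1 - t_end))            (back-extrapolated to the
                                                   end of the infusion)
    CL   = D * (1 - exp(-ke*T)) / (T * Cmax * (1 - exp(-ke*tau)))
    Vd   = CL / ke

with dose amount D, infusion duration T and dosing interval tau.  Forecasting
then evaluates the full superposition model with (CL, Vd) over the actual
future dose schedule, so mid-course dose changes are honored exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .pk import DosingEvent, concentration_cv

__all__ = ["TwoPointFit", "fit_two_point", "forecast_first_order"]

logger = logging.getLogger(__name__)

#: Half-lives after which steady state is conventionally assumed.
STEADY_STATE_HALF_LIVES = 5.0


@dataclass(frozen=True)
class TwoPointFit:
    """Result of a two-point fit: ke (1/h), Cmax at infusion end (mg/L), Vd (L)."""

    ke: float
    cmax_end_infusion: float
    vd: float
    source_times: tuple[float, float]

    @property
    def cl(self) -> float:
        """Clearance (L/h) = ke * Vd."""
        return self.ke * self.vd


def fit_two_point(
    c1: float,
    t1: float,
    c2: float,
    t2: float,
    dose: DosingEvent,
    tau: float,
    back_extrapolate: bool = True,
) -> TwoPointFit:
    """Fit (ke, Cmax, Vd) from two post-infusion levels of one dosing interval.

    Parameters
    ----------
    c1, t1, c2, t2 : float
        The two concentrations (mg/L) at absolute times (h), ``t1 < t2``, both
        after the end of ``dose``'s infusion; requires ``c1 > c2 > 0``.
    dose : DosingEvent
        The dose whose interval contains both samples.
    tau : float
        The dosing interval (h) in force at the fitting occasion.
    back_extrapolate : bool
        If False, use ``c1`` directly as the end-of-infusion peak instead of
        back-extrapolating along the fitted slope.
    """
    if not (t1 < t2):
        raise ValueError(f"sample times must be ordered t1 < t2, got {t1}, {t2}")
    if not (c1 > 0 and c2 > 0):
        raise ValueError("concentrations must be > 0")
    if c1 <= c2:
        raise ValueError(
            f"non-decaying pair: c1={c1} <= c2={c2}; cannot estimate a positive ke"
        )
    t_end = dose.end_time
    if t1 < t_end or t2 < t_end:
        raise ValueError(
            f"both samples must follow the infusion end (t_end={t_end} h), got {t1}, {t2}"
        )
    if not tau > 0:
        raise ValueError(f"dosing interval must be > 0, got {tau}")

    ke = math.log(c1 / c2) / (t2 - t1)
    cmax = c1 * math.exp(ke * (t1 - t_end)) if back_extrapolate else c1
    bigt = dose.infusion_duration
    cl = (
        dose.amount
        * (1.0 - math.exp(-ke * bigt))
        / (bigt * cmax * (1.0 - math.exp(-ke * tau)))
    )
    vd = cl / ke

    elapsed = t2 - 0.0  # hours since first dose (times are on that clock)
    half_life = math.log(2.0) / ke
    if elapsed < STEADY_STATE_HALF_LIVES * half_life:
        logger.warning(
            "two-point fit at t=%.1f h precedes %g estimated half-lives "
            "(t1/2=%.1f h); steady-state assumption may be violated",
            t2,
            STEADY_STATE_HALF_LIVES,
            half_life,
        )
    return TwoPointFit(ke=ke, cmax_end_infusion=cmax, vd=vd, source_times=(t1, t2))


def forecast_first_order(
    fit: TwoPointFit, future_doses: Sequence[DosingEvent], times
) -> np.ndarray:
    """Forecast concentrations (mg/L) at ``times`` under the actual dose schedule."""
    if not future_doses:
        raise ValueError("cannot forecast without a dose schedule")
    return np.atleast_1d(concentration_cv(fit.cl, fit.vd, list(future_doses), times))
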