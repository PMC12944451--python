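"""Occasion-to-occasion forecasting: for every subsequent TDM occasion, fit on
the immediately preceding occasion and forecast each of the target occasion's
observations under the actual dose schedule.

A TDM occasion is the set of samples lying in one dosing interval; occasions
are indexed chronologically.  Fitting methods: the first-order two-point
method (Sawchuk-Zaske) and MAP-Bayesian estimation (conventional, flattened,
weighted-flattened) from one or two of the preceding occasion's samples.  For
Bayesian methods the typical values are re-evaluated with the serum creatinine
in force at each forecast time while the individual random effect eta is held
fixed; dose changes during the lead time apply exactly.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pk import (
    DosingEvent,
    ObservationRecord,
    PatientCovariates,
    PopPrior,
    classify_sample,
    concentration_cv,
)
from .bayes import (
    FLAT_COEF_GRID,
    FixedWeight,
    FlattenSpec,
    MapFit,
    RetrospectiveWeight,
    map_estimate,
)
from .sawchuk import fit_two_point, forecast_first_order

__all__ = [
    "PatientLedger",
    "Occasion",
    "ForecastTask",
    "ForecastPair",
    "split_occasions",
    "select_samples",
    "run_forecast",
    "run_matrix",
    "default_methods",
    "BAYES_SELECTIONS",
    "ALL_SELECTIONS",
]

logger = logging.getLogger(__name__)

#: Sample selections examined for the Bayesian methods (single levels and pairs).
BAYES_SELECTIONS = ("peak", "mid", "trough", "peak+mid", "peak+trough", "mid+trough")
ALL_SELECTIONS = BAYES_SELECTIONS + ("two_post_dose",)


@dataclass
class PatientLedger:
    """One patient's longitudinal record: doses, observations, covariates."""

    patient_id: str
    doses: list[DosingEvent]
    obs: list[ObservationRecord]
    covariates: PatientCovariates

    def __post_init__(self) -> None:
        self.doses = sorted(self.doses, key=lambda d: d.start_time)
        self.obs = sorted(self.obs, key=lambda o: o.time)


@dataclass
class Occasion:
    """All observations within one dosing interval."""

    index: int
    dose_index: int
    start: float
    end: float  # next dose start (or +inf for the final interval)
    obs: list[ObservationRecord]


@dataclass(frozen=True)
class ForecastTask:
    patient_id: str
    preceding: int
    target: int
    method: str  # "first_order" | "conventional" | "flat_<coef>" | "weighted"
    samples_used: str

    def __post_init__(self) -> None:
        if not self.preceding < self.target:
            raise ValueError("preceding occasion must precede the target")


@dataclass(frozen=True)
class ForecastPair:
    c_forecast: float
    c_observed: float
    target_time: float
    lead_time_days: float
    task: ForecastTask
    map_weight: float | None = None

    def __post_init__(self) -> None:
        if not (self.c_forecast > 0 and self.c_observed > 0):
            raise ValueError("forecast and observed concentrations must be > 0")


def split_occasions(
    obs: Sequence[ObservationRecord], doses: Sequence[DosingEvent]
) -> list[Occasion]:
    """Group observations by the (half-open) dosing interval containing them."""
    ordered_doses = sorted(doses, key=lambda d: d.start_time)
    starts = [d.start_time for d in ordered_doses]
    groups: dict[int, list[ObservationRecord]] = {}
    for o in sorted(obs, key=lambda x: x.time):
        idx = int(np.searchsorted(starts, o.time, side="right")) - 1
        if idx < 0:
            raise ValueError(
                f"observation at t={o.time} h is not covered by any dose"
            )
        if o.window is None:
            o = ObservationRecord(
                time=o.time,
                conc=o.conc,
                window=classify_sample(o.time, ordered_doses),
                occasion=o.occasion,
            )
        groups.setdefault(idx, []).append(o)
    occasions = []
    for rank, dose_idx in enumerate(sorted(groups)):
        end = starts[dose_idx + 1] if dose_idx + 1 < len(starts) else math.inf
        occasions.append(
            Occasion(
                index=rank,
                dose_index=dose_idx,
                start=starts[dose_idx],
                end=end,
                obs=groups[dose_idx],
            )
        )
    return occasions


def select_samples(occasion: Occasion, samples_used: str) -> list[ObservationRecord] | None:
    """Pick the requested sample(s) from an occasion; None when unavailable."""
    if samples_used == "two_post_dose":
        if len(occasion.obs) < 2:
            return None
        return occasion.obs[:2]
    wanted = samples_used.split("+")
    picked = []
    for w in wanted:
        match = [o for o in occasion.obs if o.window == w]
        if not match:
            return None
        picked.append(match[0])
    return sorted(picked, key=lambda o: o.time)


def _interval_of(occasion: Occasion, ledger: PatientLedger) -> float:
    if math.isfinite(occasion.end):
        return occasion.end - occasion.start
    dose = ledger.doses[occasion.dose_index]
    if dose.interval_hint is not None:
        return dose.interval_hint
    raise ValueError("cannot infer the dosing interval of the final dose")


def run_forecast(
    task: ForecastTask,
    ledger: PatientLedger,
    prior: PopPrior,
    weight_strategy=None,
    _occasions: list[Occasion] | None = None,
    _fit_cache: dict | None = None,
) -> list[ForecastPair]:
    """Execute one forecasting task, one ForecastPair per target observation.

    Returns an empty list (with a log record) when the requested samples are
    absent from the preceding occasion, mirroring observational availability.
    """
    occasions = _occasions if _occasions is not None else split_occasions(
        ledger.obs, ledger.doses
    )
    if task.target >= len(occasions) or task.preceding < 0:
        raise ValueError(
            f"task occasions ({task.preceding}->{task.target}) outside the ledger's "
            f"{len(occasions)} occasions"
        )
    prev, target = occasions[task.preceding], occasions[task.target]
    sel = select_samples(prev, task.samples_used)
    if sel is None:
        logger.info(
            "patient %s occasion %d: samples %r unavailable; task skipped",
            task.patient_id, task.preceding, task.samples_used,
        )
        return []

    cov = ledger.covariates
    doses = ledger.doses
    map_weight: float | None = None

    if task.method == "first_order":
        c1, c2 = sel[0], sel[1]
        dose = doses[prev.dose_index]
        tau = _interval_of(prev, ledger)
        try:
            fit = fit_two_point(c1.conc, c1.time, c2.conc, c2.time, dose, tau)
        except ValueError as err:
            logger.info(
                "patient %s occasion %d: two-point fit failed (%s); task skipped",
                task.patient_id, task.preceding, err,
            )
            return []

        def predict(t: float) -> float:
            return float(forecast_first_order(fit, doses, [t])[0])

    else:
        if task.method == "conventional":
            spec = FlattenSpec("conventional")
        elif task.method.startswith("flat_"):
            spec = FlattenSpec("flattened", flat_coef=float(task.method[5:]))
        elif task.method == "weighted":
            strategy = weight_strategy if weight_strategy is not None else FixedWeight()
            history = []
            for occ in occasions[: task.preceding]:
                picked = select_samples(occ, task.samples_used)
                history.append(picked if picked is not None else occ.obs)
            history.append(sel)
            map_weight = strategy.select(history, doses, prior, cov)
            spec = FlattenSpec("weighted", weight=map_weight)
        else:
            raise ValueError(f"unknown method {task.method!r}")

        cache_key = None
        fit = None
        if _fit_cache is not None:
            cache_key = (task.preceding, task.samples_used, spec.weights())
            fit = _fit_cache.get(cache_key)
        if fit is None:
            fit = map_estimate(sel, doses, prior, cov, spec)
            if _fit_cache is not None:
                _fit_cache[cache_key] = fit

        e0, e1 = math.exp(fit.eta[0]), math.exp(fit.eta[1])

        def predict(t: float) -> float:
            clp, vp = prior.typical(cov, t)  # scr in force at the forecast time
            return float(concentration_cv(clp * e0, vp * e1, doses, t))

    last_used = max(o.time for o in sel)
    first_target = min(o.time for o in target.obs)
    lead_days = (first_target - last_used) / 24.0
    pairs = []
    for o in target.obs:
        pairs.append(
            ForecastPair(
                c_forecast=predict(o.time),
                c_observed=o.conc,
                target_time=o.time,
                lead_time_days=lead_days,
                task=task,
                map_weight=map_weight,
            )
        )
    return pairs


def default_methods(flat_coefs: Sequence[float] = FLAT_COEF_GRID) -> list[str]:
    """The study's method matrix: conventional, flattened grid, weighted, first-order."""
    return (
        ["conventional"]
        + [f"flat_{c:g}" for c in flat_coefs]
        + ["weighted", "first_order"]
    )


def run_matrix(
    ledgers: Sequence[PatientLedger],
    prior: PopPrior,
    methods: Sequence[str] | None = None,
    selections: Sequence[str] = BAYES_SELECTIONS,
    weight_strategy=None,
) -> pd.DataFrame:
    """Run every (method x sample-selection) forecast over consecutive occasions.

    Bayesian methods use each selection in ``selections``; the first-order
    method always uses the two post-dose levels.  Returns the tidy per-pair
    table consumed by :mod:`vancoforecast.evaluation`.
    """
    methods = list(methods) if methods is not None else default_methods()
    if weight_strategy is None:
        weight_strategy = RetrospectiveWeight()
    rows = []
    for ledger in ledgers:
        occasions = split_occasions(ledger.obs, ledger.doses)
        fit_cache: dict = {}
        cov = ledger.covariates
        for target_idx in range(1, len(occasions)):
            for method in methods:
                sels = ["two_post_dose"] if method == "first_order" else selections
                for sel in sels:
                    task = ForecastTask(
                        patient_id=ledger.patient_id,
                        preceding=target_idx - 1,
                        target=target_idx,
                        method=method,
                        samples_used=sel,
                    )
                    pairs = run_forecast(
                        task,
                        ledger,
                        prior,
                        weight_strategy=weight_strategy,
                        _occasions=occasions,
                        _fit_cache=fit_cache,
                    )
                    for p in pairs:
                        rows.append(
                            {
                                "patient": ledger.patient_id,
                                "preceding_occasion": task.preceding,
                                "target_occasion": task.target,
                                "method": method,
                                "samples_used": sel,
                                "map_weight": p.map_weight,
                                "target_time_h": p.target_time,
                                "lead_time_days": p.lead_time_days,
                                "c_forecast": p.c_forecast,
                                "c_observed": p.c_observed,
                                "age_months": cov.age_months,
                                "weight_kg": cov.weight_kg,
                                "scr_mgdl": cov.scr_at(p.target_time),
                            }
                        )
    return pd.DataFrame(rows)
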