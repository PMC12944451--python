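"""Readers and writers for the pipeline's tidy-CSV interchange formats.

The longitudinal ledger is a NONMEM-style CSV with columns
``ID, TIME, AMT, DUR, DV, EVID, AGE_MO, WT_KG, SCR_MGDL`` — one row per dose
(``EVID=1``, blank ``DV``) or observation (``EVID=0``, blank ``AMT``), times in
hours since the first dose, monotone within a patient.  Serum creatinine may
vary over rows; it becomes a right-continuous step series.  The prior config
is a YAML file (see ``data/prior_le2014.yaml`` for the shipped default).
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pk import (
    DosingEvent,
    ObservationRecord,
    PatientCovariates,
    PopPrior,
    ResidualModel,
    StepSeries,
)
from .forecaster import PatientLedger

__all__ = [
    "LedgerFormatError",
    "read_ledger",
    "write_ledger",
    "read_prior_config",
    "default_prior",
]

logger = logging.getLogger(__name__)

LEDGER_COLUMNS = ["ID", "TIME", "AMT", "DUR", "DV", "EVID", "AGE_MO", "WT_KG", "SCR_MGDL"]
REQUIRED_COLUMNS = ["ID", "TIME", "AMT", "DV", "EVID", "AGE_MO", "WT_KG", "SCR_MGDL"]

DEFAULT_INFUSION_DURATION_H = 1.0


class LedgerFormatError(ValueError):
    """Raised for malformed ledger files, with offending row numbers."""


def read_ledger(path: str | Path) -> list[PatientLedger]:
    """Read and validate a ledger CSV into per-patient records."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise LedgerFormatError(f"ledger {path} is missing columns: {missing}")
    if "DUR" not in df.columns:
        logger.warning(
            "ledger %s has no DUR column; infusion duration defaults to %g h",
            path, DEFAULT_INFUSION_DURATION_H,
        )
        df["DUR"] = np.nan

    bad_rows = []
    for pid, sub in df.groupby("ID", sort=False):
        t = sub["TIME"].to_numpy(dtype=float)
        dec = np.where(np.diff(t) < 0)[0]
        # +2: 1-based and header row, matching what a user sees in the file
        bad_rows.extend((sub.index[i + 1] + 2) for i in dec)
    if bad_rows:
        raise LedgerFormatError(
            f"ledger {path}: TIME not monotone within ID at row(s) {sorted(bad_rows)}"
        )

    ledgers = []
    for pid, sub in df.groupby("ID", sort=False):
        doses, obs = [], []
        for row_no, row in sub.iterrows():
            if int(row["EVID"]) == 1:
                dur = row["DUR"]
                if pd.isna(dur):
                    logger.warning(
                        "row %d: missing infusion duration, defaulting to %g h",
                        row_no + 2, DEFAULT_INFUSION_DURATION_H,
                    )
                    dur = DEFAULT_INFUSION_DURATION_H
                doses.append(
                    DosingEvent(
                        start_time=float(row["TIME"]),
                        amount=float(row["AMT"]),
                        infusion_duration=float(dur),
                    )
                )
            else:
                if pd.isna(row["DV"]):
                    raise LedgerFormatError(
                        f"row {row_no + 2}: observation row with blank DV"
                    )
                obs.append(
                    ObservationRecord(time=float(row["TIME"]), conc=float(row["DV"]))
                )
        scr_t = sub["TIME"].to_numpy(dtype=float)
        scr_v = sub["SCR_MGDL"].to_numpy(dtype=float)
        keep = np.concatenate(([True], np.diff(scr_v) != 0))
        times = scr_t[keep]
        values = scr_v[keep]
        if times[0] != 0.0:
            times = np.concatenate(([0.0], times))
            values = np.concatenate(([values[0]], values))
        # drop duplicate times keeping the last value (right-continuity)
        _, last_idx = np.unique(times[::-1], return_index=True)
        sel = sorted(len(times) - 1 - last_idx)
        cov = PatientCovariates(
            age_months=float(sub["AGE_MO"].iloc[0]),
            weight_kg=float(sub["WT_KG"].iloc[0]),
            scr=StepSeries(times[sel], values[sel]),
        )
        ledgers.append(PatientLedger(str(pid), doses, obs, cov))
    return ledgers


def write_ledger(ledgers: list[PatientLedger], path: str | Path) -> None:
    """Write per-patient records to the ledger CSV dialect (lossless round trip)."""
    rows = []
    for led in ledgers:
        cov = led.covariates
        events = [("dose", d.start_time, d) for d in led.doses] + [
            ("obs", o.time, o) for o in led.obs
        ]
        events.sort(key=lambda e: (e[1], 0 if e[0] == "dose" else 1))
        for kind, t, ev in events:
            rows.append(
                {
                    "ID": led.patient_id,
                    "TIME": t,
                    "AMT": ev.amount if kind == "dose" else np.nan,
                    "DUR": ev.infusion_duration if kind == "dose" else np.nan,
                    "DV": ev.conc if kind == "obs" else np.nan,
                    "EVID": 1 if kind == "dose" else 0,
                    "AGE_MO": cov.age_months,
                    "WT_KG": cov.weight_kg,
                    "SCR_MGDL": cov.scr_at(t),
                }
            )
    # %.17g round-trips IEEE doubles exactly (lossless read-back)
    pd.DataFrame(rows, columns=LEDGER_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_prior_config(path: str | Path) -> PopPrior:
    """Build a :class:`PopPrior` from a YAML config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return _prior_from_dict(cfg)


def _prior_from_dict(cfg: dict) -> PopPrior:
    sigma_cfg = cfg.get("sigma", {})
    return PopPrior(
        model=cfg.get("model", "le2014"),
        theta=cfg.get("theta"),
        omega2=cfg.get("omega2"),
        sigma=ResidualModel(
            prop_cv=float(sigma_cfg.get("prop_cv", 0.15)),
            add_sd=float(sigma_cfg.get("add_sd", 0.0)),
        ),
        iov2=float(cfg.get("iov2", 0.0)),
        penalty_space=cfg.get("penalty_space", "eta"),
    )


def default_prior() -> PopPrior:
    """The shipped pediatric vancomycin prior (see data/prior_le2014.yaml)."""
    ref = resources.files("vancoforecast").joinpath("data/prior_le2014.yaml")
    cfg = yaml.safe_load(ref.read_text())
    return _prior_from_dict(cfg)
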