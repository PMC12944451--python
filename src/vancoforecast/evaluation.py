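"""Forecast-accuracy metrics (rBias, rRMSE), cluster-bootstrap confidence
intervals and the linear mixed-effects factor analysis.

The symmetric relative deviation of a forecast/observed pair is

    d_i = 100 * (Cf_i - Co_i) / ((Cf_i + Co_i) / 2)        (%)

which is bounded in (-200, 200).  rBias is the mean of d_i; rRMSE is the root
mean square of d_i (hence 0 <= rRMSE < 200 and rRMSE >= |rBias|).  Confidence
intervals resample whole patients with replacement (cluster bootstrap), which
respects the repeated measures within a patient.  The factor analysis fits
linear mixed-effects models with a random intercept per patient, univariable
screening at p < 0.05 followed by a multivariable model on the survivors.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "symmetric_deviation",
    "rbias",
    "rrmse",
    "bootstrap_ci",
    "MetricResult",
    "stratified_metrics",
    "LmeRow",
    "lme_factor_analysis",
    "prepare_lme_table",
]

logger = logging.getLogger(__name__)

SIG_LEVEL = 0.05


def _as_arrays(c_forecast, c_observed) -> tuple[np.ndarray, np.ndarray]:
    cf = np.asarray(c_forecast, dtype=float)
    co = np.asarray(c_observed, dtype=float)
    if cf.size == 0:
        raise ValueError("metrics need at least one forecast/observed pair")
    if cf.shape != co.shape:
        raise ValueError("forecast and observed arrays must have equal shape")
    if np.any(cf <= 0) or np.any(co <= 0):
        raise ValueError("all concentrations must be strictly positive")
    return cf, co


def symmetric_deviation(c_forecast, c_observed) -> np.ndarray:
    """Per-pair symmetric relative deviation in % (bounded in (-200, 200))."""
    cf, co = _as_arrays(c_forecast, c_observed)
    return 100.0 * (cf - co) / ((cf + co) / 2.0)


def rbias(c_forecast, c_observed) -> float:
    """Relative bias (%): mean symmetric relative deviation."""
    return float(np.mean(symmetric_deviation(c_forecast, c_observed)))


def rrmse(c_forecast, c_observed) -> float:
    """Relative RMSE (%): root mean squared symmetric relative deviation."""
    return float(np.sqrt(np.mean(symmetric_deviation(c_forecast, c_observed) ** 2)))


def _cluster_stats(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    dev = symmetric_deviation(table["c_forecast"], table["c_observed"])
    frame = pd.DataFrame({"patient": table["patient"].to_numpy(), "dev": dev})
    grouped = frame.groupby("patient")["dev"]
    sums = grouped.sum().to_numpy()
    sq = grouped.apply(lambda s: float(np.sum(s.to_numpy() ** 2))).to_numpy()
    counts = grouped.size().to_numpy()
    return sums, sq, counts


def bootstrap_ci(
    table: pd.DataFrame,
    metric: str = "rbias",
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile cluster-bootstrap CI, resampling patients with replacement.

    ``table`` needs columns ``patient``, ``c_forecast``, ``c_observed``.
    Reproducible under ``seed``; a single-patient table yields a degenerate CI
    (logged), since there is nothing to resample between clusters.
    """
    if metric not in ("rbias", "rrmse"):
        raise ValueError(f"unknown metric {metric!r}")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    sums, sq, counts = _cluster_stats(table)
    n_pat = len(counts)
    if n_pat < 2:
        logger.warning("cluster bootstrap over a single patient: degenerate CI")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_pat, size=(n_boot, n_pat))
    tot_n = counts[idx].sum(axis=1).astype(float)
    if metric == "rbias":
        stats = sums[idx].sum(axis=1) / tot_n
    else:
        stats = np.sqrt(sq[idx].sum(axis=1) / tot_n)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(stats, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


@dataclass(frozen=True)
class MetricResult:
    """Aggregated accuracy/precision for one (method, samples_used) stratum."""

    stratum: tuple[str, str]
    rbias: float
    rrmse: float
    n: int
    ci95_rbias: tuple[float, float]
    ci95_rrmse: tuple[float, float]


def stratified_metrics(
    table: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """rBias/rRMSE with bootstrap CIs per (method, samples_used) stratum."""
    rows = []
    for (method, sel), sub in table.groupby(["method", "samples_used"], sort=True):
        rb = rbias(sub["c_forecast"], sub["c_observed"])
        rr = rrmse(sub["c_forecast"], sub["c_observed"])
        ci_rb = bootstrap_ci(sub, "rbias", n_boot=n_boot, seed=seed)
        ci_rr = bootstrap_ci(sub, "rrmse", n_boot=n_boot, seed=seed)
        rows.append(
            {
                "method": method,
                "samples_used": sel,
                "n": len(sub),
                "rbias": rb,
                "rbias_lo": ci_rb[0],
                "rbias_hi": ci_rb[1],
                "rrmse": rr,
                "rrmse_lo": ci_rr[0],
                "rrmse_hi": ci_rr[1],
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LmeRow:
    variable: str
    estimate: float
    ci95: tuple[float, float]
    p_value: float
    model: str  # "univariable" | "multivariable"
    flag: str = ""


#: Reference levels: conventional Bayes; two-concentration sampling.
METHOD_REFERENCE = "conventional"
SAMPLE_REFERENCE = "two"

_STANDARD_TERMS = {
    "age_months": "age_months",
    "weight_kg": "weight_kg",
    "scr_mgdl": "scr_mgdl",
    "lead_time_days": "lead_time_days",
    "sample_group": f"C(sample_group, Treatment('{SAMPLE_REFERENCE}'))",
    "method": f"C(method, Treatment('{METHOD_REFERENCE}'))",
}


def prepare_lme_table(pair_table: pd.DataFrame) -> pd.DataFrame:
    """Add per-pair outcomes and the pooled sample grouping to a forecast table.

    Outcomes: ``dev`` (signed symmetric relative deviation, the per-pair
    "rBias") and ``abs_dev`` (its absolute value, the per-pair root squared
    deviation, the "rRMSE" outcome).  Two-sample selections (the explicit
    pairs and ``two_post_dose``) map to the reference level "two".
    """
    out = pair_table.copy()
    out["dev"] = symmetric_deviation(out["c_forecast"], out["c_observed"])
    out["abs_dev"] = np.abs(out["dev"])
    out["sample_group"] = [
        s if s in ("peak", "mid", "trough") else SAMPLE_REFERENCE
        for s in out["samples_used"]
    ]
    return out


def _fit_mixed(formula: str, data: pd.DataFrame, group_col: str):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        model = smf.mixedlm(formula, data, groups=data[group_col])
        return model.fit(reml=False)


def _extract_rows(result, model_label: str, flag: str = "") -> list[LmeRow]:
    ci = result.conf_int()
    rows = []
    for name in result.fe_params.index:
        if name == "Intercept":
            continue
        rows.append(
            LmeRow(
                variable=name,
                estimate=float(result.fe_params[name]),
                ci95=(float(ci.loc[name, 0]), float(ci.loc[name, 1])),
                p_value=float(result.pvalues[name]),
                model=model_label,
                flag=flag,
            )
        )
    return rows


def lme_factor_analysis(
    table: pd.DataFrame,
    outcome: str = "rbias",
    covariates: Sequence[str] | None = None,
    group_col: str = "patient",
    sig_level: float = SIG_LEVEL,
) -> pd.DataFrame:
    """Univariable screen then multivariable linear mixed-effects regression.

    ``outcome`` is ``"rbias"`` (signed per-pair deviation) or ``"rrmse"``
    (absolute per-pair deviation), or the name of any numeric column already in
    ``table``.  One random-intercept model is fitted per covariate; covariates
    with any coefficient at p < ``sig_level`` enter the multivariable model.
    Returns one row per coefficient and model, Wald 95% CIs, ML fits.
    """
    data = table.copy()
    if outcome in ("rbias", "rrmse"):
        if "dev" not in data.columns:
            data = prepare_lme_table(data)
        data["_outcome"] = data["dev"] if outcome == "rbias" else data["abs_dev"]
    else:
        data["_outcome"] = data[outcome]
    if covariates is None:
        covariates = [c for c in _STANDARD_TERMS if c in data.columns]
    rows: list[LmeRow] = []
    survivors: list[str] = []
    for cov in covariates:
        term = _STANDARD_TERMS.get(cov, cov)
        try:
            res = _fit_mixed(f"_outcome ~ {term}", data, group_col)
            cov_rows = _extract_rows(res, "univariable")
        except (np.linalg.LinAlgError, ValueError) as err:
            logger.warning("univariable fit for %s failed: %s", cov, err)
            rows.append(LmeRow(cov, float("nan"), (float("nan"),) * 2, float("nan"),
                               "univariable", flag="singular"))
            continue
        rows.extend(cov_rows)
        if any(r.p_value < sig_level for r in cov_rows):
            survivors.append(term)
    if survivors:
        try:
            res = _fit_mixed("_outcome ~ " + " + ".join(survivors), data, group_col)
            rows.extend(_extract_rows(res, "multivariable"))
        except (np.linalg.LinAlgError, ValueError) as err:
            logger.warning("multivariable fit failed: %s", err)
            rows.append(LmeRow("+".join(survivors), float("nan"), (float("nan"),) * 2,
                               float("nan"), "multivariable", flag="singular"))
    return pd.DataFrame(
        {
            "variable": [r.variable for r in rows],
            "estimate": [r.estimate for r in rows],
            "ci95_lo": [r.ci95[0] for r in rows],
            "ci95_hi": [r.ci95[1] for r in rows],
            "p_value": [r.p_value for r in rows],
            "model": [r.model for r in rows],
            "flag": [r.flag for r in rows],
        }
    )
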