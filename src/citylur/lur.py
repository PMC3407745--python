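"""Period-specific land use regression on log NO2 concentrations.

Workflow: per-site annual means from repeated one-week deployments (complete
coverage required), univariate screening of every candidate predictor, then a
manual-style backward stepwise multiple regression on the log scale with two
domain rules layered on plain p-value elimination:

* *sign rule* — a predictor whose fitted slope contradicts its expected
  direction (e.g. a negative slope on traffic density) is removed, worst
  violator first, regardless of significance;
* *coordinate pairing* — the planar x/y coordinates enter and leave the model
  as a pair: if one of them earns its place by p-value, the other is kept
  irrespective of its own p-value.

Predictions back-transform by plain exponentiation; an optional Duan smearing
factor is available but off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from ._ols import OLSFit, fit_ols
from .predictors import PREDICTOR_SCHEMA, ExpectedSignTable

DEFAULT_P_REMOVE = 0.20

_COORDS = ("x_coord", "y_coord")


@dataclass
class MeasurementSet:
    """One campaign's raw records plus site metadata."""

    campaign: int
    sampler: str
    records: pd.DataFrame          # columns: site_id, period, value
    sites: pd.DataFrame            # columns: site_id, x, y, site_type

    def __post_init__(self) -> None:
        if self.records.duplicated(["site_id", "period"]).any():
            raise ValueError("duplicate (site_id, period) records")
        if (self.records["value"].dropna() <= 0).any():
            raise ValueError("concentrations must be positive")


@dataclass
class LURModel:
    campaign: int
    predictors: list[str]
    intercept: float
    coefficients: dict[str, float]
    pvalues: dict[str, float]
    r2: float
    adjusted_r2: float
    rmse_log: float
    n_sites: int
    signs: ExpectedSignTable = field(repr=False)
    smearing_factor: float = 1.0
    removal_trace: list[dict] = field(default_factory=list, repr=False)

    def to_dict(self) -> dict:
        return {
            "campaign": self.campaign,
            "predictors": list(self.predictors),
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "pvalues": dict(self.pvalues),
            "r2": self.r2,
            "adjusted_r2": self.adjusted_r2,
            "rmse_log": self.rmse_log,
            "n_sites": self.n_sites,
            "smearing_factor": self.smearing_factor,
            "removal_trace": list(self.removal_trace),
        }


def site_period_mean(
    records: pd.DataFrame, required_periods: int
) -> tuple[pd.Series, list, list]:
    """Annual value per site = mean over deployment periods.

    Sites missing any of the ``required_periods`` periods are dropped and
    reported, so the annual estimate always averages a complete set.

    Returns (per-site means indexed by site_id, retained ids, dropped ids).
    """
    if required_periods < 1:
        raise ValueError("required_periods must be >= 1")
    if records.empty:
        return pd.Series(dtype=float, name="value"), [], []
    wide = records.pivot(index="site_id", columns="period", values="value")
    complete = wide.notna().sum(axis=1) >= required_periods
    retained = wide.index[complete].tolist()
    dropped = wide.index[~complete].tolist()
    means = wide.loc[complete].mean(axis=1)
    means.name = "value"
    return means, retained, dropped


def univariate_screen(
    predictor_table: pd.DataFrame, log_response: np.ndarray | pd.Series
) -> pd.DataFrame:
    """Simple OLS of the log response on each predictor separately."""
    y = np.asarray(log_response, dtype=float)
    if len(predictor_table) != len(y):
        raise ValueError("predictor table and response lengths differ")
    if len(y) < 3:
        raise ValueError("univariate screening needs >= 3 sites")
    rows = []
    for name in predictor_table.columns:
        x = predictor_table[name].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append({"predictor": name, "slope": np.nan, "p_value": np.nan, "constant": True})
            continue
        f = fit_ols(x[:, None], y, [name])
        rows.append(
            {"predictor": name, "slope": f.coef[1], "p_value": f.pvalues[1], "constant": False}
        )
    return pd.DataFrame(rows).set_index("predictor")


def _refit(table: pd.DataFrame, y: np.ndarray, kept: list[str]) -> OLSFit:
    return fit_ols(table[kept].to_numpy(dtype=float), y, kept)


def _schema_rank(name: str) -> int:
    try:
        return PREDICTOR_SCHEMA.index(name)
    except ValueError:
        return len(PREDICTOR_SCHEMA)


def _coordinate_protected(name: str, kept: list[str], pvals: dict[str, float], p_remove: float) -> bool:
    # a coordinate is shielded from p-removal while its partner stays on merit
    if name not in _COORDS:
        return False
    partner = _COORDS[1 - _COORDS.index(name)]
    return partner in kept and pvals[partner] <= p_remove


def backward_stepwise_fit(
    predictor_table: pd.DataFrame,
    log_response: np.ndarray | pd.Series,
    signs: ExpectedSignTable,
    p_remove: float = DEFAULT_P_REMOVE,
    campaign: int = 0,
    sign_rule: Literal["iterative", "prescreen"] = "iterative",
) -> LURModel:
    """Sign-constrained backward elimination on the log concentration scale.

    Starting from the model with every candidate, repeat until stable:

    1. if any sign-constrained predictor's current coefficient violates its
       expected direction, drop the violator with the largest p-value;
    2. otherwise drop the predictor with the largest p-value above
       ``p_remove``, unless it is a coordinate protected by the pairing rule.

    Ties in p-value are broken by dropping the predictor that appears later in
    the canonical schema ordering. ``sign_rule="prescreen"`` instead applies
    the sign rule once to the univariate slopes before any p-based removal.
    """
    y = np.asarray(log_response, dtype=float)
    kept = list(predictor_table.columns)
    n = len(y)
    if n <= len(kept) + 1:
        raise ValueError(f"{n} sites cannot support {len(kept)} candidate predictors")
    trace: list[dict] = []

    for name in list(kept):  # constant columns can never be identified
        if np.ptp(predictor_table[name].to_numpy(dtype=float)) == 0:
            kept.remove(name)
            trace.append({"removed": name, "reason": "constant", "p": float("nan")})

    if sign_rule == "prescreen":
        uni = univariate_screen(predictor_table, y)
        for name in list(kept):
            if not uni.loc[name, "constant"] and signs.violates(name, uni.loc[name, "slope"]):
                kept.remove(name)
                trace.append({"removed": name, "reason": "sign (univariate)", "p": float(uni.loc[name, "p_value"])})

    while kept:
        fit = _refit(predictor_table, y, kept)
        coefs = dict(zip(kept, fit.coef[1:]))
        pvals = dict(zip(kept, fit.pvalues[1:]))

        if sign_rule == "iterative":
            violators = [k for k in kept if signs.violates(k, coefs[k])]
            if violators:
                worst = max(violators, key=lambda k: (pvals[k], _schema_rank(k)))
                kept.remove(worst)
                trace.append({"removed": worst, "reason": "sign", "p": float(pvals[worst])})
                continue

        removable = sorted(
            (k for k in kept if pvals[k] > p_remove),
            key=lambda k: (-pvals[k], -_schema_rank(k)),
        )
        removed = False
        for cand in removable:
            if _coordinate_protected(cand, kept, pvals, p_remove):
                continue
            kept.remove(cand)
            trace.append({"removed": cand, "reason": "p-value", "p": float(pvals[cand])})
            removed = True
            break
        if not removed:
            break

    if not kept:
        warnings.warn("no predictor survived elimination; returning intercept-only model")
        mu = float(y.mean())
        resid = y - mu
        df = n - 1
        rmse = float(np.sqrt(resid @ resid / df)) if df > 0 else 0.0
        return LURModel(
            campaign=campaign, predictors=[], intercept=mu, coefficients={},
            pvalues={}, r2=0.0, adjusted_r2=0.0, rmse_log=rmse, n_sites=n,
            signs=signs, smearing_factor=float(np.mean(np.exp(resid))),
            removal_trace=trace,
        )

    fit = _refit(predictor_table, y, kept)
    return LURModel(
        campaign=campaign,
        predictors=list(kept),
        intercept=float(fit.coef[0]),
        coefficients={k: float(c) for k, c in zip(kept, fit.coef[1:])},
        pvalues={k: float(p) for k, p in zip(kept, fit.pvalues[1:])},
        r2=float(fit.r2),
        adjusted_r2=float(fit.adj_r2),
        rmse_log=float(fit.rmse),
        n_sites=n,
        signs=signs,
        smearing_factor=float(np.mean(np.exp(fit.residuals))),
        removal_trace=trace,
    )


def predict_no2(
    model: LURModel, predictor_rows: pd.DataFrame, smearing: bool = False
) -> np.ndarray:
    """Concentration predictions in ug/m3 (strictly positive)."""
    missing = [p for p in model.predictors if p not in predictor_rows.columns]
    if missing:
        raise KeyError(f"predictor columns missing from input: {missing}")
    lin = np.full(len(predictor_rows), model.intercept, dtype=float)
    for name in model.predictors:
        lin += model.coefficients[name] * predictor_rows[name].to_numpy(dtype=float)
    out = np.exp(lin)
    if smearing:
        out *= model.smearing_factor
    return out
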