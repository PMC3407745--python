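"""Exposure assignment to cohort addresses and descriptive comparisons.

Predicted concentrations from each fitted exposure model are attached to every
subject's address, categorised into quintiles and into four fixed
concentration classes, summarised by population stratum, and compared across
ordered groups with a rank-based trend test and between genders with an
unequal-variance t-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lur import LURModel, predict_no2

#: fixed class bounds, ug/m3; intervals are left-open / right-closed
FIXED4_BOUNDS = (35.0, 45.0, 50.0)
FIXED4_LABELS = ("<=35", "35-45", "45-50", ">50")


def assign_exposure(
    model: LURModel, cohort: pd.DataFrame, predictor_table_at_addresses: pd.DataFrame
) -> np.ndarray:
    """Model-predicted concentration at each subject's address (row-aligned)."""
    if len(cohort) != len(predictor_table_at_addresses):
        raise ValueError("cohort and address predictor table lengths differ")
    return predict_no2(model, predictor_table_at_addresses)


def categorize_exposure(values: np.ndarray, scheme: str = "quintiles") -> np.ndarray:
    """Integer group labels (1-based) under ``quintiles`` or ``fixed4``.

    Quintile cutpoints are the empirical 20/40/60/80 percentiles; values tied
    with a cutpoint go to the lower group. Fixed classes are
    (-inf,35], (35,45], (45,50], (50,inf).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot categorise an empty exposure vector")
    if scheme == "quintiles":
        cuts = np.quantile(values, [0.2, 0.4, 0.6, 0.8])
    elif scheme == "fixed4":
        cuts = np.asarray(FIXED4_BOUNDS)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    # searchsorted(left): value equal to a cutpoint lands in the lower group
    return np.searchsorted(cuts, values, side="left") + 1


def stratified_summary(
    exposures: np.ndarray, covariates: pd.DataFrame, strata: list[str] | None = None
) -> pd.DataFrame:
    """n, mean, sd, quartiles (linear interpolation), min, max per stratum.

    One block of rows per stratifying variable plus an overall row; empty
    strata produce a row with n = 0 and blank statistics.
    """
    x = np.asarray(exposures, dtype=float)
    if len(x) != len(covariates):
        raise ValueError("exposures and covariates lengths differ")
    strata = strata or list(covariates.columns)

    def _row(var, level, vals):
        if len(vals) == 0:
            return {"variable": var, "level": level, "n": 0}
        return {
            "variable": var,
            "level": level,
            "n": len(vals),
            "mean": vals.mean(),
            "sd": vals.std(ddof=1) if len(vals) > 1 else 0.0,
            "q25": np.quantile(vals, 0.25),
            "q50": np.quantile(vals, 0.50),
            "q75": np.quantile(vals, 0.75),
            "min": vals.min(),
            "max": vals.max(),
        }

    rows = [_row("all", "all", x)]
    for var in strata:
        labels = covariates[var].to_numpy()
        for level in pd.unique(labels):
            rows.append(_row(var, level, x[labels == level]))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class TrendTest:
    z: float
    p_value: float
    T: float
    expected_T: float
    var_T: float


def cuzick_trend(values: np.ndarray, ordered_group_labels: np.ndarray) -> TrendTest:
    """Rank-based test for trend across ordered groups (integer group scores).

    T = sum of group score x midrank over observations; under the null
    E[T] = (N+1) * sum(score_j n_j) / 2 and, with a tie correction,
    Var[T] = (N+1)/12 * (N sum(score^2 n) - L^2) * (1 - sum(t^3-t)/(N^3-N)).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(ordered_group_labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("trend test needs >= 2 ordered groups")
    if np.ptp(values) == 0:
        raise ValueError("all values tied; trend test undefined")
    scores = {g: i + 1 for i, g in enumerate(groups)}
    li = np.vectorize(scores.get)(labels).astype(float)
    n_tot = len(values)
    ranks = stats.rankdata(values)  # midranks for ties
    T = float(np.sum(li * ranks))
    n_j = np.array([(labels == g).sum() for g in groups], dtype=float)
    z_j = np.arange(1, len(groups) + 1, dtype=float)
    L = float(np.sum(z_j * n_j))
    e_T = (n_tot + 1) * L / 2.0
    var_T = (n_tot + 1) / 12.0 * (n_tot * float(np.sum(z_j**2 * n_j)) - L**2)
    _, counts = np.unique(values, return_counts=True)
    tie_adj = 1.0 - float(np.sum(counts**3 - counts)) / (n_tot**3 - n_tot)
    var_T *= tie_adj
    if var_T <= 0:
        raise ValueError("degenerate trend-test variance")
    z = (T - e_T) / np.sqrt(var_T)
    return TrendTest(z=float(z), p_value=float(2 * stats.norm.sf(abs(z))), T=T, expected_T=e_T, var_T=float(var_T))


def gender_difference(values: np.ndarray, gender: np.ndarray) -> tuple[float, float]:
    """Welch's unequal-variance t-test between the two gender groups."""
    g = np.asarray(gender)
    levels = pd.unique(g)
    if len(levels) != 2:
        raise ValueError("gender comparison needs exactly 2 groups")
    a = np.asarray(values, float)[g == levels[0]]
    b = np.asarray(values, float)[g == levels[1]]
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)
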