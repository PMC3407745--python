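"""Diagnostics and validation for a fitted exposure model.

Covers leave-one-out cross-validation on the concentration scale,
multicollinearity (variance inflation factors), influence (Cook's distance),
spatial autocorrelation of residuals (Moran's I with a permutation test), and
cross-period transportability of a model to another campaign's measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._ols import RankDeficientError, fit_ols, hat_diagonal
from .lur import LURModel, predict_no2


@dataclass
class CVResult:
    measured: np.ndarray
    predicted: np.ndarray         # leave-one-out predictions, ug/m3
    r2: float
    adjusted_r2: float
    rmse: float                   # sqrt(mean squared measured-predicted gap)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"measured": self.measured, "predicted": self.predicted})


@dataclass
class MoranResult:
    I: float
    expected_I: float             # -1/(n-1) under exchangeability
    p_perm: float | None
    n_perm: int
    p_analytic: float | None = None


def loocv(
    predictor_table: pd.DataFrame,
    measurements: np.ndarray | pd.Series,
    selected_predictors: list[str],
    log_scale: bool = True,
) -> CVResult:
    """Leave-one-out cross-validation with a fixed predictor set.

    Each site is predicted from coefficients refitted on the remaining sites
    (the selection itself is not redone, the standard practice for exposure
    models); predictions are back-transformed and compared with the measured
    concentrations on the original scale. ``r2``/``adjusted_r2`` come from the
    regression of measured on predicted values; ``rmse`` is the root mean
    squared measured-predicted difference.
    """
    y_raw = np.asarray(measurements, dtype=float)
    n = len(y_raw)
    if n < len(selected_predictors) + 2:
        raise ValueError("too few sites for leave-one-out with this predictor set")
    X = predictor_table[selected_predictors].to_numpy(dtype=float) if selected_predictors else np.empty((n, 0))
    y = np.log(y_raw) if log_scale else y_raw

    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            f = fit_ols(X[mask], y[mask], selected_predictors) if selected_predictors else None
        except RankDeficientError as exc:
            raise RankDeficientError(f"rank deficiency when holding out site {i}") from exc
        if f is None:
            preds[i] = y[mask].mean()
        else:
            preds[i] = float(f.predict(X[i][None, :])[0])
    if log_scale:
        preds = np.exp(preds)

    gap = y_raw - preds
    rmse = float(np.sqrt(np.mean(gap * gap)))
    if np.ptp(preds) > 0:
        reg = fit_ols(preds[:, None], y_raw, ["predicted"])
        r2, adj = float(reg.r2), float(reg.adj_r2)
    else:
        r2 = adj = 0.0
    return CVResult(measured=y_raw, predicted=preds, r2=r2, adjusted_r2=adj, rmse=rmse)


def vif(predictor_table: pd.DataFrame, selected_predictors: list[str]) -> tuple[pd.Series, float]:
    """VIF_k = 1/(1 - R^2 of predictor k regressed on the others).

    Perfect collinearity yields ``inf`` for the affected predictors rather
    than an exception.
    """
    if len(selected_predictors) < 2:
        raise ValueError("VIF needs at least 2 selected predictors")
    X = predictor_table[selected_predictors].to_numpy(dtype=float)
    out = {}
    for j, name in enumerate(selected_predictors):
        others = np.delete(X, j, axis=1)
        try:
            f = fit_ols(others, X[:, j])
            r2 = min(f.r2, 1.0)
        except RankDeficientError:
            r2 = 1.0
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    series = pd.Series(out, name="vif")
    return series, float(series.mean())


def cooks_distance(
    predictor_table: pd.DataFrame,
    log_response: np.ndarray | pd.Series,
    selected_predictors: list[str],
    threshold: float = 0.3,
) -> tuple[np.ndarray, float, list[int]]:
    """Classical Cook's D per observation for the selected-predictor OLS.

    Returns (per-site D, max D, indices exceeding ``threshold``). Sites with
    leverage 1 get ``nan`` (their D is undefined) and are excluded from the max.
    """
    y = np.asarray(log_response, dtype=float)
    X = predictor_table[selected_predictors].to_numpy(dtype=float)
    f = fit_ols(X, y, selected_predictors)
    h = hat_diagonal(X)
    k = len(selected_predictors) + 1
    s2 = f.rmse**2
    scale = max(1.0, float(np.abs(y).max()))
    if f.rmse <= 1e-12 * scale:  # perfect fit: D = 0 by definition, not 0/0
        d = np.where(h < 1.0 - 1e-12, 0.0, np.nan)
        return d, 0.0, []
    denom = (1.0 - h) ** 2
    d = np.full(len(y), np.nan)
    ok = h < 1.0 - 1e-12
    d[ok] = (f.residuals[ok] ** 2 / (k * s2)) * (h[ok] / denom[ok])
    finite = d[np.isfinite(d)]
    dmax = float(finite.max()) if finite.size else np.nan
    flagged = [int(i) for i in np.nonzero(np.nan_to_num(d) > threshold)[0]]
    return d, dmax, flagged


def spatial_weights(
    coordinates: np.ndarray,
    scheme: str = "inverse_distance",
    k: int = 8,
    band: float | None = None,
    row_standardize: bool = True,
) -> np.ndarray:
    """Spatial weight matrix with zero diagonal.

    ``inverse_distance`` (default) weights every pair by 1/d; ``knn`` links
    each site to its k nearest neighbours (binary, asymmetric); ``distance_band``
    links pairs closer than ``band`` metres (binary).
    """
    xy = np.asarray(coordinates, dtype=float)
    n = len(xy)
    d = np.hypot(xy[:, 0][:, None] - xy[:, 0], xy[:, 1][:, None] - xy[:, 1])
    if scheme == "inverse_distance":
        with np.errstate(divide="ignore"):
            w = 1.0 / d
        np.fill_diagonal(w, 0.0)
    elif scheme == "knn":
        w = np.zeros((n, n))
        order = np.argsort(d + np.diag(np.full(n, np.inf)), axis=1)
        rows = np.repeat(np.arange(n), k)
        w[rows, order[:, :k].ravel()] = 1.0
    elif scheme == "distance_band":
        if band is None:
            raise ValueError("distance_band scheme requires a band")
        w = ((d > 0) & (d <= band)).astype(float)
    else:
        raise ValueError(f"unknown weight scheme {scheme!r}")
    if row_standardize:
        sums = w.sum(axis=1, keepdims=True)
        w = np.divide(w, sums, out=np.zeros_like(w), where=sums > 0)
    return w


def morans_i(
    residuals: np.ndarray,
    coordinates: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    n_perm: int = 999,
    seed: int | None = None,
    method: str = "permutation",
    **weight_kwargs,
) -> MoranResult:
    """Moran's I of residuals with a permutation (default) or analytic p-value.

    I = (n/SW) * (z' W z)/(z' z) with z centred residuals and zero-diagonal
    weights W. The permutation p is two-sided around the exchangeability
    expectation -1/(n-1), computed as (count_extreme + 1)/(n_perm + 1).
    """
    z = np.asarray(residuals, dtype=float)
    n = len(z)
    if n < 4:
        raise ValueError("Moran's I needs at least 4 observations")
    if np.ptp(z) == 0:
        raise ValueError("residuals have zero variance; Moran's I undefined")
    if weights is None:
        if coordinates is None:
            raise ValueError("provide coordinates or a weight matrix")
        weights = spatial_weights(coordinates, **weight_kwargs)
    W = np.asarray(weights, dtype=float)
    if np.count_nonzero(W) < 2:
        raise ValueError("fewer than 2 nonzero spatial weights")
    z = z - z.mean()
    sw = W.sum()
    denom = float(z @ z)
    scale = n / (sw * denom)
    i_obs = float(scale * (z @ W @ z))
    e_i = -1.0 / (n - 1)

    p_perm = None
    p_analytic = None
    if method == "permutation":
        rng = np.random.default_rng(seed)
        Z = np.tile(z, (n_perm, 1))
        Z = rng.permuted(Z, axis=1)
        i_perm = scale * np.einsum("ij,ij->i", Z @ W.T, Z)
        extreme = np.abs(i_perm - e_i) >= np.abs(i_obs - e_i) - 1e-15
        p_perm = float((extreme.sum() + 1) / (n_perm + 1))
    elif method == "analytic":
        # normal approximation under the randomisation assumption
        s0 = sw
        s1 = 0.5 * np.sum((W + W.T) ** 2)
        s2 = np.sum((W.sum(axis=0) + W.sum(axis=1)) ** 2)
        b2 = n * np.sum(z**4) / denom**2
        var = (
            n * ((n**2 - 3 * n + 3) * s1 - n * s2 + 3 * s0**2)
            - b2 * ((n**2 - n) * s1 - 2 * n * s2 + 6 * s0**2)
        ) / ((n - 1) * (n - 2) * (n - 3) * s0**2) - e_i**2
        zstat = (i_obs - e_i) / np.sqrt(var)
        p_analytic = float(2 * stats.norm.sf(abs(zstat)))
        n_perm = 0
    else:
        raise ValueError(f"unknown method {method!r}")
    return MoranResult(I=i_obs, expected_I=e_i, p_perm=p_perm, n_perm=n_perm, p_analytic=p_analytic)


@dataclass
class CrossPeriodResult:
    r_overall: float
    r_by_site_type: dict[str, float]
    scatter: pd.DataFrame = field(repr=False)


def cross_period_predict(
    model: LURModel,
    measurements: pd.Series,
    predictor_table: pd.DataFrame,
    site_types: pd.Series | None = None,
) -> CrossPeriodResult:
    """Predict another campaign's sites with this model; correlate with its data.

    ``measurements`` and ``predictor_table`` must be aligned row-for-row
    (indexed by site id); correlations are Pearson, overall and per site type.
    """
    if len(measurements) < 3:
        raise ValueError("cross-period comparison needs >= 3 sites")
    pred = predict_no2(model, predictor_table)
    meas = np.asarray(measurements, dtype=float)
    r = float(stats.pearsonr(pred, meas).statistic)
    by_type: dict[str, float] = {}
    if site_types is not None:
        st = np.asarray(site_types)
        for t in pd.unique(st):
            m = st == t
            if m.sum() >= 3:
                by_type[str(t)] = float(stats.pearsonr(pred[m], meas[m]).statistic)
    scatter = pd.DataFrame(
        {"site_id": measurements.index, "measured": meas, "predicted": pred}
    )
    return CrossPeriodResult(r_overall=r, r_by_site_type=by_type, scatter=scatter)
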