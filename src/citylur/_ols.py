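"""Small ordinary-least-squares core shared by the regression modules.

Fits y = X b with an explicit intercept column, and reports the classical
t-based inference (two-sided p-values on n - k residual degrees of freedom)
plus the fit statistics the exposure models need: R^2, adjusted R^2 and the
root mean square error computed with the n - k denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class RankDeficientError(np.linalg.LinAlgError):
    """Design matrix is numerically rank deficient."""


@dataclass
class OLSFit:
    names: list[str]              # regressor names, "(intercept)" first
    coef: np.ndarray              # shape (k,)
    se: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray           # two-sided, df = n - k
    fitted: np.ndarray
    residuals: np.ndarray
    r2: float
    adj_r2: float
    rmse: float                   # sqrt(SSE / (n - k))
    n: int
    df_resid: int
    xtx_inv: np.ndarray = field(repr=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return np.column_stack([np.ones(len(X)), X]) @ self.coef


def fit_ols(X: np.ndarray, y: np.ndarray, names: list[str] | None = None) -> OLSFit:
    """OLS of ``y`` on ``X`` (columns = regressors; intercept added here)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and len(y) == X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if names is None:
        names = [f"x{i}" for i in range(p)]
    D = np.column_stack([np.ones(n), X])
    k = D.shape[1]
    if n <= k:
        raise RankDeficientError(f"{n} observations cannot identify {k} coefficients")
    if np.linalg.matrix_rank(D) < k:
        raise RankDeficientError("design matrix is rank deficient")
    xtx = D.T @ D
    xtx_inv = np.linalg.inv(xtx)
    coef = xtx_inv @ (D.T @ y)
    fitted = D @ coef
    resid = y - fitted
    df = n - k
    sse = float(resid @ resid)
    sigma2 = sse / df
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, coef / se, np.inf * np.sign(coef))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / df if sst > 0 else 1.0
    return OLSFit(
        names=["(intercept)", *names],
        coef=coef,
        se=se,
        tvalues=tvals,
        pvalues=pvals,
        fitted=fitted,
        residuals=resid,
        r2=r2,
        adj_r2=adj_r2,
        rmse=float(np.sqrt(sigma2)),
        n=n,
        df_resid=df,
        xtx_inv=xtx_inv,
    )


def hat_diagonal(X: np.ndarray) -> np.ndarray:
    """Leverages h_ii of the intercept-augmented design."""
    X = np.asarray(X, dtype=float)
    D = np.column_stack([np.ones(len(X)), X])
    Q, _ = np.linalg.qr(D)
    return np.sum(Q * Q, axis=1)
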