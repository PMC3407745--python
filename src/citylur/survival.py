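"""Cox proportional-hazards regression with a self-contained maximizer.

The partial likelihood is maximised by Newton-Raphson with the Efron tie
correction by default (Breslow optional); covariance is the inverse observed
information, and confidence intervals are Wald intervals on the log scale.
Exposure can enter as a linear term (per ug/m3), as quintile dummies, or as
dummies for the four fixed concentration classes; categorical adjusters are
reference-coded against their most frequent level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exposure import FIXED4_LABELS, categorize_exposure

Z95 = stats.norm.ppf(0.975)


class ConvergenceError(RuntimeError):
    pass


class DegenerateDesignError(ValueError):
    pass


@dataclass
class CoxFit:
    names: list[str]
    coef: np.ndarray
    cov: np.ndarray = field(repr=False)
    se: np.ndarray
    hr: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    pvalues: np.ndarray
    n_subjects: int
    n_events: int
    ties: str
    loglik: float
    n_iter: int
    exposure_terms: list[str]
    exposure_values: np.ndarray | None = field(default=None, repr=False)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "hr": self.hr,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p": self.pvalues,
            },
            index=self.names,
        )


def _newton_cox(
    times: np.ndarray, events: np.ndarray, X: np.ndarray, ties: str, max_iter: int = 60
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Maximise the log partial likelihood; returns (beta, cov, ll, iters)."""
    order = np.argsort(times, kind="stable")
    t, d, X = times[order], events[order].astype(bool), X[order]
    n, p = X.shape

    # event-time groups over the sorted array
    ev_idx = np.nonzero(d)[0]
    ev_times = t[ev_idx]
    grp_starts = np.nonzero(np.r_[True, np.diff(ev_times) > 0])[0]
    groups = np.split(ev_idx, grp_starts[1:])
    # first sorted index belonging to each group's risk set
    risk_first = np.array([np.searchsorted(t, t[g[0]], side="left") for g in groups])

    def _quantities(beta: np.ndarray):
        lp = X @ beta
        lp -= lp.max()  # guards overflow; cancels in all ratios
        w = np.exp(lp)
        wX = w[:, None] * X
        cum0 = np.cumsum(w[::-1])[::-1]
        cum1 = np.cumsum(wX[::-1], axis=0)[::-1]
        wXX = np.einsum("ij,ik->ijk", wX, X)
        cum2 = np.cumsum(wXX[::-1], axis=0)[::-1]

        ll = 0.0
        grad = np.zeros(p)
        info = np.zeros((p, p))
        for g, f in zip(groups, risk_first):
            dsz = len(g)
            s0r, s1r, s2r = cum0[f], cum1[f], cum2[f]
            ll += float(lp[g].sum())
            grad += X[g].sum(axis=0)
            if ties == "efron" and dsz > 1:
                s0t = w[g].sum()
                s1t = wX[g].sum(axis=0)
                s2t = wXX[g].sum(axis=0)
                for l in range(dsz):
                    fr = l / dsz
                    den = s0r - fr * s0t
                    nu1 = s1r - fr * s1t
                    nu2 = s2r - fr * s2t
                    ll -= np.log(den)
                    grad -= nu1 / den
                    info += nu2 / den - np.outer(nu1, nu1) / den**2
            else:  # breslow, or a single event where both coincide
                ll -= dsz * np.log(s0r)
                grad -= dsz * s1r / s0r
                info += dsz * (s2r / s0r - np.outer(s1r, s1r) / s0r**2)

        if not np.isfinite(ll):
            raise ConvergenceError("log partial likelihood is not finite")
        return ll, grad, info

    beta = np.zeros(p)
    ll, grad, info = _quantities(beta)
    for it in range(1, max_iter + 1):
        converged = np.max(np.abs(grad)) < 1e-8
        if converged:
            break
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise DegenerateDesignError("singular information matrix") from exc
        # step-halving keeps the likelihood ascending
        shrink = 1.0
        while True:
            beta_new = beta + shrink * step
            if np.any(np.abs(beta_new) > 20):
                raise ConvergenceError(
                    "estimate diverging (|coef| > 20); likely monotone likelihood / separation"
                )
            ll_new, grad_new, info_new = _quantities(beta_new)
            if ll_new >= ll - 1e-12 or shrink < 1e-4:
                break
            shrink *= 0.5
        if abs(ll_new - ll) <= 1e-10 * max(1.0, abs(ll)) and np.max(np.abs(grad_new)) < 1e-6:
            beta, ll, grad, info = beta_new, ll_new, grad_new, info_new
            break
        beta, ll, grad, info = beta_new, ll_new, grad_new, info_new
    else:
        if np.max(np.abs(grad)) >= 1e-6:
            raise ConvergenceError(f"Newton-Raphson did not converge in {max_iter} iterations")
    cov = np.linalg.inv(info)
    # a huge coefficient with a flat likelihood is monotone-likelihood
    # divergence that happened to meet the gradient tolerance
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    if np.any((np.abs(beta) > 10) & (se > 10)):
        raise ConvergenceError(
            "estimate diverging (flat partial likelihood); likely monotone likelihood / separation"
        )
    return beta, cov, float(ll), it


def _reference_code(series: pd.Series, prefix: str) -> tuple[np.ndarray, list[str]]:
    counts = series.value_counts()
    ref = counts.index[0]  # most frequent level is the reference
    levels = [lv for lv in counts.index if lv != ref]
    cols = np.column_stack([(series == lv).to_numpy(float) for lv in levels]) if levels else np.empty((len(series), 0))
    return cols, [f"{prefix}[{lv}]" for lv in levels]


def _exposure_columns(
    exposure: np.ndarray, coding: str
) -> tuple[np.ndarray, list[str]]:
    x = np.asarray(exposure, dtype=float)
    if coding == "linear":
        return x[:, None], ["exposure"]
    if coding == "quintiles":
        g = categorize_exposure(x, "quintiles")
        labels = [f"exposure_q{k}" for k in range(2, 6)]
        cols = np.column_stack([(g == k).astype(float) for k in range(2, 6)])
        return cols, labels
    if coding == "fixed4":
        g = categorize_exposure(x, "fixed4")
        present = sorted(np.unique(g))
        ref = present[0]
        keep = [k for k in present if k != ref]
        cols = np.column_stack([(g == k).astype(float) for k in keep]) if keep else np.empty((len(x), 0))
        return cols, [f"exposure_cat[{FIXED4_LABELS[k - 1]}]" for k in keep]
    raise ValueError(f"unknown exposure coding {coding!r}")


def build_design(
    data: pd.DataFrame,
    exposure_col: str,
    exposure_coding: str,
    covariates: list[str],
) -> tuple[np.ndarray, list[str], list[str]]:
    """(X, column names, exposure column names)."""
    xcols, xnames = _exposure_columns(data[exposure_col].to_numpy(float), exposure_coding)
    blocks = [xcols]
    names = list(xnames)
    for cov in covariates:
        s = data[cov]
        if s.dtype.kind in "OUSb" or s.nunique() <= 10:
            cols, nm = _reference_code(s.astype(str) if s.dtype.kind not in "OUS" else s, cov)
        else:
            cols, nm = s.to_numpy(float)[:, None], [cov]
        blocks.append(cols)
        names.extend(nm)
    X = np.hstack(blocks)
    return X, names, xnames


def fit_cox(
    data: pd.DataFrame,
    exposure_col: str,
    exposure_coding: str = "linear",
    covariates: list[str] | None = None,
    duration_col: str = "followup_time",
    event_col: str = "event",
    ties: str = "efron",
) -> CoxFit:
    """Cox PH fit of mortality on exposure plus categorical adjusters."""
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    covariates = covariates or []
    times = data[duration_col].to_numpy(float)
    events = data[event_col].to_numpy(bool)
    if events.sum() == 0:
        raise ValueError("no events; Cox model unidentifiable")
    X, names, xnames = build_design(data, exposure_col, exposure_coding, covariates)
    spans = np.ptp(X, axis=0)
    if np.any(spans == 0):
        flat = [names[i] for i in np.nonzero(spans == 0)[0]]
        raise DegenerateDesignError(f"constant design columns: {flat}")

    beta, cov, ll, it = _newton_cox(times, events, X, ties)
    se = np.sqrt(np.diag(cov))
    hr = np.exp(beta)
    z = beta / se
    return CoxFit(
        names=names,
        coef=beta,
        cov=cov,
        se=se,
        hr=hr,
        ci_lower=np.exp(beta - Z95 * se),
        ci_upper=np.exp(beta + Z95 * se),
        pvalues=2 * stats.norm.sf(np.abs(z)),
        n_subjects=len(data),
        n_events=int(events.sum()),
        ties=ties,
        loglik=ll,
        n_iter=it,
        exposure_terms=xnames,
        exposure_values=data[exposure_col].to_numpy(float) if exposure_coding == "linear" else None,
    )


def hr_for_increment(fit: CoxFit, delta: float | None = None, iqr: bool = False) -> dict:
    """HR (with CI) for a ``delta``-unit increase of a linear exposure term.

    ``iqr=True`` sets delta to Q75 - Q25 of the analysis population's
    exposure. Hazard ratios scale log-linearly, so HR(delta) = exp(coef*delta)
    and the CI endpoints transform identically.
    """
    if fit.exposure_terms != ["exposure"]:
        raise ValueError("increment HRs require a linear exposure term")
    i = fit.names.index("exposure")
    if iqr:
        if fit.exposure_values is None:
            raise ValueError("fit carries no exposure vector for IQR computation")
        delta = float(np.quantile(fit.exposure_values, 0.75) - np.quantile(fit.exposure_values, 0.25))
    if delta is None or delta < 0:
        raise ValueError("delta must be a non-negative increment")
    b, s = fit.coef[i], fit.se[i]
    return {
        "delta": delta,
        "hr": float(np.exp(b * delta)),
        "ci_lower": float(np.exp((b - Z95 * s) * delta)),
        "ci_upper": float(np.exp((b + Z95 * s) * delta)),
    }


def trend_across_categories(
    data: pd.DataFrame,
    category_labels: np.ndarray,
    covariates: list[str] | None = None,
    duration_col: str = "followup_time",
    event_col: str = "event",
    ties: str = "efron",
) -> tuple[float, CoxFit]:
    """Wald p for an ordinal score (0,1,2,...) replacing the category dummies."""
    cats = np.asarray(category_labels)
    levels = np.unique(cats)
    if len(levels) < 3:
        raise ValueError("trend requires >= 3 ordered categories")
    score = np.searchsorted(levels, cats).astype(float)
    df = data.copy()
    df["_ordinal_score"] = score
    fit = fit_cox(
        df, "_ordinal_score", "linear", covariates,
        duration_col=duration_col, event_col=event_col, ties=ties,
    )
    i = fit.names.index("exposure")
    return float(fit.pvalues[i]), fit
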