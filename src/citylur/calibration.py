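"""Alignment of two passive-sampler types via co-located measurements.

Diffusion samplers of different designs respond approximately affinely to the
same true concentration, so measurements from a source device are mapped onto
the target device's scale with an ordinary least squares line fitted to
co-located pairs (target regressed on source). Agreement between paired series
is summarised with Bland-Altman statistics.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class CalibrationModel:
    slope: float
    intercept: float
    r: float
    r2: float
    n_pairs: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class BlandAltman:
    mean_diff: float
    sd_diff: float          # n-1 denominator
    loa_lower: float        # mean - 1.96 sd
    loa_upper: float
    n_pairs: int


def fit_calibration(source: np.ndarray, target: np.ndarray) -> CalibrationModel:
    """OLS of target-device values on source-device values at shared sites."""
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape or source.ndim != 1:
        raise ValueError("source and target must be 1-d arrays of equal length")
    n = len(source)
    if n < 3:
        raise ValueError(f"calibration needs >= 3 co-located pairs, got {n}")
    if np.ptp(source) == 0:
        raise ValueError("source values are constant; calibration line is unidentifiable")
    res = stats.linregress(source, target)
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        r2=float(res.rvalue) ** 2,
        n_pairs=n,
    )


def apply_calibration(model: CalibrationModel, values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    return model.slope * values + model.intercept


def bland_altman(first: np.ndarray, second: np.ndarray) -> BlandAltman:
    """Mean difference (first - second), its sd, and 95% limits of agreement."""
    first = np.asarray(first, dtype=float)
    second = np.asarray(second, dtype=float)
    if first.shape != second.shape or first.ndim != 1:
        raise ValueError("paired series must be 1-d arrays of equal length")
    if len(first) < 2:
        raise ValueError("Bland-Altman needs at least 2 pairs")
    d = first - second
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(
        mean_diff=mean,
        sd_diff=sd,
        loa_lower=mean - 1.96 * sd,
        loa_upper=mean + 1.96 * sd,
        n_pairs=len(d),
    )
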