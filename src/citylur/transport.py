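"""Two-campaign stability report.

Summarises how stable the spatial pollution contrast is across campaigns
taken years apart: correlation of measurements at shared sites (overall and
by site type), prospective and retrospective cross-period prediction
correlations, correlation of the two models' predictions at cohort addresses,
and Bland-Altman agreement at the shared sites.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import bland_altman
from .lur import LURModel
from .validation import cross_period_predict


@dataclass
class StabilityReport:
    r_measured_shared_sites: float
    r_measured_by_site_type: dict[str, float]
    r_prospective: float            # model 1 predictions vs campaign-2 measurements
    r_prospective_by_site_type: dict[str, float]
    r_retrospective: float          # model 2 predictions vs campaign-1 measurements
    r_retrospective_by_site_type: dict[str, float]
    r_assigned_addresses: float     # model 1 vs model 2 predictions at addresses
    bland_altman_shared: dict
    n_shared_sites: int
    model_summaries: dict = field(default_factory=dict)
    scatter_panels: dict[str, pd.DataFrame] = field(default_factory=dict, repr=False)

    def to_json(self) -> str:
        d = asdict(self)
        d.pop("scatter_panels")
        return json.dumps(d, indent=2, default=float)

    @staticmethod
    def from_json(text: str) -> "StabilityReport":
        d = json.loads(text)
        return StabilityReport(**d, scatter_panels={})


def _r(a, b) -> float:
    return float(stats.pearsonr(np.asarray(a, float), np.asarray(b, float)).statistic)


def build_stability_report(
    means_1: pd.Series,
    means_2: pd.Series,
    sites_1: pd.DataFrame,
    sites_2: pd.DataFrame,
    model_1: LURModel,
    model_2: LURModel,
    predictors_1: pd.DataFrame,
    predictors_2: pd.DataFrame,
    assigned_1: np.ndarray,
    assigned_2: np.ndarray,
) -> StabilityReport:
    """All four comparison panels plus Bland-Altman on the shared sites.

    ``means_*`` are per-site annual values indexed by site id;
    ``predictors_*`` are predictor tables indexed identically; assignments are
    the two models' predictions at the same cohort addresses. Shared sites are
    matched by site id (ids are stable across campaigns).
    """
    shared = means_1.index.intersection(means_2.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared sites between campaigns")
    m1 = means_1.loc[shared]
    m2 = means_2.loc[shared]
    types = sites_1.set_index("site_id").loc[shared, "site_type"]

    by_type_meas: dict[str, float] = {}
    for t in types.unique():
        sel = types == t
        if sel.sum() >= 3:
            by_type_meas[str(t)] = _r(m1[sel.to_numpy()], m2[sel.to_numpy()])

    cp_pro = cross_period_predict(
        model_1, means_2, predictors_2, sites_2.set_index("site_id").loc[means_2.index, "site_type"]
    )
    cp_retro = cross_period_predict(
        model_2, means_1, predictors_1, sites_1.set_index("site_id").loc[means_1.index, "site_type"]
    )
    ba = bland_altman(np.asarray(m1, float), np.asarray(m2, float))

    panels = {
        "A_shared_measurements": pd.DataFrame(
            {"site_id": shared, "campaign1": m1.to_numpy(), "campaign2": m2.to_numpy(),
             "site_type": types.to_numpy()}
        ),
        "B_prospective": cp_pro.scatter,
        "C_retrospective": cp_retro.scatter,
        "D_assigned_addresses": pd.DataFrame(
            {"model1": np.asarray(assigned_1, float), "model2": np.asarray(assigned_2, float)}
        ),
    }
    return StabilityReport(
        r_measured_shared_sites=_r(m1, m2),
        r_measured_by_site_type=by_type_meas,
        r_prospective=cp_pro.r_overall,
        r_prospective_by_site_type=cp_pro.r_by_site_type,
        r_retrospective=cp_retro.r_overall,
        r_retrospective_by_site_type=cp_retro.r_by_site_type,
        r_assigned_addresses=_r(assigned_1, assigned_2),
        bland_altman_shared=asdict(ba),
        n_shared_sites=int(len(shared)),
        model_summaries={
            "model_1": {"adjusted_r2": model_1.adjusted_r2, "rmse_log": model_1.rmse_log,
                        "n_sites": model_1.n_sites, "predictors": list(model_1.predictors)},
            "model_2": {"adjusted_r2": model_2.adjusted_r2, "rmse_log": model_2.rmse_log,
                        "n_sites": model_2.n_sites, "predictors": list(model_2.predictors)},
        },
        scatter_panels=panels,
    )
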