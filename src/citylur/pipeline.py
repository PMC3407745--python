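"""Configuration-driven end-to-end study runner.

Generates the synthetic study system, builds the two campaign exposure models,
validates and compares them, assigns exposures to the cohort, and fits the
mortality models — writing every stage's artifacts as plain-text files when an
output directory is given. All randomness flows from one global seed through
stable per-stage seeds, so a rerun with the same configuration reproduces
every number bit for bit.
"""

from __future__ import annotations

import hashlib
import logging
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from .calibration import bland_altman, fit_calibration
from .exposure import assign_exposure, categorize_exposure, cuzick_trend, gender_difference, stratified_summary
from .lur import backward_stepwise_fit, site_period_mean
from .predictors import DEFAULT_SIGNS, assemble_predictor_table
from .survival import fit_cox, hr_for_increment, trend_across_categories
from .synthetic import (
    DEFAULT_PERIOD_EFFECTS,
    DISTORTED_SAMPLER,
    REFERENCE_SAMPLER,
    CityConfig,
    SurfaceParams,
    generate_city,
    place_sites,
    simulate_campaign,
    simulate_cohort,
    simulate_colocated_pairs,
    simulate_true_surface,
)

log = logging.getLogger("citylur")

STAGES = (
    "simulate", "predictors", "calibrate", "means", "fit-lur",
    "validate", "assign", "transport", "summarize", "cox", "report",
)


@dataclass
class PipelineConfig:
    seed: int = 0
    city: CityConfig = field(default_factory=CityConfig)
    surface: SurfaceParams = field(default_factory=SurfaceParams)
    n_background_1: int = 46
    n_traffic_1: int = 24
    extra_background_2: int = 3
    extra_traffic_2: int = 7
    extra_regional_2: int = 1
    n_colocated: int = 27
    periods: int = 3
    missing_rate: float = 3.0 / 70.0
    cohort_n: int = 20_000
    beta_no2_per10: float = math.log(1.06)
    confounding_strength: float = 0.6
    horizon_years: float = 5.2
    p_remove: float = 0.20
    n_perm_moran: int = 999
    cox_covariates: tuple[str, ...] = (
        "age_band", "gender", "marital_status", "place_of_birth",
        "education", "occupation", "sep",
    )

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        city = CityConfig(**raw.pop("city", {}))
        surface = SurfaceParams(**raw.pop("surface", {}))
        return PipelineConfig(city=city, surface=surface, **raw)


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage stream: adding stages never shifts earlier streams."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path | None = None, last_stage: str = "report"
) -> dict:
    """Execute the stages in order up to ``last_stage``; returns all results."""
    if last_stage not in STAGES:
        raise ValueError(f"unknown stage {last_stage!r}")
    cutoff = STAGES.index(last_stage)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    res: dict = {"config": config}
    sd = lambda name: stage_seed(config.seed, name)  # noqa: E731

    def done(stage: str) -> bool:
        return STAGES.index(stage) >= cutoff

    # --- simulate -----------------------------------------------------------
    log.info("stage simulate")
    city = generate_city(config.city, sd("city"))
    surface = simulate_true_surface(city, config.surface, sd("surface"))
    sites1 = place_sites(city, config.n_background_1, config.n_traffic_1, seed=sd("sites1"))
    extra = place_sites(
        city, config.extra_background_2, config.extra_traffic_2, config.extra_regional_2,
        seed=sd("sites2"), start_id=len(sites1) + 1,
    )
    campaign1 = simulate_campaign(
        city, surface, sites1, config.periods, DISTORTED_SAMPLER, 1,
        seed=sd("campaign1"), period_effects=DEFAULT_PERIOD_EFFECTS[: config.periods],
        missing_rate=config.missing_rate,
    )
    means1_raw, retained1, dropped1 = site_period_mean(campaign1.records, config.periods)
    sites1_kept = sites1[sites1["site_id"].isin(retained1)].reset_index(drop=True)
    sites2 = pd.concat([sites1_kept, extra], ignore_index=True)
    campaign2 = simulate_campaign(
        city, surface, sites2, config.periods, REFERENCE_SAMPLER, 2,
        seed=sd("campaign2"), period_effects=DEFAULT_PERIOD_EFFECTS[: config.periods],
    )
    rng_pairs = np.random.default_rng(sd("colocated"))
    pair_ids = rng_pairs.choice(
        sites1_kept["site_id"].to_numpy(), size=min(config.n_colocated, len(sites1_kept)), replace=False
    )
    pair_sites = sites2[sites2["site_id"].isin(pair_ids)].reset_index(drop=True)
    pairs = simulate_colocated_pairs(
        pair_sites, surface, REFERENCE_SAMPLER, DISTORTED_SAMPLER, seed=sd("pairs")
    )
    cohort, truth = simulate_cohort(
        city, surface, config.cohort_n, config.beta_no2_per10,
        confounding_strength=config.confounding_strength,
        horizon_years=config.horizon_years, seed=sd("cohort"),
    )
    res.update(
        city=city, surface=surface, sites1=sites1, sites2=sites2, campaign1=campaign1,
        campaign2=campaign2, pairs=pairs, cohort=cohort, ground_truth=truth,
        dropped_sites_1=dropped1,
    )
    if out is not None:
        cio.write_scene(city, out / "scene", config.city)
        cio.write_measurements(campaign1, out, "campaign1")
        cio.write_measurements(campaign2, out, "campaign2")
        pairs.to_csv(out / "colocated_pairs.csv", index=False)
        cohort.to_csv(out / "cohort.csv", index=False)
        cio.write_json(truth, out / "ground_truth.json")
    if done("simulate"):
        return res

    # --- predictors ---------------------------------------------------------
    log.info("stage predictors")
    pred1 = assemble_predictor_table(sites1_kept[["x", "y"]].to_numpy(), city)
    pred1.index = sites1_kept["site_id"]
    pred2 = assemble_predictor_table(sites2[["x", "y"]].to_numpy(), city)
    pred2.index = sites2["site_id"]
    res.update(predictors1=pred1, predictors2=pred2)
    if out is not None:
        pred1.to_csv(out / "predictors_campaign1.csv")
        pred2.to_csv(out / "predictors_campaign2.csv")
    if done("predictors"):
        return res

    # --- calibrate ----------------------------------------------------------
    log.info("stage calibrate")
    calib = fit_calibration(pairs["value_b"].to_numpy(), pairs["value_a"].to_numpy())
    ba_pairs = bland_altman(pairs["value_a"].to_numpy(), pairs["value_b"].to_numpy())
    rec1 = campaign1.records.copy()
    rec1["value"] = calib.slope * rec1["value"] + calib.intercept
    res.update(calibration=calib, bland_altman_pairs=ba_pairs, campaign1_calibrated_records=rec1)
    if out is not None:
        cio.write_json(calib.to_dict(), out / "calibration.json")
    if done("calibrate"):
        return res

    # --- means --------------------------------------------------------------
    means1, _, _ = site_period_mean(rec1, config.periods)
    means2, _, _ = site_period_mean(campaign2.records, config.periods)
    means1 = means1.loc[pred1.index]
    means2 = means2.loc[pred2.index]
    res.update(means1=means1, means2=means2)
    if out is not None:
        means1.rename("value").to_csv(out / "annual_means_campaign1.csv")
        means2.rename("value").to_csv(out / "annual_means_campaign2.csv")
    if done("means"):
        return res

    # --- fit-lur ------------------------------------------------------------
    log.info("stage fit-lur")
    model1 = backward_stepwise_fit(pred1, np.log(means1.to_numpy()), DEFAULT_SIGNS,
                                   p_remove=config.p_remove, campaign=1)
    model2 = backward_stepwise_fit(pred2, np.log(means2.to_numpy()), DEFAULT_SIGNS,
                                   p_remove=config.p_remove, campaign=2)
    res.update(model1=model1, model2=model2)
    if out is not None:
        cio.write_model(model1, out / "lur_model1.json")
        cio.write_model(model2, out / "lur_model2.json")
    if done("fit-lur"):
        return res

    # --- validate -----------------------------------------------------------
    log.info("stage validate")
    from .validation import cooks_distance, loocv, morans_i, vif

    validation = {}
    for tag, (model, pred, means, sites) in {
        "model1": (model1, pred1, means1, sites1_kept),
        "model2": (model2, pred2, means2, sites2),
    }.items():
        cv = loocv(pred, means.to_numpy(), model.predictors)
        resid = np.log(means.to_numpy()) - (
            model.intercept
            + sum(model.coefficients[p] * pred[p].to_numpy() for p in model.predictors)
        )
        moran = morans_i(
            resid, sites[["x", "y"]].to_numpy(), n_perm=config.n_perm_moran,
            seed=stage_seed(config.seed, f"moran-{tag}"),
        )
        d, dmax, flagged = cooks_distance(pred, np.log(means.to_numpy()), model.predictors)
        entry = {
            "cv_r2": cv.r2, "cv_adjusted_r2": cv.adjusted_r2, "cv_rmse": cv.rmse,
            "moran_I": moran.I, "moran_p": moran.p_perm, "cooks_max": dmax,
            "cooks_flagged": flagged,
        }
        if len(model.predictors) >= 2:
            v, vmean = vif(pred, model.predictors)
            entry["vif"] = v.to_dict()
            entry["vif_mean"] = vmean
        validation[tag] = entry
    res["validation"] = validation
    if out is not None:
        cio.write_json(validation, out / "validation.json")
    if done("validate"):
        return res

    # --- assign -------------------------------------------------------------
    log.info("stage assign")
    addr_pred = assemble_predictor_table(cohort[["x", "y"]].to_numpy(), city)
    exp1 = assign_exposure(model1, cohort, addr_pred)
    exp2 = assign_exposure(model2, cohort, addr_pred)
    cohort_exp = cohort.copy()
    cohort_exp["no2_model1"] = exp1
    cohort_exp["no2_model2"] = exp2
    for m in ("1", "2"):
        cohort_exp[f"quintile_model{m}"] = categorize_exposure(cohort_exp[f"no2_model{m}"].to_numpy(), "quintiles")
        cohort_exp[f"fixed4_model{m}"] = categorize_exposure(cohort_exp[f"no2_model{m}"].to_numpy(), "fixed4")
    res["cohort_exposed"] = cohort_exp
    if out is not None:
        cohort_exp.to_csv(out / "cohort_with_exposure.csv", index=False)
    if done("assign"):
        return res

    # --- transport ----------------------------------------------------------
    log.info("stage transport")
    from .transport import build_stability_report

    stability = build_stability_report(
        means1, means2, sites1_kept, sites2, model1, model2, pred1, pred2, exp1, exp2
    )
    res["stability"] = stability
    if out is not None:
        (out / "stability_report.json").write_text(stability.to_json())
        for name, panel in stability.scatter_panels.items():
            panel.to_csv(out / f"panel_{name}.csv", index=False)
    if done("transport"):
        return res

    # --- summarize ----------------------------------------------------------
    log.info("stage summarize")
    summaries = {}
    for m in ("1", "2"):
        vals = cohort_exp[f"no2_model{m}"].to_numpy()
        tab = stratified_summary(vals, cohort_exp[["gender", "age_band", "sep"]])
        trend_age = cuzick_trend(vals, cohort_exp["age_band"].to_numpy())
        trend_sep = cuzick_trend(vals, cohort_exp["sep"].to_numpy())
        tstat, tp = gender_difference(vals, cohort_exp["gender"].to_numpy())
        summaries[f"model{m}"] = {
            "table": tab, "p_trend_age": trend_age.p_value, "p_trend_sep": trend_sep.p_value,
            "gender_t": tstat, "gender_p": tp,
        }
        if out is not None:
            tab.to_csv(out / f"exposure_summary_model{m}.csv", index=False)
    res["summaries"] = summaries
    if done("summarize"):
        return res

    # --- cox ----------------------------------------------------------------
    log.info("stage cox")
    covs = list(config.cox_covariates)
    cox_results = {}
    for m in ("1", "2"):
        col = f"no2_model{m}"
        lin = fit_cox(cohort_exp, col, "linear", covs)
        per10 = hr_for_increment(lin, delta=10.0)
        per_iqr = hr_for_increment(lin, iqr=True)
        quint = fit_cox(cohort_exp, col, "quintiles", covs)
        fixed = fit_cox(cohort_exp, col, "fixed4", covs)
        p_trend_q, _ = trend_across_categories(
            cohort_exp, cohort_exp[f"quintile_model{m}"].to_numpy(), covs
        )
        p_trend_f, _ = trend_across_categories(
            cohort_exp, cohort_exp[f"fixed4_model{m}"].to_numpy(), covs
        )
        cox_results[f"model{m}"] = {
            "linear": lin, "per10": per10, "per_iqr": per_iqr,
            "quintiles": quint, "fixed4": fixed,
            "p_trend_quintiles": p_trend_q, "p_trend_fixed4": p_trend_f,
        }
    res["cox"] = cox_results
    if out is not None:
        rows = []
        for m, r in cox_results.items():
            for coding in ("quintiles", "fixed4"):
                f = r[coding]
                for name, hr, lo, hi in zip(f.names, f.hr, f.ci_lower, f.ci_upper):
                    if name.startswith("exposure"):
                        rows.append({"model": m, "coding": coding, "term": name,
                                     "hr": hr, "ci_lower": lo, "ci_upper": hi})
            rows.append({"model": m, "coding": "per10", "term": "exposure",
                         "hr": r["per10"]["hr"], "ci_lower": r["per10"]["ci_lower"],
                         "ci_upper": r["per10"]["ci_upper"]})
            rows.append({"model": m, "coding": "per_iqr", "term": "exposure",
                         "hr": r["per_iqr"]["hr"], "ci_lower": r["per_iqr"]["ci_lower"],
                         "ci_upper": r["per_iqr"]["ci_upper"]})
        pd.DataFrame(rows).to_csv(out / "hazard_ratios.csv", index=False)
    if done("cox"):
        return res

    # --- report -------------------------------------------------------------
    log.info("stage report")
    summary = {
        "seed": config.seed,
        "n_sites_campaign1": int(len(means1)),
        "n_sites_campaign2": int(len(means2)),
        "calibration": calib.to_dict(),
        "model1": {"predictors": model1.predictors, "adjusted_r2": model1.adjusted_r2,
                   "rmse_log": model1.rmse_log},
        "model2": {"predictors": model2.predictors, "adjusted_r2": model2.adjusted_r2,
                   "rmse_log": model2.rmse_log},
        "validation": validation,
        "stability": {
            "r_measured_shared_sites": stability.r_measured_shared_sites,
            "r_prospective": stability.r_prospective,
            "r_retrospective": stability.r_retrospective,
            "r_assigned_addresses": stability.r_assigned_addresses,
        },
        "cox": {
            m: {"per10_hr": r["per10"]["hr"], "per_iqr_hr": r["per_iqr"]["hr"],
                "p_trend_quintiles": r["p_trend_quintiles"]}
            for m, r in cox_results.items()
        },
        "ground_truth_hr_per10": truth["hr_per10"],
    }
    res["summary"] = summary
    if out is not None:
        cio.write_json(summary, out / "summary.json")
        digest = hashlib.sha256(cio.json.dumps(summary, sort_keys=True, default=float).encode()).hexdigest()
        (out / "summary.sha256").write_text(digest)
        res["summary_checksum"] = digest
    else:
        res["summary_checksum"] = hashlib.sha256(
            cio.json.dumps(summary, sort_keys=True, default=float).encode()
        ).hexdigest()
    return res
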