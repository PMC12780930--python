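"""End-to-end orchestration: simulate -> cohort -> match -> survival ->
reallocate -> report, plus descriptive trend tabulations.

The run produces CSV artifacts for each stage and a machine-readable
``summary.json`` holding the Kaplan-Meier survival at the horizon per
exposure arm, the log-rank p-value, Cox hazard-ratio tables for the
full cohort and the 1- and 5-year landmarks, the covariate-balance
table, and the reallocation wait-time summary per distance ceiling.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from . import psm as psm_mod
from . import reallocation as realloc_mod
from . import survival as surv_mod
from .synthetic_registry import RegistryConfig, generate_registry, \
    read_registry, write_registry

__all__ = ["RunConfig", "run_pipeline", "trend_tabulation",
           "mismatch_trend", "percent"]

logger = logging.getLogger(__name__)


def percent(numerator: float, denominator: float, digits: int = 1) -> float:
    """Percentage rounded to the registry's reporting precision."""
    if denominator == 0:
        raise ZeroDivisionError("denominator must be non-zero")
    return round(100.0 * numerator / denominator, digits)


@dataclass
class RunConfig:
    """Configuration for one end-to-end run.

    Exactly one of ``input_dir`` (registry CSVs on disk) or ``registry``
    (simulate) must be provided.
    """
    registry: RegistryConfig | None = None
    input_dir: str | None = None
    out_dir: str = "agemix_out"
    exposure_cutoff_years: float = 10.0
    horizon_years: float = 10.0
    landmarks: tuple = (1.0, 5.0)
    caliper: float = 0.1
    caliper_scale: str = "score"
    ceilings: tuple = (500.0, 1000.0, 1500.0, None)
    window_days: int = 90
    weight_tolerance_kg: float = 20.0
    policy_start_date: date = cohort_mod.ACUITY_CIRCLES_DATE
    admin_censor_date: date = date(2025, 4, 4)
    consume_grafts: bool = False
    seed: int = 0

    def __post_init__(self):
        if (self.registry is None) == (self.input_dir is None):
            raise ValueError(
                "exactly one of registry / input_dir must be set")


#: Cox adjustment set (numeric columns built by ``_cox_design``):
#: exposure plus graft type/size, donor and recipient sex and mismatch,
#: recipient BSA (per 0.1 m^2), diagnosis, cold ischemia >= 8 h, MELD,
#: status 1, admission status, and center volume.
def _cox_design(cohort: pd.DataFrame) -> tuple[pd.DataFrame, list]:
    d = pd.DataFrame(index=cohort.index)
    d["age_mismatched"] = cohort["age_mismatched"].astype(float)
    for lev in ("split_or_reduced", "small", "large"):
        d[f"size_{lev}"] = cohort["size_class"].eq(lev).astype(float)
    d["donor_male"] = cohort["donor_sex"].eq("M").astype(float)
    d["sex_mismatch"] = cohort["sex_mismatch"].astype(float)
    d["recipient_male"] = cohort["recipient_sex"].eq("M").astype(float)
    d["recipient_bsa_per_0.1"] = cohort["recipient_bsa"] * 10.0
    for lev in ("acute_liver_failure", "metabolic", "other_cholestatic",
                "other_noncholestatic"):
        d[f"dx_{lev}"] = cohort["diagnosis"].eq(lev).astype(float)
    d["cit_ge_8h"] = (cohort["cit_hours"] >= 8).astype(float)
    d["meld"] = cohort["meld"].astype(float)
    d["status1"] = cohort["status1"].astype(float)
    d["admission_icu"] = cohort["admission"].eq("ICU").astype(float)
    d["admission_hospital"] = cohort["admission"].eq("hospital").astype(float)
    d["volume_low"] = cohort["center_volume_class"].eq("low").astype(float)
    d["volume_middle"] = cohort["center_volume_class"].eq("middle").astype(float)
    covs = [c for c in d.columns if d[c].nunique() > 1]
    return d, covs


def _survival_block(cohort: pd.DataFrame, horizon: float,
                    landmarks) -> dict:
    """KM-at-horizon per arm, log-rank p, Cox tables (full + landmarks)."""
    out: dict = {}
    exp = cohort["age_mismatched"].astype(bool)
    for outcome in ("graft", "patient"):
        tcol, ecol = f"{outcome}_survival_time", f"{outcome}_event"
        arms = {}
        for name, mask in (("mismatched", exp), ("matched", ~exp)):
            km = surv_mod.km_estimate(cohort.loc[mask, tcol],
                                      cohort.loc[mask, ecol])
            arms[name] = {
                "km_survival_at_horizon_pct": round(
                    100.0 * km.survival_at(horizon), 1),
                "n": int(mask.sum()),
                "events": int(cohort.loc[mask, ecol].sum()),
            }
        chi2, p = surv_mod.log_rank(
            cohort.loc[exp, tcol], cohort.loc[exp, ecol],
            cohort.loc[~exp, tcol], cohort.loc[~exp, ecol])
        out[outcome] = {"arms": arms,
                        "log_rank_chi2": chi2, "log_rank_p": p}

    design, covs = _cox_design(cohort)
    work = pd.concat([design, cohort[["graft_survival_time",
                                      "graft_event"]]], axis=1)
    cox_tables = {}
    specs = {"full": None}
    for lm in landmarks:
        specs[f"landmark_{lm:g}y"] = surv_mod.LandmarkSpec(lm, horizon)
    for label, spec in specs.items():
        sub = work if spec is None else surv_mod.apply_landmark(
            work, spec, "graft_survival_time", "graft_event")
        _, sub_covs = _cox_design_recheck(sub, covs)
        fit = surv_mod.cox_fit(sub, "graft_survival_time", "graft_event",
                               sub_covs)
        cox_tables[label] = fit.table.round(4).to_dict(orient="index")
    out["cox_graft"] = cox_tables
    return out


def _cox_design_recheck(sub: pd.DataFrame, covs):
    """Drop covariates that became constant inside a landmark subset."""
    keep = [c for c in covs if sub[c].nunique() > 1]
    return sub, keep


def trend_tabulation(adolescent_donor_tx: pd.DataFrame) -> pd.DataFrame:
    """Per-year destination of adolescent-donor grafts.

    Input: transplants whose donors are adolescents, with ``tx_date``
    and ``recipient_category`` in {adult, adolescent, child}.  Returns
    one row per calendar year with counts and fractions per category
    (fractions sum to 1; years with no grafts are omitted).
    """
    if len(adolescent_donor_tx) == 0:
        raise ValueError("empty input")
    df = adolescent_donor_tx.copy()
    df["year"] = pd.to_datetime(df["tx_date"]).dt.year
    counts = (df.groupby(["year", "recipient_category"]).size()
                .unstack(fill_value=0))
    counts["total"] = counts.sum(axis=1)
    out = counts.copy()
    for cat in [c for c in counts.columns if c != "total"]:
        out[f"frac_{cat}"] = counts[cat] / counts["total"]
    return out.reset_index()


def mismatch_trend(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-year fraction of age-mismatched transplants, stratified by
    pretransplant hospitalization (ICU or ward vs home)."""
    df = cohort.copy()
    df["year"] = pd.to_datetime(df["tx_date"]).dt.year
    df["hospitalized"] = df["admission"].isin(["ICU", "hospital"])
    rows = []
    for (year, hosp), grp in df.groupby(["year", "hospitalized"]):
        rows.append({
            "year": int(year), "hospitalized": bool(hosp),
            "n": len(grp),
            "n_mismatched": int(grp["age_mismatched"].sum()),
            "frac_mismatched": float(grp["age_mismatched"].mean()),
        })
    return pd.DataFrame(rows)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if obj is None or isinstance(obj, str):
        return obj
    return str(obj)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write all artifacts; returns the summary.

    Deterministic for a fixed config and seed.  A stage failure aborts
    with the stage name in the raised error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "load"
    try:
        if config.registry is not None:
            stage = "simulate"
            reg = dataclasses.replace(config.registry, seed=config.seed)
            hospitals, adolescent, adult = generate_registry(reg)
            write_registry(out / "registry", hospitals, adolescent, adult)
            admin_date = reg.admin_censor_date
            window = reg.date_window
        else:
            hospitals, adolescent, adult = read_registry(config.input_dir)
            admin_date = config.admin_censor_date
            window = None

        stage = "cohort"
        cohort, report = cohort_mod.apply_inclusion(
            adolescent, date_window=window,
            admin_censor_date=admin_date,
            horizon_years=config.horizon_years,
            exposure_cutoff_years=config.exposure_cutoff_years)
        cohort.to_csv(out / "cohort.csv", index=False,
                      date_format="%Y-%m-%d")
        with open(out / "cohort_report.jsonl", "w") as fh:
            fh.write(json.dumps(_jsonable(report.to_records())) + "\n")
        logger.info("cohort: %d of %d rows retained", report.n_retained,
                    report.n_input)

        stage = "match"
        complete = cohort.dropna(
            subset=["recipient_bsa", "donor_bsa", "meld"])
        model = psm_mod.fit_propensity(complete)
        scores = model.predict(complete)
        match = psm_mod.match_1to1(
            scores, complete["age_mismatched"], caliper=config.caliper,
            seed=config.seed, caliper_scale=config.caliper_scale)
        balance = psm_mod.balance_table(complete, pairs=match.pairs)
        balance.to_csv(out / "balance.csv")
        pd.DataFrame(match.pairs,
                     columns=["exposed_id", "control_id"]).to_csv(
            out / "matched_pairs.csv", index=False)

        stage = "survival"
        surv = _survival_block(cohort, config.horizon_years,
                               config.landmarks)
        matched_ids = match.matched_ids
        surv_matched = {}
        if matched_ids:
            msub = complete.loc[matched_ids]
            exp = msub["age_mismatched"].astype(bool)
            arms = {}
            for name, mask in (("mismatched", exp), ("matched", ~exp)):
                km = surv_mod.km_estimate(
                    msub.loc[mask, "graft_survival_time"],
                    msub.loc[mask, "graft_event"])
                arms[name] = {"km_survival_at_horizon_pct": round(
                    100.0 * km.survival_at(config.horizon_years), 1),
                    "n": int(mask.sum())}
            chi2, p = surv_mod.log_rank(
                msub.loc[exp, "graft_survival_time"],
                msub.loc[exp, "graft_event"],
                msub.loc[~exp, "graft_survival_time"],
                msub.loc[~exp, "graft_event"])
            surv_matched = {"arms": arms, "log_rank_chi2": chi2,
                            "log_rank_p": p}

        stage = "reallocate"
        index_cases = cohort[
            cohort["age_mismatched"]
            & (cohort["tx_date"] >= pd.to_datetime(config.policy_start_date))]
        realloc_summary = []
        if len(index_cases):
            results = realloc_mod.simulate_scenarios(
                index_cases, adult, hospitals, ceilings=config.ceilings,
                window_days=config.window_days,
                weight_tolerance_kg=config.weight_tolerance_kg,
                policy_start_date=config.policy_start_date,
                consume=config.consume_grafts)
            arrivals = pd.DataFrame({
                ("unlimited" if r.ceiling_nm is None
                 else f"{r.ceiling_nm:g}nm"): r.first_arrival_day
                for r in results})
            arrivals.to_csv(out / "reallocation_first_arrivals.csv")
            for r in results:
                realloc_summary.append({
                    "ceiling_nm": r.ceiling_nm,
                    "p90_wait_days": r.p90_wait,
                    "fraction_matched": r.fraction_matched,
                    "n_index_cases": int(len(r.first_arrival_day)),
                })
            pd.DataFrame(realloc_summary).to_csv(
                out / "reallocation_summary.csv", index=False)

        stage = "trends"
        adolescent_donor = pd.concat([
            cohort[cohort["donor_age"].between(12, 17)],
            adult[adult["donor_age"].between(12, 17)]], join="inner")
        trends = trend_tabulation(adolescent_donor)
        trends.to_csv(out / "trend_destination.csv", index=False)
        mm_trend = mismatch_trend(cohort)
        mm_trend.to_csv(out / "trend_mismatch.csv", index=False)

        stage = "report"
        summary = {
            "seed": config.seed,
            "cohort": {
                "n_input": report.n_input,
                "n_retained": report.n_retained,
                "n_mismatched": int(cohort["age_mismatched"].sum()),
                "mismatched_pct": percent(
                    int(cohort["age_mismatched"].sum()), len(cohort)),
            },
            "matching": {
                "n_pairs": len(match.pairs),
                "n_unmatched_exposed": len(match.unmatched_exposed),
                "caliper_value": match.caliper_value,
                "max_abs_smd_before": float(
                    balance["smd_before"].abs().max()),
                "max_abs_smd_after": float(balance["smd_after"].abs().max()),
            },
            "survival_unmatched": surv,
            "survival_matched": surv_matched,
            "reallocation": realloc_summary,
        }
        summary = _jsonable(summary)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        return summary
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
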