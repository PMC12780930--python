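"""Cohort derivation: inclusion/exclusion rules and derived covariates.

Builds the analysis-ready cohort of adolescent (12-17 y) recipients of
liver-only transplants from brain-dead donors, and derives the exposure
flag (donor at least 10 years older than the recipient), the donor/
recipient body-surface-area index and graft size class, center-volume
tertile class, era and allocation-policy flags, and right-censored graft
and patient survival outcomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

__all__ = [
    "bsa_du_bois",
    "classify_size",
    "classify_exposure",
    "classify_center_volume",
    "apply_inclusion",
    "CohortReport",
    "ACUITY_CIRCLES_DATE",
]

logger = logging.getLogger(__name__)

#: Liver-allocation policy change introducing distance-based sharing.
ACUITY_CIRCLES_DATE = date(2020, 2, 4)

_DAYS_PER_YEAR = 365.25

# Du Bois & Du Bois body-surface-area formula constants
_DU_BOIS_COEF = 0.007184
_DU_BOIS_H_EXP = 0.725
_DU_BOIS_W_EXP = 0.425

# Graft size classes on the donor/recipient BSA ratio
SIZE_SMALL_MAX = 0.78   # exclusive upper bound of "small"
SIZE_LARGE_MIN = 1.24   # exclusive lower bound of "large"

# Center-volume tertile cutoffs (cases per center over the study period)
VOLUME_HIGH_MIN = 57
VOLUME_MIDDLE_MIN = 28

EXPOSURE_CUTOFF_YEARS = 10.0

_REQUIRED_FIELDS = ["tx_id", "tx_date", "donor_age", "recipient_age",
                    "donor_type", "multiorgan", "graft_type",
                    "last_followup_date", "center_id"]


def bsa_du_bois(height_cm, weight_kg):
    """Body surface area (m^2) from the Du Bois formula.

    BSA = 0.007184 * height^0.725 * weight^0.425, height in cm, weight
    in kg.  Accepts scalars or arrays; raises on non-positive finite
    inputs (NaNs propagate, supporting missing anthropometrics).
    """
    h = np.asarray(height_cm, dtype=float)
    w = np.asarray(weight_kg, dtype=float)
    if np.any(h[~np.isnan(h)] <= 0) or np.any(w[~np.isnan(w)] <= 0):
        raise ValueError("height and weight must be positive")
    out = _DU_BOIS_COEF * h ** _DU_BOIS_H_EXP * w ** _DU_BOIS_W_EXP
    if np.isscalar(height_cm) and np.isscalar(weight_kg):
        return float(out)
    return out


def classify_size(bsa_index):
    """Graft size class from the donor/recipient BSA ratio.

    small: < 0.78; normal: 0.78-1.24 (closed); large: > 1.24.
    Vectorized; NaN maps to NaN (size class undefined).
    """
    x = np.asarray(bsa_index, dtype=float)
    if np.any(x[~np.isnan(x)] <= 0):
        raise ValueError("bsa_index must be positive")
    out = np.where(x < SIZE_SMALL_MAX, "small",
                   np.where(x > SIZE_LARGE_MIN, "large", "normal"))
    out = np.where(np.isnan(x), None, out)
    if np.isscalar(bsa_index):
        return out.item()
    return out


def classify_exposure(donor_age, recipient_age,
                      cutoff_years: float = EXPOSURE_CUTOFF_YEARS):
    """Age-mismatch exposure: donor at least `cutoff_years` older.

    The difference is signed — a donor 10+ years *younger* than the
    recipient is not exposed.
    """
    d = np.asarray(donor_age, dtype=float)
    r = np.asarray(recipient_age, dtype=float)
    if np.any(d < 0) or np.any(r < 0):
        raise ValueError("ages must be non-negative")
    out = (d - r) >= cutoff_years
    if np.isscalar(donor_age) and np.isscalar(recipient_age):
        return bool(out)
    return out


def classify_center_volume(center_case_count,
                           high_min: int = VOLUME_HIGH_MIN,
                           middle_min: int = VOLUME_MIDDLE_MIN):
    """Center-volume class: high (>=57 cases), middle (28-56), low (<28)."""
    c = np.asarray(center_case_count)
    if np.any(c < 0):
        raise ValueError("case counts must be non-negative")
    out = np.where(c >= high_min, "high",
                   np.where(c >= middle_min, "middle", "low"))
    if np.isscalar(center_case_count):
        return out.item()
    return out


@dataclass
class CohortReport:
    """Row-attrition accounting for one cohort derivation."""
    n_input: int = 0
    n_retained: int = 0
    exclusions: dict = field(default_factory=dict)   # reason -> count
    dropped_rows: list = field(default_factory=list)  # row-level validation log

    def to_records(self):
        return {"n_input": self.n_input, "n_retained": self.n_retained,
                "exclusions": dict(self.exclusions),
                "dropped_rows": list(self.dropped_rows)}


def _inclusion_masks(tx: pd.DataFrame, age_range, date_window):
    """Independent boolean inclusion criteria (order-free composition)."""
    lo, hi = age_range
    masks = {
        "recipient_age_out_of_range": tx["recipient_age"].between(lo, hi),
        "not_dbd_donor": tx["donor_type"].eq("DBD"),
        "multiorgan": ~tx["multiorgan"].astype(bool),
    }
    if date_window is not None:
        start, end = (pd.to_datetime(d) for d in date_window)
        masks["tx_date_outside_window"] = tx["tx_date"].between(start, end)
    return masks


def _survival_pair(tx, event_dates, admin, horizon_years):
    """(time in years, event flag) censored at follow-up end, the
    administrative date, and the horizon, whichever comes first."""
    tx_date = tx["tx_date"]
    censor_end = tx["last_followup_date"].where(
        tx["last_followup_date"] <= admin, admin)
    has_event = event_dates.notna() & (event_dates <= censor_end)
    end = event_dates.where(has_event, censor_end)
    t = (end - tx_date).dt.days / _DAYS_PER_YEAR
    t = t.clip(lower=0.0)
    if horizon_years is not None:
        over = t > horizon_years
        has_event = has_event & ~over
        t = t.clip(upper=horizon_years)
    return t, has_event


def apply_inclusion(transplants: pd.DataFrame,
                    *,
                    date_window=None,
                    admin_censor_date: date = date(2025, 4, 4),
                    horizon_years: float = 10.0,
                    age_range=(12, 17),
                    exposure_cutoff_years: float = EXPOSURE_CUTOFF_YEARS,
                    policy_date: date = ACUITY_CIRCLES_DATE,
                    volume_high_min: int = VOLUME_HIGH_MIN,
                    volume_middle_min: int = VOLUME_MIDDLE_MIN,
                    ) -> tuple[pd.DataFrame, CohortReport]:
    """Apply inclusion/exclusion rules and derive all cohort covariates.

    Keeps recipients aged ``age_range`` receiving liver-only (non-
    multiorgan) grafts from brain-dead donors within ``date_window``.
    Rows missing a required field are dropped and logged in the report.

    Returns ``(cohort, report)``.  The cohort carries every registry
    column plus: ``age_mismatched``, ``donor_bsa``, ``recipient_bsa``,
    ``bsa_index`` (NaN for split/reduced grafts, for which the index is
    undefined), ``size_class``, ``sex_mismatch``,
    ``center_volume_class``, ``era``, ``post_acuity_circles``,
    ``graft_survival_time``/``graft_event`` (graft loss = retransplant
    or death, whichever first), and ``patient_survival_time``/
    ``patient_event``.
    """
    report = CohortReport(n_input=len(transplants))
    tx = transplants.copy()
    for col in ("tx_date", "graft_loss_date", "death_date",
                "last_followup_date"):
        if col in tx.columns:
            tx[col] = pd.to_datetime(tx[col])

    # row-level validation: required fields present
    missing = [c for c in _REQUIRED_FIELDS if c not in tx.columns]
    if missing:
        raise ValueError(f"registry is missing required columns: {missing}")
    bad = tx[_REQUIRED_FIELDS].isna().any(axis=1)
    for _, row in tx[bad].iterrows():
        absent = [c for c in _REQUIRED_FIELDS if pd.isna(row[c])]
        entry = {"tx_id": row.get("tx_id"), "reason": "missing_required",
                 "fields": absent}
        report.dropped_rows.append(entry)
        logger.warning("dropped row %s: missing %s", row.get("tx_id"), absent)
    tx = tx[~bad]
    if bad.any():
        report.exclusions["missing_required"] = int(bad.sum())

    masks = _inclusion_masks(tx, age_range, date_window)
    keep = pd.Series(True, index=tx.index)
    for reason, mask in masks.items():
        report.exclusions[reason] = int((keep & ~mask).sum())
        keep &= mask
    cohort = tx[keep].copy()
    report.n_retained = len(cohort)

    # ---- derived covariates -------------------------------------------
    cohort["age_mismatched"] = classify_exposure(
        cohort["donor_age"].to_numpy(), cohort["recipient_age"].to_numpy(),
        exposure_cutoff_years)
    cohort["donor_bsa"] = bsa_du_bois(
        cohort["donor_height"], cohort["donor_weight"])
    cohort["recipient_bsa"] = bsa_du_bois(
        cohort["recipient_height"], cohort["recipient_weight"])
    split = cohort["graft_type"].eq("split_or_reduced")
    cohort["bsa_index"] = np.where(
        split, np.nan, cohort["donor_bsa"] / cohort["recipient_bsa"])
    size = pd.Series(classify_size(cohort["bsa_index"].to_numpy()),
                     index=cohort.index, dtype=object)
    cohort["size_class"] = size.where(~split, "split_or_reduced")
    cohort["sex_mismatch"] = cohort["donor_sex"] != cohort["recipient_sex"]

    counts = cohort["center_id"].value_counts()
    cohort["center_volume_class"] = classify_center_volume(
        cohort["center_id"].map(counts).to_numpy(),
        volume_high_min, volume_middle_min)

    year = cohort["tx_date"].dt.year
    cohort["era"] = np.where(year <= 2010, "2002-2010", "2011-2024")
    cohort["post_acuity_circles"] = (
        cohort["tx_date"] >= pd.to_datetime(policy_date))

    admin = pd.to_datetime(admin_censor_date)
    graft_end = cohort[["graft_loss_date", "death_date"]].min(axis=1)
    t, e = _survival_pair(cohort, graft_end, admin, horizon_years)
    cohort["graft_survival_time"], cohort["graft_event"] = t, e
    t, e = _survival_pair(cohort, cohort["death_date"], admin, horizon_years)
    cohort["patient_survival_time"], cohort["patient_event"] = t, e

    return cohort, report
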