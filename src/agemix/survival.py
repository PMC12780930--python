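"""Kaplan-Meier, log-rank, Cox PH, and landmark restriction.

Thin, typed surface over lifelines: product-limit survival curves,
two-group log-rank tests, Cox proportional-hazards fits with Efron tie
handling and Wald 95% CIs, and the landmark restriction that resets
time 0 to a post-transplant landmark, keeping only subjects event-free
and under follow-up at that time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from lifelines.utils import ConvergenceError

__all__ = [
    "KMCurve",
    "CoxFitResult",
    "LandmarkSpec",
    "km_estimate",
    "log_rank",
    "cox_fit",
    "apply_landmark",
]


@dataclass
class KMCurve:
    """Product-limit survival curve (right-continuous step function)."""
    event_times: np.ndarray     # sorted distinct observed times
    survival_probs: np.ndarray  # S(t) at each event time, non-increasing
    at_risk: np.ndarray         # number at risk just before each time
    median: float               # median survival time (inf if not reached)

    def survival_at(self, t) -> float | np.ndarray:
        """S(t); S(0) = 1, step drops at event times."""
        idx = np.searchsorted(self.event_times, np.asarray(t, dtype=float),
                              side="right")
        probs = np.concatenate([[1.0], self.survival_probs])
        out = probs[idx]
        return float(out) if np.isscalar(t) else out


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    At tied times, events are processed before censorings (the standard
    convention).  Raises on an empty sample.
    """
    t = np.asarray(time, dtype=float)
    e = np.asarray(event, dtype=bool)
    if t.size == 0:
        raise ValueError("empty sample")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValueError("times must be finite and non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    sf = kmf.survival_function_["KM_estimate"]
    times = sf.index.to_numpy(dtype=float)
    probs = sf.to_numpy(dtype=float)
    keep = times > 0
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(float)
    med = float(kmf.median_survival_time_)
    return KMCurve(times[keep], probs[keep], at_risk[keep], med)


def log_rank(time_a, event_a, time_b, event_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square, p) with 1 df.

    With no events in either group the statistic is 0 and p = 1.
    """
    ea = np.asarray(event_a, dtype=bool)
    eb = np.asarray(event_b, dtype=bool)
    if len(ea) == 0 or len(eb) == 0:
        raise ValueError("both groups must be non-empty")
    if not (ea.any() or eb.any()):
        return 0.0, 1.0
    res = logrank_test(time_a, time_b, event_observed_A=ea,
                       event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxFitResult:
    """Cox PH fit: per-covariate HR, Wald 95% CI and p, log-likelihood."""
    table: pd.DataFrame          # columns: hr, ci_lower, ci_upper, p
    log_likelihood: float

    def hr(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hr"])


def cox_fit(df: pd.DataFrame, duration_col: str, event_col: str,
            covariates) -> CoxFitResult:
    """Cox proportional-hazards fit (Efron ties, Wald CIs on log scale).

    ``covariates`` are numeric/boolean columns of ``df``.  Raises on
    constant covariates, absence of events, or non-convergence.
    """
    covariates = list(covariates)
    if df[event_col].sum() == 0:
        raise ValueError("no events in sample")
    sub = df[[duration_col, event_col] + covariates].copy()
    for c in covariates:
        sub[c] = sub[c].astype(float)
        if sub[c].nunique() <= 1:
            raise ValueError(f"constant covariate: {c}")
    cph = CoxPHFitter()
    try:
        cph.fit(sub, duration_col=duration_col, event_col=event_col)
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox fit did not converge: {exc}") from exc
    s = cph.summary
    table = pd.DataFrame({
        "hr": s["exp(coef)"],
        "ci_lower": s["exp(coef) lower 95%"],
        "ci_upper": s["exp(coef) upper 95%"],
        "p": s["p"],
    })
    return CoxFitResult(table, float(cph.log_likelihood_))


@dataclass
class LandmarkSpec:
    """Landmark restriction: reset time 0 to ``landmark_time`` years
    post-transplant; analyze up to the original ``horizon``."""
    landmark_time: float
    horizon: float = 10.0

    def __post_init__(self):
        if not 0 <= self.landmark_time < self.horizon:
            raise ValueError("require 0 <= landmark_time < horizon")


def apply_landmark(df: pd.DataFrame, spec: LandmarkSpec,
                   duration_col: str, event_col: str) -> pd.DataFrame:
    """Restrict to the landmark risk set and reset the clock.

    Keeps subjects whose follow-up extends strictly beyond the landmark
    (an event or a censoring at or before the landmark — including
    exactly at it — is excluded), subtracts the landmark from the
    surviving times, and truncates at ``horizon`` (so a 5-year landmark
    with a 10-year horizon analyzes the 5 post-landmark years).
    """
    t = df[duration_col].astype(float)
    keep = t > spec.landmark_time
    if not keep.any():
        raise ValueError("empty risk set at landmark")
    out = df[keep].copy()
    t = out[duration_col].astype(float)
    over = t > spec.horizon
    out[event_col] = out[event_col].astype(bool) & ~over
    out[duration_col] = t.clip(upper=spec.horizon) - spec.landmark_time
    return out
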