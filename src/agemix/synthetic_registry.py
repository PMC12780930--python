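"""Seeded synthetic transplant-registry generator.

Real adolescent liver-transplant outcome data live in the restricted
OPTN/UNOS STAR file and cannot be redistributed.  This module generates a
synthetic registry with the statistical structure the downstream analysis
assumes, so that every stage of the pipeline — cohort derivation,
propensity-score matching, landmark survival analysis, and the
counterfactual reallocation simulation — is testable end to end.

The generative model (all distributional choices are stand-ins, not
estimates from the restricted data; see docs/methods.md):

* A single standard-normal latent *acuity* score per adolescent recipient
  drives pretransplant admission status, status-1 listing, and the MELD
  score, and raises the log-odds of accepting an age-mismatched graft
  (``confounding_strength`` per SD) as well as the post-transplant hazard
  (``acuity_log_hr`` per SD).  This reproduces, qualitatively, the
  confounding between illness severity and mismatched-graft acceptance
  seen in national registry data.
* Graft-failure times are drawn from a piecewise-constant yearly baseline
  hazard with a multiplicative exposure effect that acts on years (0, 1]
  (``exposure_log_hr_early``) and on years (5, 10] and beyond
  (``exposure_log_hr_late``) and is null on (1, 5] — a late-emerging
  exposure effect.
* Independent exponential loss to follow-up at ``censor_rate`` per year,
  plus administrative censoring at ``admin_censor_date``.
* A separate stream of adolescent-donor grafts transplanted into adult
  recipients, with transplant dates uniform over the study window and
  donor weights overlapping the adolescent recipient weight range; the
  reallocation simulation treats this stream as exogenous supply.
* Hospitals placed uniformly in a configurable bounding box; transplant
  centers are hospitals, with a skewed (log-normal) volume distribution.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import optimize, stats

__all__ = [
    "RegistryConfig",
    "ConfigError",
    "generate_registry",
    "write_registry",
    "read_registry",
    "load_config",
    "HOSPITAL_COLUMNS",
    "TRANSPLANT_COLUMNS",
]

HOSPITAL_COLUMNS = ["hospital_id", "latitude", "longitude"]

#: Column schema of one transplant record (the atomic registry row).
TRANSPLANT_COLUMNS = [
    "tx_id", "tx_date", "donor_id", "recipient_id",
    "donor_age", "donor_sex", "donor_height", "donor_weight",
    "donor_type", "donor_hospital",
    "recipient_age", "recipient_sex", "recipient_height", "recipient_weight",
    "recipient_category", "diagnosis", "meld", "status1", "admission",
    "prior_transplant", "multiorgan", "graft_type", "cit_hours",
    "center_id", "recipient_hospital", "waiting_days",
    "graft_loss_date", "death_date", "last_followup_date",
]

DIAGNOSES = ("biliary_atresia", "acute_liver_failure", "metabolic",
             "other_cholestatic", "other_noncholestatic")

_DAYS_PER_YEAR = 365.25


class ConfigError(ValueError):
    """Raised when a RegistryConfig field violates its invariant."""


@dataclass
class RegistryConfig:
    """Parameters of the synthetic registry.

    Defaults emulate the published national adolescent liver-transplant
    cohort: 2020 adolescent transplants and 5401 adolescent-donor grafts
    to adults over March 2002 – December 2024, a 30.3% age-mismatch
    prevalence, acuity confounding sized to the reported covariate
    imbalance, and a late-window exposure hazard ratio of 1.67.
    """

    n_adolescent_tx: int = 2020
    n_adult_tx_of_adolescent_grafts: int = 5401
    date_window: tuple[date, date] = (date(2002, 3, 1), date(2024, 12, 31))
    frac_mismatched_target: float = 0.303
    #: log-odds of mismatched-graft acceptance per SD of latent acuity
    confounding_strength: float = 0.9
    #: log hazard ratio per SD of latent acuity (confounder -> outcome link)
    acuity_log_hr: float = 0.30
    exposure_log_hr_early: float = 0.0
    exposure_log_hr_late: float = math.log(1.67)
    #: piecewise-constant yearly graft-failure rates; last entry extends
    baseline_hazard: tuple[float, ...] = (
        0.08, 0.03, 0.025, 0.025, 0.025, 0.02, 0.02, 0.02, 0.02, 0.02)
    censor_rate: float = 0.02
    admin_censor_date: date = date(2025, 4, 4)
    n_hospitals: int = 103
    #: (lat_min, lat_max, lon_min, lon_max) in degrees
    geography: tuple[float, float, float, float] = (25.0, 49.0, -124.0, -67.0)
    frac_split: float = 0.074
    #: probability a generated graft failure is a death (vs retransplant)
    death_given_graft_loss: float = 0.64
    seed: int = 0

    def validate(self) -> None:
        def _nonneg(name):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for name in ("n_adolescent_tx", "n_adult_tx_of_adolescent_grafts",
                     "frac_mismatched_target", "censor_rate", "n_hospitals",
                     "frac_split", "death_given_graft_loss"):
            _nonneg(name)
        for name in ("frac_mismatched_target", "frac_split",
                     "death_given_graft_loss"):
            if getattr(self, name) > 1:
                raise ConfigError(f"{name} must be <= 1")
        if any(r < 0 for r in self.baseline_hazard) or not self.baseline_hazard:
            raise ConfigError("baseline_hazard must be non-empty, rates >= 0")
        start, end = self.date_window
        if not (start < end <= self.admin_censor_date):
            raise ConfigError(
                "date_window must satisfy start < end <= admin_censor_date")
        lat0, lat1, lon0, lon1 = self.geography
        if not (-90 <= lat0 < lat1 <= 90 and -180 <= lon0 < lon1 <= 180):
            raise ConfigError("geography bounding box out of range")

    def __post_init__(self) -> None:
        self.validate()


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _solve_exposure_intercept(beta: float, target: float) -> float:
    """Intercept alpha with E[sigmoid(alpha + beta*A)] = target, A ~ N(0,1)."""
    if target <= 0.0:
        return -np.inf
    if target >= 1.0:
        return np.inf
    if beta == 0.0:
        return math.log(target / (1.0 - target))
    # Gauss-Hermite quadrature over the standard-normal latent
    nodes, weights = np.polynomial.hermite.hermgauss(64)
    a = nodes * math.sqrt(2.0)
    w = weights / math.sqrt(math.pi)

    def marginal(alpha):
        return float(w @ _sigmoid(alpha + beta * a)) - target

    return optimize.brentq(marginal, -40.0, 40.0)


def _sample_piecewise_exponential(rng, boundaries, rates):
    """Draw event times from subject-specific piecewise-constant hazards.

    boundaries: (K+1,) increasing, starting at 0 (last interval is open).
    rates: (n, K) per-subject rate in each interval, all > 0.
    """
    n, k = rates.shape
    widths = np.diff(boundaries)[: k - 1]  # widths of the closed intervals
    cum = np.zeros((n, k))
    cum[:, 1:] = np.cumsum(rates[:, :-1] * widths, axis=1)
    target = rng.exponential(1.0, size=n)
    idx = np.sum(cum <= target[:, None], axis=1) - 1
    rows = np.arange(n)
    t = boundaries[idx] + (target - cum[rows, idx]) / rates[rows, idx]
    return t


def _exposure_rates(cfg: RegistryConfig, acuity, exposed):
    """Per-subject yearly rates under the late-emerging exposure effect."""
    base = np.asarray(cfg.baseline_hazard, dtype=float)
    k = len(base)
    # exposure log-HR by year-interval: early on (0,1], 0 on (1,5],
    # late on (5,10] and beyond
    lhr = np.zeros(k)
    lhr[0] = cfg.exposure_log_hr_early
    for j in range(1, k):
        if j >= 5:
            lhr[j] = cfg.exposure_log_hr_late
    mult = np.exp(cfg.acuity_log_hr * acuity[:, None]
                  + exposed[:, None] * lhr[None, :])
    rates = np.clip(base[None, :] * mult, 1e-12, None)
    boundaries = np.arange(k + 1, dtype=float)
    return boundaries, rates


def _uniform_dates(rng, start: date, end: date, n: int):
    span = (end - start).days
    offsets = rng.integers(0, span + 1, size=n)
    return pd.to_datetime(start) + pd.to_timedelta(offsets, unit="D")


def _heights_weights(rng, sex, age, adult: bool):
    """Sex-specific normal anthropometrics, clipped to plausible ranges."""
    female = sex == "F"
    if adult:
        h_mean = np.where(female, 163.0, 177.0)
        h_sd = 7.5
        bmi = rng.normal(26.0, 4.5, size=len(sex))
    else:
        # adolescent / pediatric donors: shrink toward age-typical stature
        deficit = np.clip(18.0 - age, 0.0, None) * 2.5
        h_mean = np.where(female, 163.0, 177.0) - deficit
        h_sd = 7.0
        bmi = rng.normal(21.5, 3.5, size=len(sex))
    height = np.clip(rng.normal(h_mean, h_sd), 120.0, 205.0)
    bmi = np.clip(bmi, 14.0, 45.0)
    weight = np.clip(bmi * (height / 100.0) ** 2, 25.0, 160.0)
    return height.round(1), weight.round(1)


def _generate_hospitals(rng, cfg: RegistryConfig) -> pd.DataFrame:
    lat0, lat1, lon0, lon1 = cfg.geography
    n = cfg.n_hospitals
    return pd.DataFrame({
        "hospital_id": [f"H{i:04d}" for i in range(n)],
        "latitude": rng.uniform(lat0, lat1, n).round(4),
        "longitude": rng.uniform(lon0, lon1, n).round(4),
    })


def _survival_columns(rng, cfg, tx_dates, acuity, exposed):
    """Observed event/censoring dates for each subject."""
    n = len(tx_dates)
    boundaries, rates = _exposure_rates(cfg, acuity, exposed)
    # extend the last interval far beyond any plausible follow-up
    boundaries = np.append(boundaries, 500.0)
    rates = np.column_stack([rates, rates[:, -1]])
    t_event = _sample_piecewise_exponential(rng, boundaries, rates)
    if cfg.censor_rate > 0:
        t_ltfu = rng.exponential(1.0 / cfg.censor_rate, size=n)
    else:
        t_ltfu = np.full(n, np.inf)
    admin = pd.to_datetime(cfg.admin_censor_date)
    t_admin = (admin - tx_dates).days.to_numpy() / _DAYS_PER_YEAR
    t_cens = np.minimum(t_ltfu, t_admin)
    observed_event = t_event <= t_cens
    t_obs = np.where(observed_event, t_event, t_cens)
    end_dates = tx_dates + pd.to_timedelta(
        np.round(t_obs * _DAYS_PER_YEAR).astype(int), unit="D")
    # events dated no later than the administrative cutoff
    end_dates = end_dates.where(end_dates <= admin, admin)
    is_death = observed_event & (
        rng.uniform(size=n) < cfg.death_given_graft_loss)
    graft_loss = end_dates.where(observed_event, pd.NaT)
    death = end_dates.where(is_death, pd.NaT)
    return graft_loss, death, end_dates


def _generate_adolescent_stream(rng, cfg: RegistryConfig,
                                hospitals: pd.DataFrame) -> pd.DataFrame:
    n = cfg.n_adolescent_tx
    start, end = cfg.date_window
    tx_dates = _uniform_dates(rng, start, end, n)

    r_age = rng.integers(12, 18, size=n)
    r_sex = np.where(rng.uniform(size=n) < 0.535, "F", "M")
    r_height, r_weight = _heights_weights(rng, r_sex, r_age, adult=False)

    # latent acuity drives admission, status 1, MELD, and exposure odds
    acuity = rng.standard_normal(n)
    icu_cut = stats.norm.ppf(1 - 0.266)       # ~26.6% ICU
    hosp_cut = stats.norm.ppf(1 - 0.402)      # ~13.6% ward
    admission = np.where(acuity > icu_cut, "ICU",
                         np.where(acuity > hosp_cut, "hospital", "home"))
    status1 = acuity > stats.norm.ppf(1 - 0.321)
    meld = np.clip(np.round(17.0 + 7.5 * acuity), 6, 40).astype(int)

    # acute liver failure more likely in high-acuity recipients
    p_alf = _sigmoid(-1.9 + 0.8 * acuity)
    is_alf = rng.uniform(size=n) < p_alf
    other_probs = np.array([0.095, 0.153, 0.188, 0.564])
    other_dx = rng.choice(
        ["biliary_atresia", "metabolic", "other_cholestatic",
         "other_noncholestatic"], size=n, p=other_probs / other_probs.sum())
    diagnosis = np.where(is_alf, "acute_liver_failure", other_dx)

    alpha = _solve_exposure_intercept(
        cfg.confounding_strength, cfg.frac_mismatched_target)
    p_exposed = _sigmoid(alpha + cfg.confounding_strength * acuity)
    exposed = rng.uniform(size=n) < p_exposed

    # donor age: mismatched donors >= 10 years older; matched within 10
    gap_mismatched = 10.0 + rng.gamma(1.8, 7.0, size=n)
    gap_matched = np.clip(rng.normal(1.0, 4.0, size=n), None, 9.0)
    d_age = np.where(exposed, r_age + gap_mismatched, r_age + gap_matched)
    d_age = np.clip(np.round(d_age), 0, 85).astype(int)
    d_sex = np.where(rng.uniform(size=n) < np.where(exposed, 0.518, 0.362),
                     "F", "M")
    d_height, d_weight = _heights_weights(rng, d_sex, d_age, adult=False)

    graft_type = np.where(rng.uniform(size=n) < cfg.frac_split,
                          "split_or_reduced", "whole")
    cit = np.round(np.exp(rng.normal(math.log(6.6), 0.35, size=n)), 1)
    waiting = np.round(
        np.exp(4.2 - 0.9 * acuity + rng.normal(0.0, 1.2, size=n))
    ).astype(int)

    # skewed center volumes; the recipient hospital is the center
    center_w = rng.lognormal(0.0, 1.0, size=cfg.n_hospitals)
    center_idx = rng.choice(cfg.n_hospitals, size=n,
                            p=center_w / center_w.sum())
    center_ids = hospitals["hospital_id"].to_numpy()[center_idx]
    donor_hosp = hospitals["hospital_id"].to_numpy()[
        rng.integers(0, cfg.n_hospitals, size=n)]

    graft_loss, death, last_fu = _survival_columns(
        rng, cfg, tx_dates, acuity, exposed.astype(float))

    return pd.DataFrame({
        "tx_id": [f"T{i:06d}" for i in range(n)],
        "tx_date": tx_dates,
        "donor_id": [f"D{i:06d}" for i in range(n)],
        "recipient_id": [f"R{i:06d}" for i in range(n)],
        "donor_age": d_age,
        "donor_sex": d_sex,
        "donor_height": d_height,
        "donor_weight": d_weight,
        "donor_type": "DBD",
        "donor_hospital": donor_hosp,
        "recipient_age": r_age,
        "recipient_sex": r_sex,
        "recipient_height": r_height,
        "recipient_weight": r_weight,
        "recipient_category": "adolescent",
        "diagnosis": diagnosis,
        "meld": meld,
        "status1": status1,
        "admission": admission,
        "prior_transplant": rng.uniform(size=n) < 0.109,
        "multiorgan": False,
        "graft_type": graft_type,
        "cit_hours": cit,
        "center_id": center_ids,
        "recipient_hospital": center_ids,
        "waiting_days": waiting,
        "graft_loss_date": graft_loss,
        "death_date": death,
        "last_followup_date": last_fu,
    })


def _generate_adult_stream(rng, cfg: RegistryConfig,
                           hospitals: pd.DataFrame) -> pd.DataFrame:
    """Adolescent-donor grafts transplanted into adult recipients.

    Exogenous supply for the reallocation simulation: adolescent DBD
    donors (ages 12-17) whose weights overlap the adolescent recipient
    range, transplant dates uniform over the study window.
    """
    n = cfg.n_adult_tx_of_adolescent_grafts
    start, end = cfg.date_window
    tx_dates = _uniform_dates(rng, start, end, n)

    d_age = rng.integers(12, 18, size=n)
    d_sex = np.where(rng.uniform(size=n) < 0.40, "F", "M")
    d_height, d_weight = _heights_weights(rng, d_sex, d_age, adult=False)

    r_age = np.clip(np.round(rng.normal(53.0, 10.0, size=n)), 18, 75).astype(int)
    r_sex = np.where(rng.uniform(size=n) < 0.38, "F", "M")
    r_height, r_weight = _heights_weights(rng, r_sex, r_age, adult=True)

    graft_type = np.where(rng.uniform(size=n) < cfg.frac_split,
                          "split_or_reduced", "whole")
    hosp_ids = hospitals["hospital_id"].to_numpy()
    donor_hosp = hosp_ids[rng.integers(0, cfg.n_hospitals, size=n)]
    recip_hosp = hosp_ids[rng.integers(0, cfg.n_hospitals, size=n)]

    # outcome columns filled for schema completeness; the reallocation
    # simulation uses only dates, donor fields, weights and geography
    acuity = rng.standard_normal(n)
    graft_loss, death, last_fu = _survival_columns(
        rng, cfg, tx_dates, acuity, np.zeros(n))

    return pd.DataFrame({
        "tx_id": [f"A{i:06d}" for i in range(n)],
        "tx_date": tx_dates,
        "donor_id": [f"DA{i:06d}" for i in range(n)],
        "recipient_id": [f"RA{i:06d}" for i in range(n)],
        "donor_age": d_age,
        "donor_sex": d_sex,
        "donor_height": d_height,
        "donor_weight": d_weight,
        "donor_type": "DBD",
        "donor_hospital": donor_hosp,
        "recipient_age": r_age,
        "recipient_sex": r_sex,
        "recipient_height": r_height,
        "recipient_weight": r_weight,
        "recipient_category": "adult",
        "diagnosis": "other_noncholestatic",
        "meld": np.clip(np.round(rng.normal(20.0, 8.0, size=n)), 6, 40).astype(int),
        "status1": False,
        "admission": rng.choice(["home", "hospital", "ICU"], size=n,
                                p=[0.7, 0.2, 0.1]),
        "prior_transplant": rng.uniform(size=n) < 0.05,
        "multiorgan": False,
        "graft_type": graft_type,
        "cit_hours": np.round(np.exp(rng.normal(math.log(6.6), 0.35, size=n)), 1),
        "center_id": recip_hosp,
        "recipient_hospital": recip_hosp,
        "waiting_days": np.round(np.exp(rng.normal(4.5, 1.3, size=n))).astype(int),
        "graft_loss_date": graft_loss,
        "death_date": death,
        "last_followup_date": last_fu,
    })


def generate_registry(config: RegistryConfig):
    """Generate a seeded synthetic registry.

    Returns ``(hospitals, adolescent_tx, adult_tx)`` DataFrames with the
    schemas in :data:`HOSPITAL_COLUMNS` and :data:`TRANSPLANT_COLUMNS`.
    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    hospitals = _generate_hospitals(rng, config)
    adolescent = _generate_adolescent_stream(rng, config, hospitals)
    adult = _generate_adult_stream(rng, config, hospitals)
    return hospitals, adolescent, adult


def write_registry(out_dir, hospitals, adolescent_tx, adult_tx) -> None:
    """Write hospitals.csv, adolescent_tx.csv, adult_tx.csv (ISO dates)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hospitals.to_csv(out / "hospitals.csv", index=False)
    for name, df in (("adolescent_tx", adolescent_tx), ("adult_tx", adult_tx)):
        df.to_csv(out / f"{name}.csv", index=False, date_format="%Y-%m-%d")


def read_registry(in_dir):
    """Read a registry written by :func:`write_registry`."""
    p = Path(in_dir)
    date_cols = ["tx_date", "graft_loss_date", "death_date",
                 "last_followup_date"]
    hospitals = pd.read_csv(p / "hospitals.csv")
    adolescent = pd.read_csv(p / "adolescent_tx.csv", parse_dates=date_cols)
    adult = pd.read_csv(p / "adult_tx.csv", parse_dates=date_cols)
    return hospitals, adolescent, adult


def load_config(path) -> RegistryConfig:
    """Build a RegistryConfig from a YAML/JSON key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RegistryConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config fields: {sorted(unknown)}")
    for key in ("date_window",):
        if key in raw:
            raw[key] = tuple(
                v if isinstance(v, date) else date.fromisoformat(v)
                for v in raw[key])
    for key in ("admin_censor_date",):
        if key in raw and not isinstance(raw[key], date):
            raw[key] = date.fromisoformat(raw[key])
    for key in ("baseline_hazard", "geography"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RegistryConfig(**raw)
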