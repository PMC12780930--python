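"""Counterfactual reallocation of adolescent-donor grafts.

For each age-mismatched index transplant performed under the
distance-based allocation policy, scan the observed stream of
adolescent brain-dead-donor grafts that actually went to adult
recipients on days 1-90 after the index date, keep those within a donor
weight tolerance of the index recipient and within a travel-distance
ceiling of the index recipient's hospital, and summarize how soon an
age-matched offer would have arrived.  The headline summary per
distance ceiling is the 90th-percentile wait: the smallest day by which
at least 90% of index recipients would have received an offer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .cohort import ACUITY_CIRCLES_DATE

__all__ = [
    "ReallocationScenario",
    "ReallocationResult",
    "great_circle_nm",
    "find_candidate_grafts",
    "simulate_scenarios",
    "EARTH_RADIUS_KM",
    "KM_PER_NM",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088   # IUGG mean Earth radius
KM_PER_NM = 1.852             # international nautical mile

#: donor ages (whole years) counting as an adolescent donor
ADOLESCENT_DONOR_AGES = (12, 17)


def great_circle_nm(lat1, lon1, lat2, lon2):
    """Haversine great-circle distance in nautical miles.

    Spherical Earth of radius 6371.0088 km; 1 NM = 1852 m.  Inputs in
    degrees; scalars or arrays.  Raises on out-of-range coordinates.
    """
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float)
                              for x in (lat1, lon1, lat2, lon2))
    for lat in (lat1, lat2):
        if np.any(np.abs(lat) > 90):
            raise ValueError("latitude out of range [-90, 90]")
    for lon in (lon1, lon2):
        if np.any(np.abs(lon) > 180):
            raise ValueError("longitude out of range [-180, 180]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlmb = np.radians(lon2) - np.radians(lon1)
    h = np.sin(dphi / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlmb / 2) ** 2
    d_km = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    out = d_km / KM_PER_NM
    return float(out) if out.ndim == 0 else out


@dataclass
class ReallocationScenario:
    """One reallocation policy scenario.

    ``ceiling_nm=None`` means no distance limit.
    """
    ceiling_nm: float | None = 500.0
    window_days: int = 90
    weight_tolerance_kg: float = 20.0
    policy_start_date: date = ACUITY_CIRCLES_DATE

    def __post_init__(self):
        if self.ceiling_nm is not None and self.ceiling_nm <= 0:
            raise ValueError("ceiling_nm must be positive or None")
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")
        if self.weight_tolerance_kg < 0:
            raise ValueError("weight_tolerance_kg must be >= 0")


@dataclass
class ReallocationResult:
    """Wait-time distribution for one distance ceiling."""
    ceiling_nm: float | None
    #: index tx_id -> first candidate day (1..window) or NaN if none
    first_arrival_day: pd.Series = field(default_factory=pd.Series)
    #: index tx_id -> candidate DataFrame (graft_id, day, distance_nm)
    candidates: dict = field(default_factory=dict)
    #: fraction of index cases with an offer by day d, for d = 1..window
    cumulative_fraction: np.ndarray = field(
        default_factory=lambda: np.zeros(0))
    #: smallest day with cumulative_fraction >= 0.9; None if never reached
    p90_wait: int | None = None

    @property
    def fraction_matched(self) -> float:
        if len(self.cumulative_fraction) == 0:
            return 0.0
        return float(self.cumulative_fraction[-1])


def _coord_lookup(hospitals: pd.DataFrame):
    h = hospitals.set_index("hospital_id")
    return h["latitude"], h["longitude"]


def _prepare_stream(adult_stream: pd.DataFrame, hospitals: pd.DataFrame):
    """Pre-filter the adult stream to whole adolescent DBD grafts with
    known donor-hospital coordinates; records missing coordinates are
    skipped with a log entry."""
    lo, hi = ADOLESCENT_DONOR_AGES
    s = adult_stream
    s = s[s["donor_age"].between(lo, hi)
          & s["donor_type"].eq("DBD")
          & s["graft_type"].eq("whole")].copy()
    lat, lon = _coord_lookup(hospitals)
    s["_lat"] = s["donor_hospital"].map(lat)
    s["_lon"] = s["donor_hospital"].map(lon)
    missing = s["_lat"].isna() | s["_lon"].isna()
    if missing.any():
        for gid in s.loc[missing, "tx_id"]:
            logger.warning("skipping graft %s: unknown donor hospital "
                           "coordinates", gid)
        s = s[~missing]
    s["tx_date"] = pd.to_datetime(s["tx_date"])
    return s.sort_values(["tx_date", "tx_id"], kind="mergesort")


def find_candidate_grafts(index_row, adult_stream: pd.DataFrame,
                          scenario: ReallocationScenario,
                          hospitals: pd.DataFrame) -> pd.DataFrame:
    """Candidate reassignable grafts for one index transplant.

    Keeps adult-stream records that are whole grafts from adolescent
    (12-17 y) brain-dead donors, transplanted on days 1..window after
    the index date, with donor weight within the tolerance of the index
    recipient's weight and donor hospital within the distance ceiling of
    the index recipient's hospital.  Returns a DataFrame with columns
    ``graft_id``, ``day``, ``distance_nm`` ordered by day then distance.
    """
    stream = _prepare_stream(adult_stream, hospitals)
    lat, lon = _coord_lookup(hospitals)
    r_hosp = index_row["recipient_hospital"]
    if r_hosp not in lat.index or pd.isna(lat[r_hosp]):
        logger.warning("index case %s: unknown recipient hospital "
                       "coordinates", index_row.get("tx_id"))
        return pd.DataFrame(columns=["graft_id", "day", "distance_nm"])
    day = (stream["tx_date"] - pd.to_datetime(index_row["tx_date"])).dt.days
    ok = day.between(1, scenario.window_days)
    ok &= (stream["donor_weight"] - index_row["recipient_weight"]).abs() \
        <= scenario.weight_tolerance_kg
    dist = great_circle_nm(float(lat[r_hosp]), float(lon[r_hosp]),
                           stream["_lat"].to_numpy(),
                           stream["_lon"].to_numpy())
    dist = pd.Series(dist, index=stream.index)
    if scenario.ceiling_nm is not None:
        ok &= dist <= scenario.ceiling_nm
    out = pd.DataFrame({
        "graft_id": stream.loc[ok, "tx_id"],
        "day": day[ok].astype(int),
        "distance_nm": dist[ok],
    })
    return out.sort_values(["day", "distance_nm"],
                           kind="mergesort").reset_index(drop=True)


def _summarize(first_days: pd.Series, window: int):
    n = len(first_days)
    days = np.arange(1, window + 1)
    arrived = first_days.to_numpy(dtype=float)
    cum = np.array([(arrived[~np.isnan(arrived)] <= d).sum() / n
                    for d in days]) if n else np.zeros(window)
    reached = np.nonzero(cum >= 0.9)[0]
    p90 = int(days[reached[0]]) if len(reached) else None
    return cum, p90


def simulate_scenarios(index_cases: pd.DataFrame,
                       adult_stream: pd.DataFrame,
                       hospitals: pd.DataFrame,
                       ceilings=(500.0, 1000.0, 1500.0, None),
                       window_days: int = 90,
                       weight_tolerance_kg: float = 20.0,
                       policy_start_date: date = ACUITY_CIRCLES_DATE,
                       consume: bool = False) -> list[ReallocationResult]:
    """Evaluate the reallocation counterfactual under several ceilings.

    By default each index case is evaluated against the full adult
    stream (no graft consumption across index cases; each candidate
    keeps its own offer list).  ``consume=True`` enables a sensitivity
    mode in which index cases, processed in index-date order, remove
    their first-arriving graft from the stream.

    Returns one :class:`ReallocationResult` per ceiling.
    """
    if len(index_cases) == 0:
        raise ValueError("at least one index case is required")
    index_cases = index_cases.sort_values(
        ["tx_date", "tx_id"], kind="mergesort")
    results = []
    for ceiling in ceilings:
        scenario = ReallocationScenario(
            ceiling_nm=ceiling, window_days=window_days,
            weight_tolerance_kg=weight_tolerance_kg,
            policy_start_date=policy_start_date)
        first, cands = {}, {}
        consumed: set = set()
        for _, row in index_cases.iterrows():
            cl = find_candidate_grafts(row, adult_stream, scenario, hospitals)
            if consume and len(cl):
                cl = cl[~cl["graft_id"].isin(consumed)]
                if len(cl):
                    consumed.add(cl.iloc[0]["graft_id"])
            cands[row["tx_id"]] = cl.reset_index(drop=True)
            first[row["tx_id"]] = (int(cl["day"].iloc[0]) if len(cl)
                                   else np.nan)
        first = pd.Series(first, name="first_arrival_day")
        cum, p90 = _summarize(first, window_days)
        results.append(ReallocationResult(
            ceiling_nm=ceiling, first_arrival_day=first, candidates=cands,
            cumulative_fraction=cum, p90_wait=p90))
    return results
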