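"""Great-circle distances, candidate filtering vs a brute-force oracle,
and wait-time percentile behavior across distance ceilings."""

import numpy as np
import pandas as pd
import pytest

from agemix import (ReallocationScenario, find_candidate_grafts,
                    great_circle_nm, simulate_scenarios)
from tests.conftest import make_tx_row


class TestGreatCircle:
    def test_identical_points_zero(self):
        assert great_circle_nm(37.0, -122.0, 37.0, -122.0) == 0.0

    def test_antipodal_on_equator(self):
        # pi * 6371.0088 km / 1.852 km per NM
        assert great_circle_nm(0, 0, 0, 180) == pytest.approx(
            10807.30, abs=0.5)

    def test_one_degree_longitude_at_equator(self):
        # 6371.0088 * pi/180 km = 111.195 km -> 60.04 NM
        assert great_circle_nm(0, 0, 0, 1) == pytest.approx(60.04, abs=0.01)

    def test_symmetry_and_vectorization(self):
        d1 = great_circle_nm(40.7, -74.0, 34.0, -118.2)
        d2 = great_circle_nm(34.0, -118.2, 40.7, -74.0)
        assert d1 == pytest.approx(d2)
        arr = great_circle_nm(np.array([0.0, 40.7]), np.array([0.0, -74.0]),
                              np.array([0.0, 34.0]), np.array([1.0, -118.2]))
        assert arr[1] == pytest.approx(d1)

    def test_out_of_range_coordinates_rejected(self):
        with pytest.raises(ValueError):
            great_circle_nm(91.0, 0, 0, 0)
        with pytest.raises(ValueError):
            great_circle_nm(0, 181.0, 0, 0)


def _toy_hospitals():
    # one degree of longitude at the equator is ~60 NM
    return pd.DataFrame({
        "hospital_id": ["HA", "HB", "HC", "HD"],
        "latitude": [0.0, 0.0, 0.0, 0.0],
        "longitude": [0.0, 1.0, 8.0, 30.0],  # ~60, ~480, ~1800 NM from HA
    })


def _toy_stream():
    """8 adult-stream records; 3 violate the reassignment rules for the
    toy index case (weight 55 kg, hospital HA, index date 2021-01-01)."""
    mk = lambda i, **kw: make_tx_row(i, recipient_category="adult", **kw)
    rows = [
        mk(0, tx_date=pd.Timestamp("2021-01-02"), donor_weight=60.0,
           donor_hospital="HB"),                      # ok: day 1, 60 NM
        mk(1, tx_date=pd.Timestamp("2021-01-05"), donor_weight=74.0,
           donor_hospital="HA"),                      # ok: |74-55| < 20
        mk(2, tx_date=pd.Timestamp("2021-01-05"), donor_weight=76.0,
           donor_hospital="HA"),                      # weight off by 21
        mk(3, tx_date=pd.Timestamp("2021-01-01"), donor_weight=55.0,
           donor_hospital="HA"),                      # day 0: same day
        mk(4, tx_date=pd.Timestamp("2021-03-31"), donor_weight=55.0,
           donor_hospital="HA"),                      # day 89: ok
        mk(5, tx_date=pd.Timestamp("2021-06-01"), donor_weight=55.0,
           donor_hospital="HA"),                      # beyond 90 days
        mk(6, tx_date=pd.Timestamp("2021-01-15"), donor_weight=50.0,
           donor_hospital="HD"),                      # ok: ~1800 NM
        mk(7, tx_date=pd.Timestamp("2021-01-10"), donor_weight=55.0,
           donor_hospital="HC"),                      # ok: ~480 NM
    ]
    df = pd.DataFrame(rows)
    df["donor_age"] = 15
    return df


def _index_case():
    return pd.Series(make_tx_row(99, tx_date=pd.Timestamp("2021-01-01"),
                                 recipient_weight=55.0,
                                 recipient_hospital="HA",
                                 donor_age=40))


def brute_force_candidates(index, stream, hospitals, ceiling, window=90,
                           tol=20.0):
    """Exhaustive per-record rule check, independent of the library."""
    coords = hospitals.set_index("hospital_id")
    out = []
    for _, r in stream.iterrows():
        day = (r["tx_date"] - index["tx_date"]).days
        if not (12 <= r["donor_age"] <= 17 and r["donor_type"] == "DBD"
                and r["graft_type"] == "whole" and 1 <= day <= window
                and abs(r["donor_weight"] - index["recipient_weight"]) <= tol):
            continue
        d = great_circle_nm(
            coords.loc[index["recipient_hospital"], "latitude"],
            coords.loc[index["recipient_hospital"], "longitude"],
            coords.loc[r["donor_hospital"], "latitude"],
            coords.loc[r["donor_hospital"], "longitude"])
        if ceiling is not None and d > ceiling:
            continue
        out.append((day, d, r["tx_id"]))
    out.sort()
    return [t for _, _, t in out]


class TestFindCandidates:
    def test_toy_stream_matches_brute_force(self):
        """5 of 8 toy records are eligible without a distance limit;
        the list equals the exhaustive rule check."""
        cands = find_candidate_grafts(_index_case(), _toy_stream(),
                                      ReallocationScenario(ceiling_nm=None),
                                      _toy_hospitals())
        expected = brute_force_candidates(_index_case(), _toy_stream(),
                                          _toy_hospitals(), None)
        assert len(cands) == 5
        assert list(cands["graft_id"]) == expected

    def test_day_boundaries(self):
        cands = find_candidate_grafts(_index_case(), _toy_stream(),
                                      ReallocationScenario(ceiling_nm=None),
                                      _toy_hospitals())
        ids = set(cands["graft_id"])
        assert "T0003" not in ids     # same-day graft (day 0)
        assert "T0000" in ids         # day 1
        assert "T0004" in ids         # day 89
        assert "T0005" not in ids     # beyond the 90-day window

    def test_weight_tolerance_boundary(self):
        cands = find_candidate_grafts(_index_case(), _toy_stream(),
                                      ReallocationScenario(ceiling_nm=None),
                                      _toy_hospitals())
        ids = set(cands["graft_id"])
        assert "T0001" in ids         # |74 - 55| = 19 <= 20
        assert "T0002" not in ids     # |76 - 55| = 21 > 20

    def test_split_grafts_excluded(self):
        stream = _toy_stream()
        stream.loc[stream["tx_id"] == "T0007",
                   "graft_type"] = "split_or_reduced"
        cands = find_candidate_grafts(_index_case(), stream,
                                      ReallocationScenario(ceiling_nm=None),
                                      _toy_hospitals())
        assert "T0007" not in set(cands["graft_id"])
        assert list(cands["graft_id"]) == brute_force_candidates(
            _index_case(), stream, _toy_hospitals(), None)

    def test_distance_ceiling_filters(self):
        cands = find_candidate_grafts(_index_case(), _toy_stream(),
                                      ReallocationScenario(ceiling_nm=100.0),
                                      _toy_hospitals())
        # only HA (0 NM) and HB (~60 NM) donors remain
        assert set(cands["graft_id"]) == {"T0000", "T0001", "T0004"}

    def test_ceiling_subsets_are_distance_filtered_unlimited_lists(self):
        unlimited = find_candidate_grafts(
            _index_case(), _toy_stream(),
            ReallocationScenario(ceiling_nm=None), _toy_hospitals())
        for ceiling in (100.0, 500.0, 1500.0):
            capped = find_candidate_grafts(
                _index_case(), _toy_stream(),
                ReallocationScenario(ceiling_nm=ceiling), _toy_hospitals())
            ref = unlimited[unlimited["distance_nm"] <= ceiling]
            assert list(capped["graft_id"]) == list(ref["graft_id"])

    def test_ordered_by_day_then_distance(self):
        cands = find_candidate_grafts(_index_case(), _toy_stream(),
                                      ReallocationScenario(ceiling_nm=None),
                                      _toy_hospitals())
        key = list(zip(cands["day"], cands["distance_nm"]))
        assert key == sorted(key)


def _index_frame(days):
    rows = []
    for i, d in enumerate(days):
        rows.append(make_tx_row(
            500 + i, tx_date=pd.Timestamp("2021-01-01"),
            recipient_weight=55.0, recipient_hospital="HA", donor_age=40))
    return pd.DataFrame(rows)


def _stream_with_first_days(days):
    """One eligible graft per index case arriving on the given day."""
    rows = []
    for i, d in enumerate(days):
        rows.append(make_tx_row(
            700 + i, recipient_category="adult", donor_age=15,
            tx_date=pd.Timestamp("2021-01-01") + pd.Timedelta(days=d),
            donor_weight=55.0, donor_hospital="HA"))
    return pd.DataFrame(rows)


class TestSimulateScenarios:
    def test_p90_smallest_day_reaching_90_percent(self):
        """10 index cases whose first arrivals are days 1..10: 9 of 10
        (90%) are matched by day 9, so p90 = 9."""
        idx = _index_frame(range(10))
        stream = _stream_with_first_days(range(1, 11))
        res = simulate_scenarios(idx, stream, _toy_hospitals(),
                                 ceilings=(None,))
        # every index case sees all grafts; first arrival is day 1
        assert res[0].p90_wait == 1
        # per-case percentile check with distinct first arrivals: give
        # each case its own weight band so case i only matches graft i
        idx2 = _index_frame(range(10))
        idx2["recipient_weight"] = [55.0 + 100 * i for i in range(10)]
        stream2 = _stream_with_first_days(range(1, 11))
        stream2["donor_weight"] = [55.0 + 100 * i for i in range(10)]
        res2 = simulate_scenarios(idx2, stream2, _toy_hospitals(),
                                  ceilings=(None,))
        arrivals = sorted(res2[0].first_arrival_day)
        assert arrivals == list(range(1, 11))
        assert res2[0].p90_wait == 9

    def test_day_one_candidates_give_p90_of_one(self):
        idx = _index_frame(range(5))
        stream = _stream_with_first_days([1])
        res = simulate_scenarios(idx, stream, _toy_hospitals(),
                                 ceilings=(500.0, None))
        assert all(r.p90_wait == 1 for r in res)

    def test_p90_none_when_90_percent_never_reached(self):
        idx = _index_frame(range(10))
        stream = _stream_with_first_days([5])
        stream["donor_weight"] = 300.0  # eligible for no one
        res = simulate_scenarios(idx, stream, _toy_hospitals(),
                                 ceilings=(None,))
        assert res[0].p90_wait is None
        assert res[0].fraction_matched == 0.0

    def test_cumulative_fraction_non_decreasing(self):
        idx = _index_frame(range(4))
        stream = _stream_with_first_days([3, 10, 40, 80])
        res = simulate_scenarios(idx, stream, _toy_hospitals(),
                                 ceilings=(500.0, None))
        for r in res:
            assert np.all(np.diff(r.cumulative_fraction) >= 0)

    def test_p90_non_increasing_in_ceiling(self, small_registry):
        """Raising the distance ceiling can only bring offers forward."""
        from agemix import apply_inclusion
        cfg, hospitals, a, ad = small_registry
        cohort, _ = apply_inclusion(a, admin_censor_date=cfg.admin_censor_date)
        idx = cohort[cohort["age_mismatched"]
                     & (cohort["tx_date"] >= pd.Timestamp("2020-02-04"))]
        res = simulate_scenarios(idx, ad, hospitals,
                                 ceilings=(500.0, 1000.0, 1500.0, None))
        p90s = [r.p90_wait if r.p90_wait is not None else np.inf
                for r in res]
        assert p90s == sorted(p90s, reverse=True) or \
            all(a >= b for a, b in zip(p90s, p90s[1:]))

    def test_row_order_invariance(self):
        idx = _index_frame(range(6))
        stream = _stream_with_first_days([2, 7, 30, 50, 70, 88])
        base = simulate_scenarios(idx, stream, _toy_hospitals(),
                                  ceilings=(None,))
        shuffled = stream.sample(frac=1.0, random_state=3)
        alt = simulate_scenarios(idx.sample(frac=1.0, random_state=4),
                                 shuffled, _toy_hospitals(),
                                 ceilings=(None,))
        pd.testing.assert_series_equal(
            base[0].first_arrival_day.sort_index(),
            alt[0].first_arrival_day.sort_index())

    def test_consume_mode_assigns_each_graft_once(self):
        idx = _index_frame(range(3))
        stream = _stream_with_first_days([1, 2, 5])
        res = simulate_scenarios(idx, stream, _toy_hospitals(),
                                 ceilings=(None,), consume=True)
        firsts = sorted(res[0].first_arrival_day)
        assert firsts == [1, 2, 5]   # no sharing of the day-1 graft

    def test_empty_index_cases_rejected(self):
        with pytest.raises(ValueError):
            simulate_scenarios(_index_frame([]), _stream_with_first_days([1]),
                               _toy_hospitals(), ceilings=(None,))

    def test_scenario_validation(self):
        with pytest.raises(ValueError):
            ReallocationScenario(ceiling_nm=-5)
        with pytest.raises(ValueError):
            ReallocationScenario(window_days=0)
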