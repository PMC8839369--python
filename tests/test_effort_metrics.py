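import numpy as np
import pandas as pd
import pytest

from haultrack.datasets import reference_trip_log
from haultrack.effort_metrics import (
    activity_by_hour,
    haversine_km,
    speed_by_state,
    summaries_frame,
    trip_distance,
    trip_duration,
    trip_summary,
)
from haultrack.fishing_activity import classify_activity, speed_threshold
from haultrack.geofence import TripValidation, containment_mask, derive_crossings, validate_trip
from haultrack.trip_segmentation import segment_trips

from conftest import make_stream, minute_times


class TestTripDuration:
    @pytest.mark.parametrize(
        "start,end,expected",
        [
            ("2021-11-01 01:40:10", "2021-11-01 06:50:47", 5.18),
            ("2021-11-22 01:45:45", "2021-11-22 08:09:12", 6.39),
            ("2021-11-01 01:00:00", "2021-11-01 02:00:00", 1.00),
        ],
    )
    def test_known_durations(self, start, end, expected):
        assert round(trip_duration(start, end), 2) == expected

    def test_end_before_start_raises(self):
        with pytest.raises(ValueError):
            trip_duration("2021-11-01 02:00:00", "2021-11-01 01:00:00")


class TestHaversine:
    def test_identical_points_are_zero(self):
        assert haversine_km((43.6, 13.5), (43.6, 13.5)) == 0.0

    def test_one_degree_of_latitude(self):
        # closed form: 2*pi*R/360 = 111.1949 km
        assert haversine_km((0, 0), (1, 0)) == pytest.approx(111.19, abs=0.01)

    def test_symmetry_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            a = (rng.uniform(-89, 89), rng.uniform(-179, 179))
            b = (rng.uniform(-89, 89), rng.uniform(-179, 179))
            assert haversine_km(a, b) == pytest.approx(haversine_km(b, a))

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            haversine_km((91, 0), (0, 0))


class TestTripDistance:
    def test_single_ping_is_zero(self):
        stream = make_stream(["2021-11-01 01:00:00"])
        assert trip_distance(stream.data) == 0.0

    def test_three_collinear_pings_one_km_apart(self):
        # 1 km of latitude = (1/111.1949) degrees
        dlat = 1.0 / (2 * np.pi * 6371.0 / 360.0)
        stream = make_stream(
            minute_times("2021-11-01 01:00:00", 3),
            latitudes=[43.0, 43.0 + dlat, 43.0 + 2 * dlat],
            longitudes=[13.0] * 3,
        )
        assert trip_distance(stream.data) == pytest.approx(2.0, abs=1e-6)

    def test_track_at_least_as_long_as_endpoint_distance(self, sim_month):
        _, stream, _ = sim_month
        for trip in segment_trips(stream):
            pings = stream.slice(trip.indices)
            direct = haversine_km(
                (pings["latitude"].iloc[0], pings["longitude"].iloc[0]),
                (pings["latitude"].iloc[-1], pings["longitude"].iloc[-1]),
            )
            assert trip_distance(pings) >= direct - 1e-9


def _summaries(sim):
    config, stream, _ = sim
    seg = segment_trips(stream)
    trip_pings = stream.data.loc[seg.membership(len(stream)) > 0]
    at_sea = ~containment_mask(trip_pings, config.port_polygon)
    threshold = speed_threshold(trip_pings.loc[at_sea, "speed"])
    out = []
    for trip in seg:
        pings = stream.slice(trip.indices)
        labels = classify_activity(pings, threshold, config.port_polygon)
        validation = validate_trip(trip, derive_crossings(trip, stream, config.port_polygon))
        out.append((trip, pings, labels, trip_summary(trip, pings, labels, validation)))
    return out


class TestTripSummary:
    def test_constant_speed_mean(self):
        stream = make_stream(minute_times("2021-11-01 01:00:00", 20), speeds=[6.0] * 20)
        seg = segment_trips(stream, min_pings=1)
        labels = classify_activity(stream.data, threshold=10.0, polygon=None)
        summary = trip_summary(seg[0], stream.data, labels, TripValidation("valid", 1, 1))
        assert summary.speed_avg_kmh == pytest.approx(6.0)

    def test_fields_match_simulator_truth(self, sim_month):
        config, stream, truth = sim_month
        rows = _summaries((config, stream, None))
        for (trip, pings, labels, summary), sched in zip(
            rows, truth.schedule.itertuples(index=False)
        ):
            assert summary.trip_start == sched.start_time
            assert summary.trip_end == sched.end_time
            assert summary.duration_h == pytest.approx(
                (sched.end_time - sched.start_time).total_seconds() / 3600
            )
            # recovered hauling within one ping interval per bout of the truth
            assert summary.hauler_h * 60 == pytest.approx(sched.hauling_minutes, abs=3.0)
            if sched.set_only:
                assert round(summary.hauler_h, 2) == 0.00
            assert summary.hauler_h <= summary.duration_h
            n_logged = (truth.crossings["trip_id"] == trip.trip_id).sum()
            assert summary.n_entry + summary.n_exit == n_logged

    def test_summary_table_header(self, sim_month):
        rows = _summaries((sim_month[0], sim_month[1], None))
        frame = summaries_frame([s for *_, s in rows])
        assert list(frame.columns) == [
            "Trip", "tripStart", "tripEnd", "Duration (h)", "SA (kmh)",
            "Distance (km)", "Hauler (h)", "Entry", "Exit",
        ]
        assert len(frame) == 28


class TestReferenceLog:
    def test_durations_reconstruct_to_two_decimals(self):
        log = reference_trip_log()
        for row in log.itertuples(index=False):
            duration = trip_duration(row.tripStart, row.tripEnd)
            assert round(duration, 2) == row[3], f"trip {row.Trip}"

    def test_hauler_hours_never_exceed_duration(self):
        log = reference_trip_log()
        assert (log["Hauler (h)"] <= log["Duration (h)"]).all()


class TestProfiles:
    def test_no_hauling_gives_zero_vector(self):
        stream = make_stream(minute_times("2021-11-01 01:00:00", 10))
        labels = classify_activity(stream.data, threshold=10.0, polygon=None)
        assert activity_by_hour(labels, stream.data).sum() == 0.0

    def test_half_hour_of_hauling_lands_in_its_hour_bin(self):
        # 30 hauling pings wholly inside 02:00-02:30, plus a trailing idle ping
        stream = make_stream(
            minute_times("2021-11-01 02:00:00", 31),
            speeds=[1.0] * 31,
            sensors=[0] * 30 + [1],
        )
        labels = classify_activity(stream.data, threshold=5.0, polygon=None)
        bins = activity_by_hour(labels, stream.data)
        assert bins[2] == pytest.approx(30.0)
        assert bins.sum() == pytest.approx(30.0)

    def test_bins_conserve_total_hauling_minutes(self, sim_month):
        from haultrack.fishing_activity import hauling_duration

        for trip, pings, labels, _ in _summaries(sim_month):
            bins = activity_by_hour(labels, pings)
            assert bins.sum() == pytest.approx(hauling_duration(labels, pings) * 60)

    def test_speed_by_state_counts_and_hauling_range(self, sim_month):
        config, stream, _ = sim_month
        rows = _summaries(sim_month)
        all_pings = pd.concat([p for _, p, _, _ in rows])
        all_labels = pd.concat([l for _, _, l, _ in rows])
        stats = speed_by_state(all_labels, all_pings)
        assert stats["n"].sum() == len(all_pings)
        hauling = stats.loc[stats["state"] == "hauling"].iloc[0]
        lo, hi = config.hauling_speed_kmh
        assert lo <= hauling["median"] <= hi
        assert hauling["q3"] >= hauling["median"] >= hauling["q1"]

    def test_constant_speed_state_has_zero_iqr(self):
        stream = make_stream(minute_times("2021-11-01 01:00:00", 5), speeds=[3.0] * 5)
        labels = classify_activity(stream.data, threshold=5.0, polygon=None)
        stats = speed_by_state(labels, stream.data)
        row = stats.loc[stats["state"] == "other"].iloc[0]
        assert row["median"] == 3.0 and row["q3"] - row["q1"] == 0.0
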