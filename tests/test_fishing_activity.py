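import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haultrack.fishing_activity import (
    classify_activity,
    condition_hauler_signal,
    hauler_hold_intervals,
    hauling_duration,
    speed_threshold,
)
from haultrack.geofence import GeofencePolygon, containment_mask
from haultrack.trip_segmentation import segment_trips

from conftest import make_stream, minute_times


class TestConditionHaulerSignal:
    def test_all_inactive_stays_inactive(self):
        raw = [(t, False) for t in range(0, 300, 60)]
        assert all(not a for _, a in condition_hauler_signal(raw))

    def test_single_pulse_held_for_one_minute(self):
        raw = [(0.0, True), (30.0, False), (59.0, False), (60.0, False), (61.0, False)]
        out = dict(condition_hauler_signal(raw, hold=60))
        assert out[0.0] and out[30.0] and out[59.0]
        assert not out[60.0] and not out[61.0]  # active over [0, 60) only

    def test_pulses_at_0_and_30_merge_into_90s_interval(self):
        raw = [(0.0, True), (30.0, True)]
        assert hauler_hold_intervals(raw, hold=60) == [(0.0, 90.0)]

    def test_separated_pulses_stay_separate(self):
        raw = [(0.0, True), (200.0, True)]
        assert hauler_hold_intervals(raw, hold=60) == [(0.0, 60.0), (200.0, 260.0)]

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            condition_hauler_signal([(10.0, True), (5.0, False)])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        pulses=st.lists(st.integers(0, 50), min_size=0, max_size=12, unique=True),
        hold=st.integers(10, 120),
    )
    def test_hold_extends_but_is_bounded(self, pulses, hold):
        raw = [(float(10 * t), t in pulses) for t in range(51)]
        intervals = hauler_hold_intervals(raw, hold=float(hold))
        total = sum(b - a for a, b in intervals)
        assert total >= (len(pulses) > 0) * hold  # at least one full hold if any pulse
        assert total <= len(pulses) * hold        # each pulse adds at most `hold`
        starts = [a for a, _ in intervals]
        assert starts == sorted(starts)           # merged, ordered, disjoint
        assert all(b1 < a2 for (_, b1), (a2, _) in zip(intervals, intervals[1:]))


class TestSpeedThreshold:
    @pytest.mark.parametrize(
        "speeds,q,expected",
        [([3, 3, 3, 3], 0.75, 3.0), ([1, 2, 3, 4], 0.75, 3.25), ([5], 0.75, 5.0)],
    )
    def test_linear_interpolated_quantile(self, speeds, q, expected):
        assert speed_threshold(speeds, q) == pytest.approx(expected)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            speed_threshold([])


PORT = GeofencePolygon("p", ((13.0, 43.0), (13.1, 43.0), (13.1, 43.1), (13.0, 43.1), (13.0, 43.0)))


class TestClassifyActivity:
    def _one(self, speed, sensor, lon=13.6, lat=43.6, threshold=5.0, polygon=PORT):
        stream = make_stream(
            ["2021-11-01 01:00:00"], speeds=[speed], sensors=[sensor],
            longitudes=[lon], latitudes=[lat],
        )
        return classify_activity(stream.data, threshold, polygon).iloc[0]

    def test_slow_sensor_active_at_sea_is_hauling(self):
        assert self._one(speed=1.5, sensor=0) == "hauling"

    def test_steaming_overrides_active_sensor(self):
        assert self._one(speed=8.0, sensor=0) == "steaming"

    def test_inside_port_overrides_everything(self):
        assert self._one(speed=1.5, sensor=0, lon=13.05, lat=43.05) == "in_port"

    def test_slow_sensor_inactive_is_other(self):
        assert self._one(speed=1.5, sensor=1) == "other"

    def test_no_polygon_never_labels_in_port(self):
        assert self._one(speed=1.5, sensor=0, lon=13.05, lat=43.05, polygon=None) == "hauling"

    def test_labels_partition_the_trip(self, sim_month):
        config, stream, _ = sim_month
        seg = segment_trips(stream)
        trip = seg[0]
        pings = stream.slice(trip.indices)
        labels = classify_activity(pings, threshold=5.0, polygon=config.port_polygon)
        assert labels.notna().all()
        assert labels.value_counts().sum() == trip.n_pings


class TestHaulingDuration:
    def test_no_hauling_gives_zero(self):
        stream = make_stream(minute_times("2021-11-01 01:00:00", 10), sensors=[1] * 10)
        labels = classify_activity(stream.data, threshold=5.0, polygon=None)
        assert hauling_duration(labels, stream.data) == 0.0

    def test_sixty_consecutive_hauling_minutes_is_one_hour(self):
        # 60 hauling pings at 60 s spacing followed by one idle ping
        stream = make_stream(
            minute_times("2021-11-01 01:00:00", 61),
            speeds=[1.0] * 61, sensors=[0] * 60 + [1],
        )
        labels = classify_activity(stream.data, threshold=5.0, polygon=None)
        assert hauling_duration(labels, stream.data) == pytest.approx(1.0)

    def test_single_isolated_hauling_ping_credits_one_interval(self):
        stream = make_stream(
            minute_times("2021-11-01 01:00:00", 3),
            speeds=[1.0] * 3, sensors=[1, 0, 1],
        )
        labels = classify_activity(stream.data, threshold=5.0, polygon=None)
        assert hauling_duration(labels, stream.data) == pytest.approx(1 / 60)

    def test_hauling_recovery_on_simulation(self, sim_month):
        config, stream, truth = sim_month
        seg = segment_trips(stream)
        trip_pings = stream.data.loc[seg.membership(len(stream)) > 0]
        at_sea = ~containment_mask(trip_pings, config.port_polygon)
        threshold = speed_threshold(trip_pings.loc[at_sea, "speed"])
        recovered = 0.0
        for trip in seg:
            pings = stream.slice(trip.indices)
            labels = classify_activity(pings, threshold, config.port_polygon)
            recovered += hauling_duration(labels, pings) * 60
        injected = truth.hauling_minutes()
        assert recovered >= 0.95 * injected
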