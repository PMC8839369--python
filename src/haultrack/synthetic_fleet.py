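"""Synthetic vessel fleet: ping streams with ground truth.

Generates the ping stream a tracked passive-gear vessel would produce
over a number of days, together with the ground truth needed to verify
every pipeline stage: per-ping trip membership and activity state, the
trip schedule, the geofence crossing log, and injected-outlier indices.

The behaviour model mirrors the monitored fleet: generally two trips per
day, one early in the morning (01:00–06:00 window) and one in the
afternoon/evening (13:00–18:00); each trip powers the tracker on (a short
run of boot pings with zero satellites and zero power), idles in port,
steams to the fishing ground at 6–9 km/h, alternates hauling bouts
(0.3–2 km/h, hauler sensor asserted) with gear-setting stretches, and
steams home. Some trips only set gear and show no hauling at all. A trip
can optionally cut back through the port polygon mid-trip to reach
grounds on the opposite side, which doubles its geofence event counts.

Trajectories are built in a local tangent plane around the port anchor
and converted to WGS84; curvature error is negligible at a ~25 km
operating radius. Movement is piecewise-constant speed with heading
noise — enough to exercise every pipeline rule, with no pretence of
oceanographic realism. The hauler line is produced the way the hardware
produces it: raw rotation pulses at sub-ping resolution with random
dropouts, conditioned by the 1-minute minimum hold, then sampled at ping
times.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from haultrack.datasets import REFERENCE_PORT_LONLAT
from haultrack.geofence import GeofencePolygon, containment_mask
from haultrack.fishing_activity import hauler_hold_intervals
from haultrack.ping_model import COLUMNS, PingStream

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimConfigError",
    "default_port_polygon",
    "simulate_trip",
    "simulate_dataset",
    "compress_port_stop",
]

#: Meters per degree of latitude on the reference sphere.
_M_PER_DEG_LAT = 111194.9


class SimConfigError(ValueError):
    """The simulation configuration is inconsistent or infeasible."""


def default_port_polygon(
    anchor: tuple[float, float] = REFERENCE_PORT_LONLAT, half_size_m: float = 400.0
) -> GeofencePolygon:
    """A square port geofence of the given half-width around the anchor."""
    lon0, lat0 = anchor
    dlat = half_size_m / _M_PER_DEG_LAT
    dlon = half_size_m / (_M_PER_DEG_LAT * np.cos(np.radians(lat0)))
    ring = (
        (lon0 - dlon, lat0 - dlat),
        (lon0 + dlon, lat0 - dlat),
        (lon0 + dlon, lat0 + dlat),
        (lon0 - dlon, lat0 + dlat),
        (lon0 - dlon, lat0 - dlat),
    )
    return GeofencePolygon(name="port", ring=ring)


@dataclass
class SimConfig:
    """Study conditions for the simulated vessel.

    Defaults emulate the reference deployment: 60-second pings, two trips
    per day in the early-morning and afternoon windows, steaming at
    6–9 km/h, hauling below 2 km/h (so the 75th-quantile steaming rule is
    learnable by construction), boot runs of 2–4 pings, and an occasional
    set-only trip with no hauling.
    """

    seed: int = 0
    port_anchor: tuple[float, float] = REFERENCE_PORT_LONLAT  # (lon, lat)
    port_polygon: GeofencePolygon | None = None
    start_date: str = "2021-11-01"
    n_days: int = 14
    trips_per_day: int = 2
    trip_windows: tuple[tuple[float, float], ...] = ((1.0, 6.0), (13.0, 18.0))
    ping_interval_s: float = 60.0
    steaming_speed_kmh: tuple[float, float] = (6.0, 9.0)
    hauling_speed_kmh: tuple[float, float] = (0.3, 2.0)
    setting_speed_kmh: tuple[float, float] = (1.0, 3.0)
    ground_distance_km: tuple[float, float] = (4.0, 10.0)
    hauling_bouts_per_trip: tuple[int, int] = (1, 3)
    bout_len_pings: tuple[int, int] = (15, 40)
    setting_len_pings: tuple[int, int] = (8, 20)
    boot_run_pings: tuple[int, int] = (2, 4)
    p_set_only: float = 0.15
    p_double_visit: float = 0.0
    n_speed_outliers: int = 0
    n_course_outliers: int = 0
    gps_noise_m: float = 5.0
    hold_s: float = 60.0
    device_id: int = 1

    def __post_init__(self) -> None:
        for lo, hi in self.trip_windows:
            if not (0 <= lo < hi <= 24):
                raise SimConfigError(f"trip window ({lo}, {hi}) not within a day")
        if len(self.trip_windows) < self.trips_per_day:
            raise SimConfigError("need one trip window per daily trip")
        if min(self.steaming_speed_kmh) < 0 or min(self.hauling_speed_kmh) < 0:
            raise SimConfigError("speeds must be non-negative")
        if max(self.hauling_speed_kmh) >= min(self.steaming_speed_kmh):
            raise SimConfigError(
                "hauling speed range must lie strictly below the steaming range"
            )
        if self.port_polygon is None:
            self.port_polygon = default_port_polygon(self.port_anchor)


@dataclass
class SimTruth:
    """Ground truth aligned index-for-index with the emitted stream.

    ``per_ping`` has one row per stream position with ``trip_id`` (0 for
    pings outside any trip, i.e. boot pings) and ``activity`` (``boot``,
    ``in_port``, ``steaming``, ``hauling``, ``other``). ``schedule`` has
    one row per trip; ``crossings`` is the geofence crossing log;
    ``outlier_indices`` lists positions of injected kinematic outliers.
    """

    per_ping: pd.DataFrame
    schedule: pd.DataFrame
    crossings: pd.DataFrame
    outlier_indices: dict[str, list[int]] = field(default_factory=dict)

    @property
    def all_outlier_indices(self) -> list[int]:
        return sorted(set(self.outlier_indices.get("speed", []))
                      | set(self.outlier_indices.get("course", [])))

    def hauling_minutes(self, trip_id: int | None = None) -> float:
        sched = self.schedule
        if trip_id is not None:
            sched = sched[sched["trip_id"] == trip_id]
        return float(sched["hauling_minutes"].sum())


def _to_lonlat(x: np.ndarray, y: np.ndarray, anchor: tuple[float, float]):
    lon0, lat0 = anchor
    lat = lat0 + y / _M_PER_DEG_LAT
    lon = lon0 + x / (_M_PER_DEG_LAT * np.cos(np.radians(lat0)))
    return lon, lat


def _steaming_leg(pos, target, speed_range, interval_s, rng):
    """Pings from ``pos`` toward ``target`` at steaming speed.

    Returns (list of (x, y, speed, course), final position). The leg ends
    when the remaining distance is below one step; the caller snaps to the
    target.
    """
    out = []
    x, y = pos
    tx, ty = target
    while True:
        dx, dy = tx - x, ty - y
        remaining = float(np.hypot(dx, dy))
        speed = float(rng.uniform(*speed_range))
        step = speed * interval_s / 3.6  # km/h * s -> m
        if remaining <= step:
            break
        bearing = np.arctan2(dx, dy) + np.radians(rng.normal(0.0, 4.0))
        x += step * np.sin(bearing)
        y += step * np.cos(bearing)
        course = float(np.degrees(bearing) % 360.0)
        out.append((x, y, speed, course))
    return out, (x, y)


def _drift_segment(pos, n, speed_range, interval_s, rng):
    """Slow random-walk pings (hauling or setting)."""
    out = []
    x, y = pos
    heading = rng.uniform(0, 2 * np.pi)
    for _ in range(n):
        speed = float(rng.uniform(*speed_range))
        step = speed * interval_s / 3.6
        heading += rng.normal(0.0, 0.4)
        x += step * np.sin(heading)
        y += step * np.cos(heading)
        out.append((x, y, speed, float(np.degrees(heading) % 360.0)))
    return out, (x, y)


def _port_jitter(n, rng, spread_m=40.0):
    pts = rng.normal(0.0, spread_m, size=(n, 2))
    return [(float(px), float(py)) for px, py in pts]


def simulate_trip(
    config: SimConfig,
    day: pd.Timestamp,
    window: tuple[float, float],
    rng: np.random.Generator,
    set_only: bool | None = None,
    double_visit: bool | None = None,
) -> pd.DataFrame:
    """Simulate one trip inside a daily window.

    Returns a frame with one row per ping: ``t`` (timestamp), ``x``/``y``
    (tangent-plane meters), ``speed``, ``course``, ``boot`` flag, and the
    true ``state``. Hauler sensor sampling is applied later, dataset-wide.
    """
    lo, hi = window
    if hi - lo < 1.0:
        raise SimConfigError(f"window ({lo}, {hi}) shorter than a minimal trip (1 h)")
    if set_only is None:
        set_only = bool(rng.random() < config.p_set_only)
    if double_visit is None:
        double_visit = bool(rng.random() < config.p_double_visit)

    interval = config.ping_interval_s
    rows: list[tuple[float, float, float, float, bool, str]] = []  # x, y, speed, course, boot, state

    def emit(points, state, boot=False):
        for x, y, speed, course in points:
            rows.append((x, y, speed, course, boot, state))

    def port_block(n):
        pts = _port_jitter(n, rng)
        emit([(x, y, float(rng.uniform(0.0, 0.8)), float(rng.uniform(0, 360))) for x, y in pts],
             "in_port")

    # power-on boot run
    nb = int(rng.integers(config.boot_run_pings[0], config.boot_run_pings[1] + 1))
    emit([(0.0, 0.0, 0.0, 0.0)] * nb, "boot", boot=True)
    port_block(int(rng.integers(2, 5)))

    bearing = rng.uniform(0, 2 * np.pi)
    dist = rng.uniform(*config.ground_distance_km) * 1000.0
    ground_a = (dist * np.sin(bearing), dist * np.cos(bearing))
    pos = (0.0, 0.0)

    leg, pos = _steaming_leg(pos, ground_a, config.steaming_speed_kmh, interval, rng)
    emit(leg, "steaming")

    if set_only:
        n_bouts = 0
        seg, pos = _drift_segment(pos, int(rng.integers(20, 41)),
                                  config.setting_speed_kmh, interval, rng)
        emit(seg, "other")
    else:
        n_bouts = int(rng.integers(config.hauling_bouts_per_trip[0],
                                   config.hauling_bouts_per_trip[1] + 1))
        bouts_here = int(np.ceil(n_bouts / 2)) if double_visit else n_bouts

        def activity_block(k):
            nonlocal pos
            for _ in range(k):
                seg, pos = _drift_segment(
                    pos, int(rng.integers(*config.bout_len_pings)),
                    config.hauling_speed_kmh, interval, rng)
                emit(seg, "hauling")
                seg, pos = _drift_segment(
                    pos, int(rng.integers(*config.setting_len_pings)),
                    config.setting_speed_kmh, interval, rng)
                emit(seg, "other")

        activity_block(bouts_here)
        if double_visit:
            # cut back through the port polygon to the opposite ground
            leg, pos = _steaming_leg(pos, (0.0, 0.0), config.steaming_speed_kmh, interval, rng)
            emit(leg, "steaming")
            pos = (0.0, 0.0)
            dist_b = rng.uniform(*config.ground_distance_km) * 1000.0
            ground_b = (-dist_b * np.sin(bearing), -dist_b * np.cos(bearing))
            leg, pos = _steaming_leg(pos, ground_b, config.steaming_speed_kmh, interval, rng)
            emit(leg, "steaming")
            activity_block(max(n_bouts - bouts_here, 1))

    leg, pos = _steaming_leg(pos, (0.0, 0.0), config.steaming_speed_kmh, interval, rng)
    emit(leg, "steaming")
    port_block(int(rng.integers(2, 5)))
    # power-off boot run
    nb = int(rng.integers(config.boot_run_pings[0], config.boot_run_pings[1] + 1))
    emit([(0.0, 0.0, 0.0, 0.0)] * nb, "boot", boot=True)

    start = day + pd.Timedelta(hours=lo) + pd.Timedelta(seconds=float(rng.uniform(0, 1800)))
    start = start.floor("s")
    times = start + pd.to_timedelta(np.arange(len(rows)) * interval, unit="s")
    df = pd.DataFrame(rows, columns=["x", "y", "speed", "course", "boot", "state"])
    df.insert(0, "t", times)
    df["set_only"] = set_only
    df["double_visit"] = double_visit
    return df


def _sample_sensor(trip_df: pd.DataFrame, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Hauler line (0 = active) at ping times, via pulse generation + hold.

    Raw rotation pulses fire every 15 s over each hauling bout (minus the
    trailing hold, so the conditioned line drops with the bout), with 15%
    random dropouts; the first and last pulses of a bout always fire. The
    1-minute hold bridges the dropouts, emulating the debouncing
    microcontroller.
    """
    t0 = trip_df["t"].iloc[0]
    rel = (trip_df["t"] - t0).dt.total_seconds().to_numpy()
    hauling = (trip_df["state"] == "hauling").to_numpy()
    sensor = np.ones(len(trip_df), dtype=int)
    if not hauling.any():
        return sensor
    edges = np.diff(np.concatenate(([0], hauling.astype(int), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1
    pulses: list[tuple[float, bool]] = []
    for s, e in zip(starts, ends):
        b0 = rel[s]
        b1 = rel[e] + config.ping_interval_s  # bout covers its pings' forward intervals
        grid = np.arange(b0, max(b0 + 15.0, b1 - config.hold_s) + 1e-9, 15.0)
        keep = rng.random(len(grid)) > 0.15
        keep[0] = keep[-1] = True
        pulses.extend((float(t), True) for t in grid[keep])
    intervals = hauler_hold_intervals(sorted(pulses), hold=config.hold_s)
    for lo_t, hi_t in intervals:
        sensor[(rel >= lo_t) & (rel < hi_t)] = 0
    return sensor


def simulate_dataset(config: SimConfig) -> tuple[PingStream, SimTruth]:
    """Simulate the full multi-day deployment.

    Emits a schema-complete :class:`PingStream` (monotone timestamps,
    progressive ids, tracker-style geofence ``eventType`` marks) and the
    matching :class:`SimTruth`. Same config and seed give bit-identical
    output. Inter-trip port stops follow the daily windows and therefore
    exceed any sensible segmentation ``min_gap`` by construction.
    """
    rng = np.random.default_rng(config.seed)
    polygon = config.port_polygon
    day0 = pd.Timestamp(config.start_date)

    trip_frames: list[pd.DataFrame] = []
    trip_id = 0
    for d in range(config.n_days):
        day = day0 + pd.Timedelta(days=d)
        for w in range(config.trips_per_day):
            trip_id += 1
            tdf = simulate_trip(config, day, config.trip_windows[w], rng)
            tdf["sensor"] = _sample_sensor(tdf, config, rng)
            tdf["trip_id"] = trip_id
            trip_frames.append(tdf)
    sim = pd.concat(trip_frames, ignore_index=True)

    lon, lat = _to_lonlat(
        sim["x"].to_numpy() + rng.normal(0.0, config.gps_noise_m, len(sim)),
        sim["y"].to_numpy() + rng.normal(0.0, config.gps_noise_m, len(sim)),
        config.port_anchor,
    )
    boot = sim["boot"].to_numpy()

    stream_df = pd.DataFrame({
        "id": np.arange(1, len(sim) + 1, dtype="int64"),
        "deviceId": np.full(len(sim), config.device_id, dtype="int64"),
        "latitude": lat,
        "longitude": lon,
        "deviceTime": sim["t"].to_numpy(),
        "course": sim["course"].to_numpy(),
        "speed": sim["speed"].to_numpy(),
        "sat": np.where(boot, 0, rng.integers(8, 15, len(sim))).astype("int64"),
        "power": np.where(boot, 0.0, np.round(rng.normal(12.6, 0.2, len(sim)), 2)),
        "eventType": "none",
        "sensor": sim["sensor"].astype("int64"),
    }, columns=list(COLUMNS))

    # truth activity: port containment takes precedence over movement state
    state = sim["state"].to_numpy(dtype=object).copy()
    normal = ~boot
    inside = np.zeros(len(sim), dtype=bool)
    inside[normal] = containment_mask(stream_df.loc[normal], polygon).to_numpy()
    state[normal & inside] = "in_port"

    # geofence crossings per trip over normal pings; tracker marks the
    # ping after each transition in eventType
    crossings = []
    for tid, grp in stream_df.groupby(sim["trip_id"].to_numpy()):
        idx = grp.index.to_numpy()[normal[grp.index]]
        ins = inside[idx]
        for k in range(1, len(idx)):
            if ins[k] != ins[k - 1]:
                kind = "geofenceExit" if ins[k - 1] else "geofenceEnter"
                stream_df.loc[idx[k], "eventType"] = kind
                crossings.append({
                    "trip_id": int(tid), "kind": kind,
                    "time": stream_df.loc[idx[k], "deviceTime"], "index": int(idx[k]),
                })

    # outlier injection on normal at-sea pings, logged exactly
    outlier_indices: dict[str, list[int]] = {"speed": [], "course": []}
    at_sea = np.flatnonzero(normal & ~inside)
    n_out = config.n_speed_outliers + config.n_course_outliers
    if n_out:
        chosen = rng.choice(at_sea, size=n_out, replace=False)
        sp, co = chosen[: config.n_speed_outliers], chosen[config.n_speed_outliers:]
        stream_df.loc[sp, "speed"] = np.round(rng.uniform(36.0, 90.0, len(sp)), 2)
        stream_df.loc[co, "course"] = np.round(
            np.where(rng.random(len(co)) < 0.5,
                     rng.uniform(360.5, 480.0, len(co)),
                     rng.uniform(-90.0, -0.5, len(co))), 2)
        outlier_indices["speed"] = sorted(int(i) for i in sp)
        outlier_indices["course"] = sorted(int(i) for i in co)

    per_ping = pd.DataFrame({
        "trip_id": np.where(boot, 0, sim["trip_id"].to_numpy()),
        "activity": state,
    })

    interval_min = config.ping_interval_s / 60.0
    schedule_rows = []
    for tid, grp in sim.groupby("trip_id"):
        norm = grp.loc[~grp["boot"]]
        true_haul = (per_ping.loc[norm.index, "activity"] == "hauling").sum()
        schedule_rows.append({
            "trip_id": int(tid),
            "start_time": norm["t"].iloc[0],
            "end_time": norm["t"].iloc[-1],
            "first_index": int(norm.index[0]),
            "last_index": int(norm.index[-1]),
            "set_only": bool(grp["set_only"].iloc[0]),
            "double_visit": bool(grp["double_visit"].iloc[0]),
            "hauling_minutes": float(true_haul * interval_min),
        })
    schedule = pd.DataFrame(schedule_rows)
    crossings_df = pd.DataFrame(crossings, columns=["trip_id", "kind", "time", "index"])

    stream = PingStream(device_id=config.device_id, data=stream_df)
    truth = SimTruth(
        per_ping=per_ping,
        schedule=schedule,
        crossings=crossings_df,
        outlier_indices=outlier_indices,
    )
    return stream, truth


def compress_port_stop(
    stream: PingStream, truth: SimTruth, after_trip: int, gap_minutes: float
) -> PingStream:
    """Shorten the port stop following ``after_trip`` to ``gap_minutes``.

    Shifts everything after the stop's midpoint earlier in time, so the
    off-time between the two surrounding trips becomes ``gap_minutes``
    while every other interval is untouched. Used to probe the
    segmentation minimum-stop rule (e.g. 30 min < 45 min merges two
    scheduled trips).
    """
    sched = truth.schedule.set_index("trip_id")
    t_end = sched.loc[after_trip, "end_time"]
    t_next = sched.loc[after_trip + 1, "start_time"]
    current_gap_s = (t_next - t_end).total_seconds()
    delta = current_gap_s - gap_minutes * 60.0
    if delta <= 0:
        return stream
    mid = t_end + pd.Timedelta(seconds=current_gap_s / 2)
    df = stream.data.copy()
    late = df["deviceTime"] > mid
    df.loc[late, "deviceTime"] = df.loc[late, "deviceTime"] - pd.Timedelta(seconds=delta)
    return PingStream(device_id=stream.device_id, data=df)


def perturbed_config(config: SimConfig, **changes) -> SimConfig:
    """Copy a config with field overrides (dataclasses.replace wrapper)."""
    return replace(config, **changes)
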