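"""Partition a ping stream into port-to-port trips.

A trip starts when the skipper powers the tracker on and leaves port, and
ends on return when the tracker powers off. Power-on and power-off both
show up in the stream as short runs of *boot pings* — records with zero
satellite count and zero supply power, emitted while the device
initializes or shuts down.

Segmentation relies only on these system parameters plus time, never on
port polygons: harbor geofences are hard to digitize at scale, and
vessels may depart from spots that are not registered ports. The rule is:

- boundaries are evaluated on the *off-time* between consecutive normal
  (non-boot) pings — from the last normal ping before a power-off to the
  first after the next power-on;
- a new trip starts when that off-time exceeds ``min_gap`` (default
  45 minutes; fishery-dependent), whether or not boot pings were seen in
  between. A short mid-sea reboot (off-time below ``min_gap``) therefore
  never splits a trip, and brief port stops are merged into one trip;
- segments with fewer than ``min_pings`` normal pings are discarded as
  harbor jitter and reported in the residual set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from haultrack.ping_model import PingStream

__all__ = ["BootEvent", "Trip", "TripSegmentation", "detect_boot_events", "segment_trips"]

DEFAULT_MIN_GAP_MIN = 45.0
DEFAULT_MIN_PINGS = 5


@dataclass(frozen=True)
class BootEvent:
    """A maximal run of boot pings (sat == 0 and power == 0)."""

    start_index: int  # positional, inclusive
    end_index: int    # positional, inclusive
    start_time: pd.Timestamp
    end_time: pd.Timestamp

    def __len__(self) -> int:
        return self.end_index - self.start_index + 1


@dataclass(frozen=True)
class Trip:
    """One port-to-port trip: a contiguous block of normal pings."""

    trip_id: int          # ordinal per device, chronological, 1-based
    device_id: int
    start_time: pd.Timestamp
    end_time: pd.Timestamp
    indices: tuple[int, ...]  # positions of the trip's normal pings in the stream

    @property
    def n_pings(self) -> int:
        return len(self.indices)


@dataclass
class TripSegmentation:
    """Result of :func:`segment_trips`.

    Iterates over its ``trips``; also exposes the ``residual`` positions
    (normal pings in discarded micro-segments) and the detected
    ``boot_events`` so that the partition accounts for every ping:
    ``sum(len(t.indices)) + len(residual) + boot ping count == len(stream)``.
    """

    trips: list[Trip]
    residual: tuple[int, ...] = ()
    boot_events: list[BootEvent] = field(default_factory=list)

    def __iter__(self) -> Iterator[Trip]:
        return iter(self.trips)

    def __len__(self) -> int:
        return len(self.trips)

    def __getitem__(self, i: int) -> Trip:
        return self.trips[i]

    def to_frame(self) -> pd.DataFrame:
        """Trips table: Trip, tripStart, tripEnd (ISO-8601), nPings."""
        return pd.DataFrame(
            {
                "Trip": [t.trip_id for t in self.trips],
                "tripStart": [t.start_time.strftime("%Y-%m-%d %H:%M:%S") for t in self.trips],
                "tripEnd": [t.end_time.strftime("%Y-%m-%d %H:%M:%S") for t in self.trips],
                "nPings": [t.n_pings for t in self.trips],
            }
        )

    def membership(self, n: int) -> np.ndarray:
        """Per-ping trip id over ``n`` stream positions; 0 = no trip."""
        out = np.zeros(n, dtype=int)
        for t in self.trips:
            out[list(t.indices)] = t.trip_id
        return out


def detect_boot_events(stream: PingStream) -> list[BootEvent]:
    """Maximal runs of boot pings, in stream order."""
    boot = stream.is_boot.to_numpy()
    if not boot.any():
        return []
    edges = np.diff(np.concatenate(([0], boot.astype(int), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1) - 1
    times = stream.times
    return [
        BootEvent(int(s), int(e), times.iloc[int(s)], times.iloc[int(e)])
        for s, e in zip(starts, ends)
    ]


def segment_trips(
    stream: PingStream,
    min_gap: float = DEFAULT_MIN_GAP_MIN,
    min_pings: int = DEFAULT_MIN_PINGS,
) -> TripSegmentation:
    """Split a stream into trips at off-times exceeding ``min_gap`` minutes.

    Boundaries are placed between consecutive *normal* pings whose time
    difference exceeds ``min_gap`` — this covers both a power-off/power-on
    cycle (boot runs in between) and a plain transmission silence. Trip
    start/end are the first/last normal-ping timestamps of each segment.
    Segments with fewer than ``min_pings`` normal pings go to the residual.
    """
    boots = detect_boot_events(stream)
    normal = np.flatnonzero(~stream.is_boot.to_numpy())
    if normal.size == 0:
        return TripSegmentation(trips=[], residual=(), boot_events=boots)

    times = stream.times.to_numpy()
    gaps_s = np.diff(times[normal]).astype("timedelta64[s]").astype(float)
    cut_after = np.flatnonzero(gaps_s > min_gap * 60.0)

    segments: list[np.ndarray] = np.split(normal, cut_after + 1)
    trips: list[Trip] = []
    residual: list[int] = []
    trip_id = 0
    for seg in segments:
        if len(seg) < min_pings:
            residual.extend(int(i) for i in seg)
            continue
        trip_id += 1
        trips.append(
            Trip(
                trip_id=trip_id,
                device_id=stream.device_id,
                start_time=stream.times.iloc[int(seg[0])],
                end_time=stream.times.iloc[int(seg[-1])],
                indices=tuple(int(i) for i in seg),
            )
        )
    return TripSegmentation(trips=trips, residual=tuple(residual), boot_events=boots)
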