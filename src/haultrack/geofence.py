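"""Port geofence: containment tests, crossing events, trip validation.

The home port is delimited by a polygon (the *geofence*). A normal trip
crosses it exactly twice — one ``geofenceExit`` on departure and one
``geofenceEnter`` on return — so the exit/enter counts validate the trips
produced by segmentation. Vessels working grounds on opposite sides of a
badly shaped polygon can cut through it mid-trip, generating extra
enter/exit pairs; such trips are reported as ``multi_crossing`` rather
than discarded, since they indicate the polygon (not the trip) needs
reshaping.

Crossings are evaluated per ping — a state change of containment between
consecutive fixes — matching how the tracker itself raises geofence
events. Containment is boundary-inclusive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd
import shapely
from shapely.geometry import Point, Polygon

from haultrack.ping_model import PingStream
from haultrack.trip_segmentation import Trip

__all__ = [
    "GeofencePolygon",
    "GeofenceEvent",
    "TripValidation",
    "point_in_polygon",
    "containment_mask",
    "derive_crossings",
    "validate_trip",
    "compare_event_sources",
]


@dataclass
class GeofencePolygon:
    """A named closed ring of (longitude, latitude) vertices.

    The ring must be explicitly closed (first vertex == last), have at
    least 4 vertices including the closure, and not self-intersect. Only
    the outer ring of a GeoJSON Polygon is used.
    """

    name: str
    ring: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        ring = tuple((float(x), float(y)) for x, y in self.ring)
        if len(ring) < 4:
            raise ValueError("polygon ring needs >= 4 vertices including closure")
        if ring[0] != ring[-1]:
            raise ValueError("polygon ring must be closed (first vertex == last)")
        poly = Polygon(ring)
        if not poly.is_valid:
            raise ValueError("polygon ring is invalid (self-intersecting?)")
        self.ring = ring
        self._poly = poly
        shapely.prepare(self._poly)

    @property
    def shapely(self) -> Polygon:
        return self._poly

    @classmethod
    def from_geojson(cls, path: str | Path, name: str | None = None) -> "GeofencePolygon":
        """Load the outer ring of a GeoJSON Polygon (bare geometry,
        Feature, or first feature of a FeatureCollection)."""
        doc = json.loads(Path(path).read_text())
        if doc.get("type") == "FeatureCollection":
            doc = doc["features"][0]
        props = doc.get("properties") or {}
        if doc.get("type") == "Feature":
            doc = doc["geometry"]
        if doc.get("type") != "Polygon":
            raise ValueError(f"expected a Polygon geometry, got {doc.get('type')!r}")
        ring = tuple((float(x), float(y)) for x, y in doc["coordinates"][0])
        return cls(name=name or props.get("name", "port"), ring=ring)

    def to_geojson(self, path: str | Path) -> None:
        doc = {
            "type": "Feature",
            "properties": {"name": self.name},
            "geometry": {"type": "Polygon", "coordinates": [[list(v) for v in self.ring]]},
        }
        Path(path).write_text(json.dumps(doc, indent=1))


@dataclass(frozen=True)
class GeofenceEvent:
    """A containment transition between two consecutive pings.

    ``index`` is the stream position of the first ping *after* the
    crossing; ``kind`` is ``geofenceExit`` for inside→outside and
    ``geofenceEnter`` for outside→inside.
    """

    kind: str
    time: pd.Timestamp
    index: int


@dataclass(frozen=True)
class TripValidation:
    status: str  # valid | multi_crossing | no_crossing
    n_enter: int
    n_exit: int


def point_in_polygon(lon: float, lat: float, polygon: GeofencePolygon) -> bool:
    """Boundary-inclusive containment of a (lon, lat) point."""
    return bool(polygon.shapely.covers(Point(lon, lat)))


def containment_mask(pings: pd.DataFrame, polygon: GeofencePolygon) -> pd.Series:
    """Vectorized boundary-inclusive containment for a ping table."""
    pts = shapely.points(pings["longitude"].to_numpy(), pings["latitude"].to_numpy())
    return pd.Series(shapely.covers(polygon.shapely, pts), index=pings.index)


def derive_crossings(
    trip: Trip, stream: PingStream, polygon: GeofencePolygon
) -> list[GeofenceEvent]:
    """Recompute geofence events of one trip from positions.

    One event per inside/outside transition between consecutive trip
    pings; kinds strictly alternate along the trip.
    """
    pings = stream.slice(trip.indices)
    inside = containment_mask(pings, polygon).to_numpy()
    events: list[GeofenceEvent] = []
    for k in range(1, len(inside)):
        if inside[k] != inside[k - 1]:
            kind = "geofenceExit" if inside[k - 1] else "geofenceEnter"
            events.append(
                GeofenceEvent(
                    kind=kind,
                    time=pings["deviceTime"].iloc[k],
                    index=int(trip.indices[k]),
                )
            )
    return events


def validate_trip(trip: Trip, events: Sequence[GeofenceEvent]) -> TripValidation:
    """Check a trip against the expected one-exit/one-enter pattern.

    ``valid`` iff exactly one exit and one enter; ``multi_crossing`` when
    either count reaches 2 (mid-trip pass through the polygon);
    ``no_crossing`` when there are no events at all. Raw counts are
    reported alongside, because unpaired crossings do occur (an event can
    be recorded while the device is off at the other end of the trip).
    """
    n_enter = sum(1 for e in events if e.kind == "geofenceEnter")
    n_exit = sum(1 for e in events if e.kind == "geofenceExit")
    if (n_enter, n_exit) == (1, 1):
        status = "valid"
    elif (n_enter, n_exit) == (0, 0):
        status = "no_crossing"
    else:  # >= 2 of either kind, or an unpaired single event
        status = "multi_crossing"
    return TripValidation(status=status, n_enter=n_enter, n_exit=n_exit)


def recorded_events(trip: Trip, stream: PingStream) -> list[GeofenceEvent]:
    """Geofence events as recorded by the tracker in the eventType field."""
    pings = stream.slice(trip.indices)
    events = []
    for pos, row in zip(trip.indices, pings.itertuples(index=False)):
        if row.eventType in ("geofenceEnter", "geofenceExit"):
            events.append(GeofenceEvent(kind=row.eventType, time=row.deviceTime, index=int(pos)))
    return events


def compare_event_sources(
    trip: Trip, stream: PingStream, polygon: GeofencePolygon
) -> dict:
    """Reconcile recorded eventType events with position-derived ones.

    Returns per-source (enter, exit) counts and whether they agree —
    useful for spotting geofence polygons that need reshaping.
    """
    rec = recorded_events(trip, stream)
    der = derive_crossings(trip, stream, polygon)
    counts = {
        "recorded": (
            sum(e.kind == "geofenceEnter" for e in rec),
            sum(e.kind == "geofenceExit" for e in rec),
        ),
        "derived": (
            sum(e.kind == "geofenceEnter" for e in der),
            sum(e.kind == "geofenceExit" for e in der),
        ),
    }
    counts["agree"] = counts["recorded"] == counts["derived"]
    return counts
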