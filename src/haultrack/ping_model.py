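"""Ping data model: schema, validation, readers/writers.

One *ping* is a single broadcast from the onboard tracker. The wire schema
has eleven fields::

    id, deviceId, latitude, longitude, deviceTime, course, speed,
    sat, power, eventType, sensor

``id`` is a progressive serial number, ``deviceId`` identifies the vessel
(playing the role an MMSI plays for AIS), ``speed`` is speed over ground in
km/h, ``course`` degrees over ground, ``sat`` the satellite count and
``power`` the supply level (both zero while the device boots or shuts
down), ``eventType`` a tracker-side geofence event (``none`` /
``geofenceEnter`` / ``geofenceExit``) and ``sensor`` the conditioned hauler
line: 0 while the hauler is active, 1 otherwise.

Timestamps are naive local wall-clock time exactly as transmitted; no
timezone conversion is applied anywhere in the package, because hour-of-day
effort profiles are meaningful in the vessel's local time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EVENT_TYPES",
    "COLUMNS",
    "PingRecord",
    "PingStream",
    "SchemaError",
    "RowError",
    "read_pings",
    "write_pings",
    "write_track_geojson",
    "read_track_geojson",
]

#: Canonical column order of the ping table.
COLUMNS = (
    "id",
    "deviceId",
    "latitude",
    "longitude",
    "deviceTime",
    "course",
    "speed",
    "sat",
    "power",
    "eventType",
    "sensor",
)

#: Valid geofence event markers on a ping.
EVENT_TYPES = ("none", "geofenceEnter", "geofenceExit")

#: Input-name aliases, lower-cased; the tracker emits ``type`` for the
#: geofence event field, which collides with too many things downstream.
_ALIASES = {
    "type": "eventType",
    "eventtype": "eventType",
    "lat": "latitude",
    "lon": "longitude",
    "lng": "longitude",
    "devicetime": "deviceTime",
    "deviceid": "deviceId",
}

_TIME_FORMAT = "%Y-%m-%d %H:%M:%S"


class SchemaError(ValueError):
    """The file/table does not match the ping schema (e.g. missing column)."""


class RowError(ValueError):
    """One or more rows are malformed; carries ``(line, message)`` pairs."""

    def __init__(self, problems: Sequence[tuple[int, str]]):
        self.problems = list(problems)
        shown = "; ".join(f"line {ln}: {msg}" for ln, msg in self.problems[:10])
        more = "" if len(self.problems) <= 10 else f" (+{len(self.problems) - 10} more)"
        super().__init__(f"{len(self.problems)} malformed row(s): {shown}{more}")


@dataclass(frozen=True)
class PingRecord:
    """A single tracker broadcast."""

    id: int
    deviceId: int
    latitude: float
    longitude: float
    deviceTime: pd.Timestamp
    course: float
    speed: float
    sat: int
    power: float
    eventType: str = "none"
    sensor: int = 1

    @property
    def hauler_active(self) -> bool:
        """True when the hauler line is asserted (``sensor == 0``)."""
        return self.sensor == 0

    @property
    def is_boot(self) -> bool:
        """True for boot/shutdown pings: no satellite fix and no power."""
        return self.sat == 0 and self.power == 0


@dataclass
class PingStream:
    """Time-ordered pings of a single device.

    Wraps a :class:`pandas.DataFrame` with the canonical columns, sorted
    stably by ``(deviceTime, id)`` so that records sharing a timestamp keep
    serial-number order.
    """

    device_id: int
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        df = self.data.loc[:, list(COLUMNS)].copy()
        if len(df) and df["deviceId"].nunique() > 1:
            raise SchemaError(
                f"stream must hold a single device, found ids {sorted(df['deviceId'].unique())}"
            )
        df = df.sort_values(["deviceTime", "id"], kind="mergesort").reset_index(drop=True)
        self.data = df

    @classmethod
    def from_records(cls, records: Sequence[PingRecord], device_id: int | None = None) -> "PingStream":
        if not records and device_id is None:
            raise ValueError("device_id required for an empty stream")
        df = pd.DataFrame([r.__dict__ for r in records], columns=list(COLUMNS))
        if not len(df):
            df = _empty_frame()
        dev = device_id if device_id is not None else int(df["deviceId"].iloc[0])
        return cls(device_id=dev, data=df)

    def __len__(self) -> int:
        return len(self.data)

    def __iter__(self) -> Iterator[PingRecord]:
        for row in self.data.itertuples(index=False):
            yield PingRecord(*row)

    def record(self, i: int) -> PingRecord:
        return PingRecord(*self.data.iloc[i])

    @property
    def times(self) -> pd.Series:
        return self.data["deviceTime"]

    @property
    def is_boot(self) -> pd.Series:
        """Boolean mask of boot/shutdown pings (sat == 0 and power == 0)."""
        return (self.data["sat"] == 0) & (self.data["power"] == 0)

    def slice(self, indices: Sequence[int]) -> pd.DataFrame:
        """Positional view of the ping table (e.g. one trip's pings)."""
        return self.data.iloc[list(indices)]


def _empty_frame() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        COLUMNS,
        ["int64", "int64", "float64", "float64", "datetime64[ns]",
         "float64", "float64", "int64", "float64", "object", "int64"],
    )})
    return df


def _canonical_columns(columns: Sequence[str]) -> dict[str, str]:
    """Map raw column names to canonical ones, case-insensitively."""
    mapping = {}
    for raw in columns:
        key = str(raw).strip().lower()
        if key in _ALIASES:
            mapping[raw] = _ALIASES[key]
        else:
            for canon in COLUMNS:
                if key == canon.lower():
                    mapping[raw] = canon
                    break
    return mapping


def _validate_rows(df: pd.DataFrame, offset: int) -> None:
    """Collect row-level problems; raise :class:`RowError` if any.

    ``offset`` converts a 0-based frame position into the 1-based line
    number of the source file (header line included for CSV).
    """
    problems: list[tuple[int, str]] = []

    def flag(mask: pd.Series, message: str) -> None:
        for pos in np.flatnonzero(mask.to_numpy()):
            problems.append((int(pos) + offset, message))

    flag(df["deviceTime"].isna(), "unparseable deviceTime")
    flag(~df["latitude"].between(-90, 90) | df["latitude"].isna(), "latitude outside [-90, 90]")
    flag(~df["longitude"].between(-180, 180) | df["longitude"].isna(), "longitude outside [-180, 180]")
    flag(~df["sensor"].isin([0, 1]), "sensor not in {0, 1}")
    flag(~df["eventType"].isin(EVENT_TYPES), f"eventType not in {EVENT_TYPES}")
    flag(df["speed"] < 0, "negative speed")
    flag(df["sat"] < 0, "negative sat")
    flag(df["power"] < 0, "negative power")
    if problems:
        raise RowError(sorted(problems))


def read_pings(path: str | Path, format: str | None = None) -> PingStream:
    """Read a ping file (CSV or JSON-lines) into a sorted :class:`PingStream`.

    Column matching is case-insensitive and accepts the tracker's ``type``
    name for the geofence event field. Records come back sorted by
    ``(deviceTime, id)``.

    Raises
    ------
    SchemaError
        A mandatory column is missing (named in the message), or the file
        mixes devices.
    RowError
        Malformed rows (bad timestamp, out-of-range coordinate, invalid
        sensor/eventType); every offending line number is reported, nothing
        is silently dropped.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "jsonl" if path.suffix.lower() in {".jsonl", ".ndjson", ".json"} else "csv"
    if format == "csv":
        raw = pd.read_csv(path, dtype={"deviceTime": str})
        offset = 2  # line 1 is the header
    elif format == "jsonl":
        raw = pd.read_json(path, lines=True, dtype={"deviceTime": str}, convert_dates=False)
        if raw.empty and not raw.columns.tolist():
            raw = _empty_frame().astype({"deviceTime": str})
        offset = 1
    else:
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'jsonl'")

    raw = raw.rename(columns=_canonical_columns(raw.columns))
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    raw = raw.loc[:, list(COLUMNS)]

    df = raw.copy()
    df["deviceTime"] = pd.to_datetime(raw["deviceTime"], format="mixed", errors="coerce")
    df["eventType"] = raw["eventType"].fillna("none").replace({"": "none"})
    for col in ("latitude", "longitude", "course", "speed", "power"):
        df[col] = pd.to_numeric(raw[col], errors="coerce")
    for col in ("id", "deviceId", "sat", "sensor"):
        df[col] = pd.to_numeric(raw[col], errors="coerce").astype("Int64")

    if len(df):
        flagged = df[["id", "deviceId", "sat", "sensor"]].isna().any(axis=1)
        if flagged.any():
            raise RowError(
                [(int(i) + offset, "non-integer id/deviceId/sat/sensor")
                 for i in np.flatnonzero(flagged.to_numpy())]
            )
        _validate_rows(df, offset)
        for col in ("id", "deviceId", "sat", "sensor"):
            df[col] = df[col].astype("int64")
        device_id = int(df["deviceId"].iloc[0])
    else:
        df = _empty_frame()
        device_id = 0
    return PingStream(device_id=device_id, data=df)


def write_pings(stream: PingStream, path: str | Path, format: str | None = None) -> None:
    """Write a stream back to CSV or JSON-lines with canonical column names.

    Round-trip safe: reading the written file reproduces every field,
    timestamps at second resolution.
    """
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix.lower() in {".jsonl", ".ndjson", ".json"} else "csv"
    out = stream.data.copy()
    out["deviceTime"] = out["deviceTime"].dt.strftime(_TIME_FORMAT)
    if format == "csv":
        out.to_csv(path, index=False)
    elif format == "jsonl":
        out.to_json(path, orient="records", lines=True)
    else:
        raise ValueError(f"unknown format {format!r}")


def write_track_geojson(stream: PingStream, path: str | Path) -> None:
    """Export the track as an RFC 7946 FeatureCollection of Point features.

    Coordinates are ``[longitude, latitude]`` (GeoJSON order); each feature
    carries ``deviceTime``, ``speed`` and ``sensor`` properties.
    """
    features = []
    for row in stream.data.itertuples(index=False):
        features.append({
            "type": "Feature",
            "geometry": {
                "type": "Point",
                "coordinates": [row.longitude, row.latitude],
            },
            "properties": {
                "deviceTime": row.deviceTime.strftime(_TIME_FORMAT),
                "speed": row.speed,
                "sensor": int(row.sensor),
            },
        })
    collection = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(collection, indent=1))


def read_track_geojson(path: str | Path) -> dict:
    """Read back a GeoJSON document written by :func:`write_track_geojson`."""
    return json.loads(Path(path).read_text())
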