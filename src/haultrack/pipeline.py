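"""End-to-end analysis pipeline: QC → trips → activity → summaries.

All randomness in the package lives in the simulator behind an explicit
seed; the analysis pipeline is fully deterministic, so the same input and
configuration always produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from haultrack import __version__
from haultrack.effort_metrics import (
    activity_by_hour,
    speed_by_state,
    summaries_frame,
    trip_summary,
)
from haultrack.fishing_activity import classify_activity, speed_threshold
from haultrack.geofence import (
    GeofencePolygon,
    containment_mask,
    derive_crossings,
    recorded_events,
    validate_trip,
)
from haultrack.ping_model import PingStream, read_pings
from haultrack.quality_control import apply_outlier_policy, ping_rate_report
from haultrack.trip_segmentation import segment_trips

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("haultrack")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, with the deployment defaults.

    ``min_gap`` (minutes) is the minimum port stop that separates trips;
    ``max_speed`` (km/h) and ``course_range`` (degrees) bound plausible
    kinematics; ``quantile`` sets the steaming speed cut on at-sea
    speeds; ``hold`` (seconds) is the hauler-line minimum hold (hardware
    emulation, used when conditioning raw sensor signals);
    ``nominal_interval`` (seconds) is the expected ping rate.
    """

    input_path: str
    out_dir: str
    format: str | None = None          # csv | jsonl | None -> by extension
    geofence_path: str | None = None
    min_gap: float = 45.0
    min_pings: int = 5
    max_speed: float = 35.0
    course_range: tuple[float, float] = (0.0, 360.0)
    quantile: float = 0.75
    hold: float = 60.0
    nominal_interval: float = 60.0
    gap_factor: float = 3.0
    outlier_policy: str = "drop"       # drop | keep

    def __post_init__(self) -> None:
        if not 0 < self.quantile < 1:
            raise ValueError("quantile must be in (0, 1)")
        for name in ("min_gap", "max_speed", "hold", "nominal_interval", "gap_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_hauling_geojson(rows: pd.DataFrame, path: Path) -> None:
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [r.longitude, r.latitude]},
            "properties": {
                "trip": int(r.trip),
                "deviceTime": r.deviceTime.strftime("%Y-%m-%d %H:%M:%S"),
                "speed": r.speed,
            },
        }
        for r in rows.itertuples(index=False)
    ]
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}, indent=1))


def run_pipeline(config: PipelineConfig, stream: PingStream | None = None) -> dict[str, Path]:
    """Run every stage and write the artifact bundle to ``out_dir``.

    Outputs: ``qc_report.json``, ``trips.csv``, ``pings_labeled.csv``,
    ``hauling_points.geojson``, ``activity_by_hour.csv``,
    ``speed_by_state.csv`` and a ``provenance.json`` recording the config
    and input checksums. Returns the mapping of artifact names to paths.
    On failure, partial outputs of this run are removed and a
    :class:`PipelineError` naming the stage is raised.

    ``stream`` may be supplied directly (e.g. fresh from the simulator)
    to skip the read stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    def emit(name: str, filename: str) -> Path:
        p = out_dir / filename
        written[name] = p
        return p

    stage = "read"
    try:
        if stream is None:
            stream = read_pings(config.input_path, config.format)
        if len(stream) == 0:
            log.warning("input %s contains no pings; writing empty outputs", config.input_path)

        polygon = None
        if config.geofence_path:
            polygon = GeofencePolygon.from_geojson(config.geofence_path)

        stage = "quality_control"
        qc = ping_rate_report(
            stream, config.nominal_interval, config.gap_factor,
            config.max_speed, config.course_range,
        )
        emit("qc_report", "qc_report.json").write_text(json.dumps(qc.to_dict(), indent=1))
        clean = apply_outlier_policy(
            stream, config.outlier_policy,
            max_speed=config.max_speed, course_range=config.course_range,
        )

        stage = "trip_segmentation"
        segmentation = segment_trips(clean, config.min_gap, config.min_pings)
        log.info("thresholds: min_gap=%s min, min_pings=%s, max_speed=%s km/h, "
                 "course_range=%s, quantile=%s, hold=%s s",
                 config.min_gap, config.min_pings, config.max_speed,
                 config.course_range, config.quantile, config.hold)

        stage = "fishing_activity"
        trip_ids = segmentation.membership(len(clean))
        in_trip = trip_ids > 0
        trip_pings = clean.data.loc[in_trip]
        if polygon is not None and len(trip_pings):
            at_sea = ~containment_mask(trip_pings, polygon)
        else:
            at_sea = pd.Series(True, index=trip_pings.index)
        at_sea_speeds = trip_pings.loc[at_sea, "speed"]
        threshold = speed_threshold(at_sea_speeds, config.quantile) if len(at_sea_speeds) else float("nan")

        labels_all = pd.Series(pd.array(["other"] * len(clean), dtype="object"))
        summaries = []
        hourly = np.zeros(24)
        for trip in segmentation:
            pings = clean.slice(trip.indices)
            labels = classify_activity(pings, threshold, polygon)
            labels_all.iloc[list(trip.indices)] = labels.astype(str).to_numpy()
            if polygon is not None:
                events = derive_crossings(trip, clean, polygon)
            else:
                events = recorded_events(trip, clean)
            validation = validate_trip(trip, events)
            summaries.append(trip_summary(trip, pings, labels, validation))
            hourly += activity_by_hour(labels, pings)

        stage = "effort_metrics"
        trips_df = summaries_frame(summaries)
        trips_df.to_csv(emit("trips", "trips.csv"), index=False)

        labeled = clean.data.copy()
        labeled["trip"] = trip_ids
        labeled["activity"] = labels_all.where(pd.Series(in_trip), "")
        labeled["deviceTime"] = labeled["deviceTime"].dt.strftime("%Y-%m-%d %H:%M:%S")
        labeled.to_csv(emit("pings_labeled", "pings_labeled.csv"), index=False)

        hauling = labeled.loc[labeled["activity"] == "hauling",
                              ["trip", "latitude", "longitude", "speed"]].copy()
        hauling["deviceTime"] = clean.data.loc[hauling.index, "deviceTime"]
        _write_hauling_geojson(hauling, emit("hauling_points", "hauling_points.geojson"))

        pd.DataFrame({"hour": np.arange(24), "hauling_minutes": np.round(hourly, 3)}).to_csv(
            emit("activity_by_hour", "activity_by_hour.csv"), index=False)

        if len(trip_pings):
            sbs = speed_by_state(
                labels_all[in_trip].astype(str), trip_pings)
        else:
            sbs = pd.DataFrame(columns=["state", "n", "median", "q1", "q3"])
        sbs.to_csv(emit("speed_by_state", "speed_by_state.csv"), index=False)

        stage = "provenance"
        prov = {
            "haultrack_version": __version__,
            "config": {k: v for k, v in dataclasses.asdict(config).items()},
            "inputs": {},
        }
        for p in filter(None, [config.input_path, config.geofence_path]):
            p = Path(p)
            if p.exists():
                prov["inputs"][str(p)] = _sha256(p)
        emit("provenance", "provenance.json").write_text(json.dumps(prov, indent=1, default=str))
    except Exception as exc:
        for p in written.values():
            p.unlink(missing_ok=True)
        raise PipelineError(stage, exc) from exc
    return written
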