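"""Reliability checks on a ping stream: outliers, ping-rate stability, gaps.

The tracker's kinematic fields occasionally glitch during acquisition or
transmission. Two plausibility rules catch them: speed over ground above
35 km/h (far beyond what a <12 m vessel does) and course outside the
[0, 360] degree range. Flagged pings are *annotated*, never removed here —
downstream stages decide the keep/drop policy.

Boot/shutdown pings (zero satellites and zero power) carry no valid fix,
so they are exempt from the kinematic rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from haultrack.ping_model import PingStream

__all__ = ["QcReport", "flag_outliers", "ping_rate_report", "apply_outlier_policy"]

DEFAULT_MAX_SPEED_KMH = 35.0
DEFAULT_COURSE_RANGE = (0.0, 360.0)


@dataclass
class QcReport:
    """Summary of stream reliability.

    Intervals are between consecutive pings; a *gap* is an interval longer
    than ``gap_factor`` times the nominal ping interval.
    """

    n_records: int
    n_speed_outliers: int
    n_course_outliers: int
    interval_median: float  # seconds; NaN when < 2 records
    interval_iqr: float     # seconds; NaN when < 2 records
    gaps: list[tuple[pd.Timestamp, pd.Timestamp, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_records": self.n_records,
            "n_speed_outliers": self.n_speed_outliers,
            "n_course_outliers": self.n_course_outliers,
            "interval_median_s": None if np.isnan(self.interval_median) else self.interval_median,
            "interval_iqr_s": None if np.isnan(self.interval_iqr) else self.interval_iqr,
            "gaps": [
                {"start": str(a), "end": str(b), "duration_s": d} for a, b, d in self.gaps
            ],
        }


def flag_outliers(
    stream: PingStream,
    max_speed: float = DEFAULT_MAX_SPEED_KMH,
    course_range: tuple[float, float] = DEFAULT_COURSE_RANGE,
) -> pd.DataFrame:
    """Per-record outlier flags.

    Returns a frame aligned to the stream with boolean columns
    ``speed_outlier`` (speed > ``max_speed``), ``course_outlier`` (course
    outside ``course_range``, bounds inclusive) and their union ``outlier``.
    Boot pings are exempt. Pure and order-independent per record.
    """
    df = stream.data
    boot = stream.is_boot.to_numpy()
    lo, hi = course_range
    speed_bad = (df["speed"].to_numpy() > max_speed) & ~boot
    course = df["course"].to_numpy()
    course_bad = ((course < lo) | (course > hi)) & ~boot
    return pd.DataFrame(
        {
            "speed_outlier": speed_bad,
            "course_outlier": course_bad,
            "outlier": speed_bad | course_bad,
        },
        index=df.index,
    )


def ping_rate_report(
    stream: PingStream,
    nominal_interval: float = 60.0,
    gap_factor: float = 3.0,
    max_speed: float = DEFAULT_MAX_SPEED_KMH,
    course_range: tuple[float, float] = DEFAULT_COURSE_RANGE,
) -> QcReport:
    """Ping-rate stability report: interval median/IQR, transmission gaps.

    A gap is any inter-ping interval exceeding ``gap_factor *
    nominal_interval`` seconds. With fewer than two records the interval
    statistics are NaN and no gaps are reported.
    """
    flags = flag_outliers(stream, max_speed, course_range)
    times = stream.times
    if len(stream) < 2:
        return QcReport(
            n_records=len(stream),
            n_speed_outliers=int(flags["speed_outlier"].sum()),
            n_course_outliers=int(flags["course_outlier"].sum()),
            interval_median=float("nan"),
            interval_iqr=float("nan"),
        )
    intervals = times.diff().dt.total_seconds().to_numpy()[1:]
    q1, med, q3 = np.quantile(intervals, [0.25, 0.5, 0.75])
    threshold = gap_factor * nominal_interval
    gaps = [
        (times.iloc[i], times.iloc[i + 1], float(intervals[i]))
        for i in np.flatnonzero(intervals > threshold)
    ]
    return QcReport(
        n_records=len(stream),
        n_speed_outliers=int(flags["speed_outlier"].sum()),
        n_course_outliers=int(flags["course_outlier"].sum()),
        interval_median=float(med),
        interval_iqr=float(q3 - q1),
        gaps=gaps,
    )


def apply_outlier_policy(stream: PingStream, policy: str = "drop", **kwargs) -> PingStream:
    """Apply the keep/drop policy for flagged pings.

    ``policy='drop'`` removes flagged records (the default downstream);
    ``policy='keep'`` returns the stream untouched.
    """
    if policy == "keep":
        return stream
    if policy != "drop":
        raise ValueError(f"unknown outlier policy {policy!r}; expected 'keep' or 'drop'")
    flags = flag_outliers(stream, **kwargs)
    kept = stream.data.loc[~flags["outlier"].to_numpy()].reset_index(drop=True)
    return PingStream(device_id=stream.device_id, data=kept)
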