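"""Hauler-signal conditioning and per-ping activity classification.

The hauler — the winch that retrieves passive gear — carries an inductive
proximity sensor whose rotation pulses are debounced by a small
microcontroller: once rotation is detected the output line is held high
for at least one minute, so the state survives the ~1-minute reporting
interval. :func:`condition_hauler_signal` emulates exactly that line.

A ping with the hauler line asserted is not automatically fishing: the
sensor can bounce while steaming, and pings inside the port are moorings,
not hauls. Classification therefore applies, in order of precedence:

    in_port  — position inside the port polygon (when one is supplied)
    steaming — speed above the steaming threshold (the 75th quantile of
               at-sea speeds; gear retrieval rarely exceeds 2 km/h)
    hauling  — hauler line asserted (sensor == 0)
    other    — everything else (gear setting, drifting, slow transit)

The package claims no gear-setting detector; ``other`` deliberately lumps
setting with slow non-hauling movement.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from haultrack.geofence import GeofencePolygon, containment_mask

__all__ = [
    "LABELS",
    "condition_hauler_signal",
    "hauler_hold_intervals",
    "speed_threshold",
    "classify_activity",
    "hauling_duration",
]

LABELS = ("in_port", "steaming", "hauling", "other")

DEFAULT_HOLD_S = 60.0
DEFAULT_QUANTILE = 0.75


def hauler_hold_intervals(
    raw: Sequence[tuple[float, bool]], hold: float = DEFAULT_HOLD_S
) -> list[tuple[float, float]]:
    """Merged active intervals implied by rotation pulses.

    Each detected rotation at time *t* keeps the line high over
    ``[t, t + hold)``; overlapping or touching holds merge. Times are
    seconds (any monotone scale).
    """
    pulses = [float(t) for t, rot in raw if rot]
    intervals: list[tuple[float, float]] = []
    for t in pulses:
        lo, hi = t, t + hold
        if intervals and lo <= intervals[-1][1]:
            intervals[-1] = (intervals[-1][0], max(intervals[-1][1], hi))
        else:
            intervals.append((lo, hi))
    return intervals


def condition_hauler_signal(
    raw: Sequence[tuple[float, bool]], hold: float = DEFAULT_HOLD_S
) -> list[tuple[float, bool]]:
    """Debounce a raw rotation-detection signal with a minimum hold.

    ``raw`` is a strictly time-increasing sequence of ``(time_s,
    rotation_detected)`` samples. The output, on the same time base, is
    active at a sample iff some detected rotation at ``t0 <= t`` satisfies
    ``t - t0 < hold`` — i.e. the line is kept high for ``hold`` seconds
    after every pulse, with overlapping holds merged.
    """
    times = [float(t) for t, _ in raw]
    if any(b <= a for a, b in zip(times, times[1:])):
        raise ValueError("sample times must be strictly increasing")
    intervals = hauler_hold_intervals(raw, hold)
    out: list[tuple[float, bool]] = []
    k = 0
    for t in times:
        while k < len(intervals) and intervals[k][1] <= t:
            k += 1
        active = k < len(intervals) and intervals[k][0] <= t < intervals[k][1]
        out.append((t, active))
    return out


def speed_threshold(speeds: Sequence[float], q: float = DEFAULT_QUANTILE) -> float:
    """Steaming speed threshold: the q-th quantile of at-sea speeds.

    Linear interpolation between order statistics; e.g. the 0.75 quantile
    of {1, 2, 3, 4} is 3.25. Raises on empty input.
    """
    arr = np.asarray(list(speeds), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot compute a speed threshold from an empty sequence")
    return float(np.quantile(arr, q))


def classify_activity(
    pings: pd.DataFrame,
    threshold: float,
    polygon: GeofencePolygon | None = None,
) -> pd.Series:
    """Label each ping in_port / steaming / hauling / other.

    ``pings`` is a ping-table slice (one trip, or a whole at-sea stream);
    ``threshold`` the steaming speed cut in km/h. Precedence:
    in_port > steaming > hauling > other.
    """
    n = len(pings)
    labels = np.full(n, "other", dtype=object)
    speed = pings["speed"].to_numpy()
    sensor = pings["sensor"].to_numpy()
    labels[(speed <= threshold) & (sensor == 0)] = "hauling"
    labels[speed > threshold] = "steaming"
    if polygon is not None:
        labels[containment_mask(pings, polygon).to_numpy()] = "in_port"
    return pd.Series(pd.Categorical(labels, categories=list(LABELS)), index=pings.index)


def hauling_duration(labels: pd.Series, pings: pd.DataFrame) -> float:
    """Hauling hours of a labeled ping slice.

    Each hauling ping is credited with the forward interval to the next
    ping; the last ping of the slice, having no successor, contributes
    nothing. There is an inherent offset between the hauler's true rotary
    motion and the transmitted line state; no correction is attempted.
    """
    if len(pings) != len(labels):
        raise ValueError("labels must align with pings")
    if len(pings) < 2:
        return 0.0
    fwd = pings["deviceTime"].diff().dt.total_seconds().to_numpy()[1:]
    hauling = (labels.to_numpy() == "hauling")[:-1]
    return float(fwd[hauling].sum() / 3600.0)
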