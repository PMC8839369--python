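"""Bundled reference data.

A one-month trip log recorded by a hauler-sensor tracking deployment on a
10 m passive-gear vessel operating out of Ancona (Adriatic Sea) in
November 2021: 28 port-to-port trips with their published per-trip
statistics. Used as the reference point for validating the duration and
summary computations, and as a realistic behaviour template (two trips
per day, early-morning and evening windows) for the simulator defaults.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_trip_log", "REFERENCE_PORT_LONLAT"]

#: Approximate home-port anchor of the reference deployment (lon, lat).
REFERENCE_PORT_LONLAT = (13.5030, 43.6190)

# Trip, tripStart, tripEnd, Duration (h), SA (kmh), Distance (km),
# Hauler (h), Entry, Exit — as published for November 2021.
_ROWS = [
    (1, "2021-11-01 01:40:10", "2021-11-01 06:50:47", 5.18, 4.27, 47.27, 3.03, 2, 2),
    (2, "2021-11-03 07:48:34", "2021-11-03 11:50:37", 4.03, 4.28, 34.49, 1.97, 2, 1),
    (3, "2021-11-03 15:58:46", "2021-11-03 16:37:23", 0.64, 7.46, 9.44, 0.00, 1, 1),
    (4, "2021-11-04 02:46:35", "2021-11-04 04:02:32", 1.27, 3.50, 9.59, 0.73, 1, 1),
    (5, "2021-11-04 15:37:07", "2021-11-04 19:07:55", 3.51, 4.44, 31.54, 1.87, 1, 1),
    (6, "2021-11-05 02:11:56", "2021-11-05 05:01:01", 2.82, 5.64, 31.84, 1.32, 1, 1),
    (7, "2021-11-07 15:07:38", "2021-11-07 16:34:34", 1.45, 8.46, 22.51, 0.02, 1, 1),
    (8, "2021-11-08 02:43:32", "2021-11-08 05:18:12", 2.58, 3.96, 21.69, 1.67, 1, 1),
    (9, "2021-11-08 06:24:19", "2021-11-08 10:19:29", 3.92, 4.94, 39.91, 2.13, 1, 1),
    (10, "2021-11-10 14:18:54", "2021-11-10 18:32:35", 4.23, 6.49, 53.53, 1.55, 2, 2),
    (11, "2021-11-11 01:39:33", "2021-11-11 05:33:34", 3.90, 5.12, 40.88, 2.07, 1, 1),
    (12, "2021-11-11 15:23:24", "2021-11-11 18:33:41", 3.17, 6.76, 40.96, 1.15, 2, 2),
    (13, "2021-11-12 01:43:35", "2021-11-12 05:39:19", 3.93, 4.46, 37.66, 1.35, 1, 1),
    (14, "2021-11-12 07:06:50", "2021-11-12 08:41:23", 1.58, 4.87, 16.63, 0.02, 1, 1),
    (15, "2021-11-13 01:41:42", "2021-11-13 06:07:41", 4.43, 4.80, 45.11, 0.00, 1, 1),
    (16, "2021-11-14 14:59:38", "2021-11-14 15:56:21", 0.95, 6.53, 11.92, 0.02, 1, 1),
    (17, "2021-11-15 02:41:28", "2021-11-15 06:00:27", 3.32, 4.00, 27.20, 1.85, 2, 2),
    (18, "2021-11-19 06:54:01", "2021-11-19 08:45:59", 1.87, 5.11, 18.15, 0.62, 1, 1),
    (19, "2021-11-20 01:58:53", "2021-11-20 05:37:43", 3.65, 3.92, 31.12, 2.07, 1, 1),
    (20, "2021-11-20 06:38:39", "2021-11-20 09:18:39", 2.67, 6.46, 33.53, 1.10, 1, 1),
    (21, "2021-11-21 14:02:21", "2021-11-21 17:01:05", 2.98, 4.40, 26.54, 1.35, 1, 1),
    (22, "2021-11-22 01:45:45", "2021-11-22 08:09:12", 6.39, 3.43, 46.42, 4.12, 1, 1),
    (23, "2021-11-24 14:07:27", "2021-11-24 15:33:19", 1.43, 7.86, 21.59, 0.02, 1, 1),
    (24, "2021-11-25 01:39:22", "2021-11-25 06:13:22", 4.57, 3.93, 38.50, 2.48, 1, 1),
    (25, "2021-11-25 07:28:34", "2021-11-25 09:13:33", 1.75, 5.86, 21.09, 0.82, 1, 1),
    (26, "2021-11-25 16:04:59", "2021-11-25 20:44:41", 4.66, 4.37, 38.46, 2.37, 1, 1),
    (27, "2021-11-26 14:06:30", "2021-11-26 18:42:23", 4.60, 4.19, 38.28, 2.42, 1, 1),
    (28, "2021-11-29 05:13:32", "2021-11-29 09:47:31", 4.57, 3.89, 37.49, 2.30, 1, 1),
]


def reference_trip_log() -> pd.DataFrame:
    """The November 2021 reference trip log as a DataFrame.

    Columns: Trip, tripStart, tripEnd (datetime64), Duration (h),
    SA (kmh), Distance (km), Hauler (h), Entry, Exit.
    """
    df = pd.DataFrame(
        _ROWS,
        columns=[
            "Trip", "tripStart", "tripEnd", "Duration (h)", "SA (kmh)",
            "Distance (km)", "Hauler (h)", "Entry", "Exit",
        ],
    )
    df["tripStart"] = pd.to_datetime(df["tripStart"])
    df["tripEnd"] = pd.to_datetime(df["tripEnd"])
    return df
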