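import numpy as np
import pandas as pd
import pytest

from haultrack.ping_model import COLUMNS, PingStream
from haultrack.synthetic_fleet import SimConfig, simulate_dataset


def make_stream(
    times,
    *,
    lat=43.70,
    lon=13.60,
    speed=6.0,
    course=90.0,
    sat=10,
    power=12.6,
    sensor=1,
    event="none",
    device_id=1,
    latitudes=None,
    longitudes=None,
    speeds=None,
    courses=None,
    sats=None,
    powers=None,
    sensors=None,
) -> PingStream:
    """Hand-build a ping stream from timestamps plus scalar or per-ping fields."""
    times = pd.to_datetime(list(times))
    n = len(times)

    def col(per_ping, scalar):
        return list(per_ping) if per_ping is not None else [scalar] * n

    df = pd.DataFrame(
        {
            "id": np.arange(1, n + 1),
            "deviceId": device_id,
            "latitude": col(latitudes, lat),
            "longitude": col(longitudes, lon),
            "deviceTime": times,
            "course": col(courses, course),
            "speed": col(speeds, speed),
            "sat": col(sats, sat),
            "power": col(powers, power),
            "eventType": event,
            "sensor": col(sensors, sensor),
        },
        columns=list(COLUMNS),
    )
    return PingStream(device_id=device_id, data=df)


def minute_times(start, n, step_s=60):
    start = pd.Timestamp(start)
    return [start + pd.Timedelta(seconds=i * step_s) for i in range(n)]


@pytest.fixture(scope="session")
def sim_month():
    """A simulated month: 14 days x 2 trips/day = 28 scheduled trips."""
    config = SimConfig(seed=11)
    stream, truth = simulate_dataset(config)
    return config, stream, truth


@pytest.fixture(scope="session")
def sim_with_outliers():
    config = SimConfig(seed=5, n_days=4, n_speed_outliers=4, n_course_outliers=3)
    stream, truth = simulate_dataset(config)
    return config, stream, truth
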