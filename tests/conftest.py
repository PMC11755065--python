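import numpy as np
import pytest

from pairforage.hmm import StepSeries
from pairforage.synth import SimConfig


@pytest.fixture
def tiny_config():
    """Two pairs, one season, short cheap deployments."""
    return SimConfig(
        n_pairs_per_year={"2022": 2},
        deployment_hours=12.0,
        depth_rate_hz=1.0,
        seed=42,
    )


def make_series(lon, lat, colony_lonlat=(0.0, 0.0), dive=None, intensity=None,
                interval_s=300.0, bird_id="T"):
    """Build a StepSeries directly from grid positions (helper, not a fixture)."""
    from pairforage.geo import haversine_km

    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    n = len(lon)
    step = np.zeros(n)
    if n > 1:
        step[1:] = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    times = np.datetime64("2022-07-25T00:00:00", "ms") + (np.arange(n) * int(interval_s * 1000)).astype(
        "timedelta64[ms]"
    )
    return StepSeries(
        bird_id=bird_id,
        times=times,
        lon=lon,
        lat=lat,
        step_km=step,
        colony_dist_km=np.asarray(haversine_km(colony_lonlat[0], colony_lonlat[1], lon, lat)),
        dive=np.zeros(n, dtype=bool) if dive is None else np.asarray(dive, dtype=bool),
        flight_intensity=np.zeros(n) if intensity is None else np.asarray(intensity, dtype=float),
        interpolated=np.zeros(n, dtype=bool),
        interval_s=interval_s,
        colony_lonlat=tuple(colony_lonlat),
    )
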