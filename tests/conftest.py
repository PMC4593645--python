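import numpy as np
import pandas as pd
import pytest

from foragescape.geo import EARTH_RADIUS_KM
from foragescape.tracks import Trip

KM_PER_DEG = EARTH_RADIUS_KM * np.pi / 180  # 1 degree of equatorial arc


def straight_trip(speed_kmh=10.0, length_km=200.0, fix_km=1.0,
                  colony=(0.0, 0.0)):
    """Due-east constant-speed trip along the equator, flight-labelled."""
    n = int(length_km / fix_km) + 1
    hours = fix_km / speed_kmh
    t = pd.date_range("2014-06-01", periods=n, tz="UTC",
                      freq=pd.Timedelta(hours=hours))
    fixes = pd.DataFrame({
        "timestamp": t,
        "lon": np.arange(n) * fix_km / KM_PER_DEG,
        "lat": np.zeros(n),
        "speed_kmh": speed_kmh,
        "behaviour": "flight",
    })
    return Trip(individual_id="s", trip_id="s_t01", colony=colony, fixes=fixes)


def trip_from_xy(xy_km, times_h, colony=(0.0, 0.0), behaviour="flight"):
    """Trip built from km offsets in an equatorial tangent plane."""
    from foragescape.geo import AzimuthalEquidistant
    proj = AzimuthalEquidistant(*colony)
    xy = np.asarray(xy_km, dtype=float)
    lon, lat = proj.inverse(xy[:, 0], xy[:, 1])
    t0 = pd.Timestamp("2014-06-01", tz="UTC")
    fixes = pd.DataFrame({
        "timestamp": [t0 + pd.Timedelta(hours=h) for h in times_h],
        "lon": lon, "lat": lat,
        "behaviour": behaviour,
    })
    return Trip(individual_id="x", trip_id="x_t01", colony=colony, fixes=fixes)


@pytest.fixture
def rng():
    return np.random.default_rng(20140601)
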