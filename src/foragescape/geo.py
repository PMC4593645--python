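"""Spherical geometry helpers shared across the package.

All geodesic arithmetic uses a sphere of radius 6371.0088 km (IUGG mean
Earth radius).  At the spatial scales of central-place foraging trips
(tens to hundreds of km) the sphere-vs-ellipsoid error is well below
0.5%, which is far inside every tolerance used downstream, and it frees
the package from a projection-library dependency.

Two projections are provided:

* :class:`AzimuthalEquidistant` — distances from the projection centre
  are exact; used wherever estimation must happen in metric (km) space
  (path interpolation, FPT circles, kernel density bandwidths).
* :func:`to_equal_area` — Lambert cylindrical equal-area; areas on the
  sphere are preserved exactly, used for all polygon-area bookkeeping.
"""

from __future__ import annotations

import numpy as np
from shapely.ops import transform as _shapely_transform

EARTH_RADIUS_KM = 6371.0088


def great_circle_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Haversine formula on the package sphere; accepts scalars or
    broadcastable arrays.  Symmetric, non-negative, zero iff the points
    coincide.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    # clip guards rounding for antipodal-ish inputs
    arc = 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return EARTH_RADIUS_KM * arc


class AzimuthalEquidistant:
    """Azimuthal equidistant projection on the sphere, centred on (lon0, lat0).

    ``forward`` maps degrees to km offsets (x east, y north); ``inverse``
    maps back.  Distances *from the centre* are exact great-circle
    distances; distances between arbitrary nearby points are accurate to
    O((d/R)^2), negligible at trip scale.
    """

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self._lam0 = np.radians(self.lon0)
        self._phi0 = np.radians(self.lat0)

    def forward(self, lon, lat):
        lam = np.radians(np.asarray(lon, dtype=float))
        phi = np.radians(np.asarray(lat, dtype=float))
        dlam = lam - self._lam0
        cosc = (np.sin(self._phi0) * np.sin(phi)
                + np.cos(self._phi0) * np.cos(phi) * np.cos(dlam))
        cosc = np.clip(cosc, -1.0, 1.0)
        c = np.arccos(cosc)
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(c > 1e-12, c / np.sin(c), 1.0)
        x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(dlam)
        y = EARTH_RADIUS_KM * k * (np.cos(self._phi0) * np.sin(phi)
                                   - np.sin(self._phi0) * np.cos(phi) * np.cos(dlam))
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float) / EARTH_RADIUS_KM
        y = np.asarray(y, dtype=float) / EARTH_RADIUS_KM
        rho = np.hypot(x, y)
        c = rho
        sinc, cosc = np.sin(c), np.cos(c)
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = np.where(
                rho > 1e-12,
                np.arcsin(np.clip(cosc * np.sin(self._phi0)
                                  + y * sinc * np.cos(self._phi0) / np.where(rho > 1e-12, rho, 1.0),
                                  -1.0, 1.0)),
                self._phi0,
            )
            lam = np.where(
                rho > 1e-12,
                self._lam0 + np.arctan2(
                    x * sinc,
                    rho * np.cos(self._phi0) * cosc - y * np.sin(self._phi0) * sinc,
                ),
                self._lam0,
            )
        return np.degrees(lam), np.degrees(phi)


def _equal_area_xy(lon, lat):
    """Lambert cylindrical equal-area: km^2 areas are exact on the sphere."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = EARTH_RADIUS_KM * np.radians(lon)
    y = EARTH_RADIUS_KM * np.sin(np.radians(lat))
    return x, y


def to_equal_area(geom):
    """Project a shapely geometry (lon/lat degrees) to an equal-area plane (km)."""
    return _shapely_transform(_equal_area_xy, geom)


def geodesic_area_km2(geom) -> float:
    """Area of a lon/lat polygon in km^2 via the equal-area projection."""
    return float(to_equal_area(geom).area)
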