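"""Spherical geometry on a 6371-km earth.

Great-circle distances/bearings, slerp interpolation along a great circle,
and a local azimuthal-equidistant (AEQD) plane centred on the colony.  All
angles in degrees, distances in km unless a suffix says otherwise.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance between points (vectorized, degrees in, km out)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def initial_bearing_deg(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing from point 1 to point 2, in [0, 360)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    x = np.sin(dlon) * np.cos(lat2)
    y = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.degrees(np.arctan2(x, y)) % 360.0


def destination_point(lon, lat, bearing_deg, distance_km):
    """Point reached travelling `distance_km` along `bearing_deg` (spherical direct)."""
    lat1 = np.radians(np.asarray(lat, dtype=float))
    lon1 = np.radians(np.asarray(lon, dtype=float))
    brg = np.radians(np.asarray(bearing_deg, dtype=float))
    delta = np.asarray(distance_km, dtype=float) / EARTH_RADIUS_KM
    lat2 = np.arcsin(np.sin(lat1) * np.cos(delta) + np.cos(lat1) * np.sin(delta) * np.cos(brg))
    lon2 = lon1 + np.arctan2(
        np.sin(brg) * np.sin(delta) * np.cos(lat1),
        np.cos(delta) - np.sin(lat1) * np.sin(lat2),
    )
    return (np.degrees(lon2) + 180.0) % 360.0 - 180.0, np.degrees(lat2)


def _to_unit_vectors(lon, lat):
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    return np.stack([np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)], axis=-1)


def _from_unit_vectors(v):
    v = v / np.linalg.norm(v, axis=-1, keepdims=True)
    lat = np.degrees(np.arcsin(np.clip(v[..., 2], -1.0, 1.0)))
    lon = np.degrees(np.arctan2(v[..., 1], v[..., 0]))
    return lon, lat


def gc_interpolate(lon1, lat1, lon2, lat2, frac):
    """Great-circle interpolation (slerp); frac=0 → point 1, frac=1 → point 2.

    `frac` may be an array; antipodal endpoints are degenerate and not handled.
    """
    frac = np.asarray(frac, dtype=float)
    v1 = _to_unit_vectors(lon1, lat1)
    v2 = _to_unit_vectors(lon2, lat2)
    omega = np.arccos(np.clip(np.dot(v1, v2), -1.0, 1.0))
    if omega < 1e-12:
        lon = np.full_like(frac, float(lon1))
        lat = np.full_like(frac, float(lat1))
        return lon, lat
    w1 = np.sin((1.0 - frac) * omega) / np.sin(omega)
    w2 = np.sin(frac * omega) / np.sin(omega)
    v = w1[..., None] * v1 + w2[..., None] * v2
    return _from_unit_vectors(v)


class ColonyProjection:
    """Azimuthal-equidistant plane centred on the colony.

    x is metres east, y metres north of the colony; radial distances from the
    origin are exact great-circle distances, which is what a metric KDE grid
    and the 1-km trip filter need.
    """

    def __init__(self, colony_lon: float, colony_lat: float):
        self.colony_lon = float(colony_lon)
        self.colony_lat = float(colony_lat)

    def to_xy_m(self, lon, lat):
        d_km = haversine_km(self.colony_lon, self.colony_lat, lon, lat)
        theta = np.radians(initial_bearing_deg(self.colony_lon, self.colony_lat, lon, lat))
        return d_km * 1000.0 * np.sin(theta), d_km * 1000.0 * np.cos(theta)

    def to_lonlat(self, x_m, y_m):
        x_m = np.asarray(x_m, dtype=float)
        y_m = np.asarray(y_m, dtype=float)
        d_km = np.hypot(x_m, y_m) / 1000.0
        bearing = np.degrees(np.arctan2(x_m, y_m)) % 360.0
        return destination_point(self.colony_lon, self.colony_lat, bearing, d_km)
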