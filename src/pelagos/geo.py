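"""Spherical geodesy primitives: haversine distance, azimuths, and a local
azimuthal-equidistant projection.

All distances are kilometres on a sphere of radius 6371.0088 km (IUGG mean
Earth radius); all angles at the interface are degrees, with azimuths
clockwise from true north in [0, 360).
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def _check_finite(*arrays: np.ndarray) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise ValueError("non-finite coordinate")


def great_circle_km(lat1, lon1, lat2, lon2):
    """Haversine great-circle distance in km. Accepts scalars or arrays."""
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    _check_finite(lat1, lon1, lat2, lon2)
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dphi = p2 - p1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    out = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(out) if out.ndim == 0 else out


def initial_bearing(lat1, lon1, lat2, lon2):
    """Forward azimuth from point 1 to point 2, degrees in [0, 360).

    Raises ``ValueError`` for coincident points, where the bearing is
    undefined (returning an arbitrary 0 would silently bias downstream
    circular means).
    """
    lat1, lon1, lat2, lon2 = (np.asarray(x, dtype=float) for x in (lat1, lon1, lat2, lon2))
    _check_finite(lat1, lon1, lat2, lon2)
    if np.any((lat1 == lat2) & (np.mod(lon1 - lon2, 360.0) == 0.0)):
        raise ValueError("bearing undefined for coincident points")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dlam = np.radians(lon2 - lon1)
    y = np.sin(dlam) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlam)
    out = np.mod(np.degrees(np.arctan2(y, x)), 360.0)
    return float(out) if out.ndim == 0 else out


def destination(lat, lon, bearing_deg, distance_km):
    """Point reached from (lat, lon) travelling ``distance_km`` along the
    great circle with initial azimuth ``bearing_deg``. Returns (lat, lon)."""
    lat, lon, bearing_deg, distance_km = (
        np.asarray(x, dtype=float) for x in (lat, lon, bearing_deg, distance_km)
    )
    _check_finite(lat, lon, bearing_deg, distance_km)
    delta = distance_km / EARTH_RADIUS_KM
    theta = np.radians(bearing_deg)
    p1 = np.radians(lat)
    l1 = np.radians(lon)
    p2 = np.arcsin(np.sin(p1) * np.cos(delta) + np.cos(p1) * np.sin(delta) * np.cos(theta))
    l2 = l1 + np.arctan2(
        np.sin(theta) * np.sin(delta) * np.cos(p1),
        np.cos(delta) - np.sin(p1) * np.sin(p2),
    )
    lat2 = np.degrees(p2)
    lon2 = np.mod(np.degrees(l2) + 180.0, 360.0) - 180.0
    if lat2.ndim == 0:
        return float(lat2), float(lon2)
    return lat2, lon2


class AzimuthalEquidistant:
    """Spherical azimuthal-equidistant projection about a fixed centre.

    Distances and azimuths from the centre are preserved exactly, which makes
    the projection well suited to kernel estimation around a colony: a point
    d km from the centre maps to a planar point d km from the origin.  The
    inverse is exact up to floating-point rounding.
    """

    def __init__(self, center_lat: float, center_lon: float):
        if not (np.isfinite(center_lat) and np.isfinite(center_lon)):
            raise ValueError("non-finite projection centre")
        self.center_lat = float(center_lat)
        self.center_lon = float(center_lon)

    def forward(self, lat, lon):
        """lat/lon degrees -> planar (x, y) km, x east, y north."""
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        _check_finite(lat, lon)
        d = great_circle_km(self.center_lat, self.center_lon, lat, lon)
        d = np.atleast_1d(np.asarray(d, dtype=float))
        lat_a = np.atleast_1d(lat)
        lon_a = np.atleast_1d(lon)
        az = np.zeros_like(d)
        nz = d > 0
        if np.any(nz):
            az[nz] = np.radians(
                initial_bearing(self.center_lat, self.center_lon, lat_a[nz], lon_a[nz])
            )
        x = d * np.sin(az)
        y = d * np.cos(az)
        if np.asarray(lat).ndim == 0:
            return float(x[0]), float(y[0])
        return x, y

    def inverse(self, x, y):
        """Planar (x, y) km -> lat/lon degrees."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        _check_finite(x, y)
        d = np.hypot(x, y)
        az = np.degrees(np.arctan2(x, y))
        return destination(self.center_lat, self.center_lon, az, d)
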