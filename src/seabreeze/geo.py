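"""Geodesy helpers for short-range radar geometry.

All positions are WGS84 longitude/latitude in degrees.  Within the ~60 km
radar range a local tangent-plane approximation using the ellipsoid's
per-latitude degree lengths (meridional radius M, normal radius N) is
accurate to well under 0.01%, which is far below the radar's own positional
accuracy (+-90..200 m).  A slower spherical great-circle mode is kept for
cross-checking.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import LineString, Point

WGS84_A = 6378137.0
WGS84_F = 1.0 / 298.257223563
WGS84_E2 = WGS84_F * (2.0 - WGS84_F)

#: mean Earth radius (m), used by the spherical cross-check mode
EARTH_RADIUS = 6371008.8


def degree_lengths(lat_deg):
    """Metres per degree of latitude and longitude at a given latitude.

    Returns ``(m_per_deg_lat, m_per_deg_lon)`` from the WGS84 meridional
    and prime-vertical radii of curvature.
    """
    lat = np.radians(np.asarray(lat_deg, dtype=float))
    s2 = np.sin(lat) ** 2
    w = np.sqrt(1.0 - WGS84_E2 * s2)
    m_rad = WGS84_A * (1.0 - WGS84_E2) / w**3          # meridional
    n_rad = WGS84_A / w                                 # prime vertical
    deg = np.pi / 180.0
    return m_rad * deg, n_rad * np.cos(lat) * deg


def enu_displacement(lon0, lat0, lon1, lat1):
    """East/North displacement (m) from point 0 to point 1, local plane.

    Degree lengths are evaluated at the midpoint latitude.
    """
    lat_mid = 0.5 * (np.asarray(lat0, dtype=float) + np.asarray(lat1, dtype=float))
    m_lat, m_lon = degree_lengths(lat_mid)
    de = (np.asarray(lon1, dtype=float) - np.asarray(lon0, dtype=float)) * m_lon
    dn = (np.asarray(lat1, dtype=float) - np.asarray(lat0, dtype=float)) * m_lat
    return de, dn


def bearing_and_distance(lon0, lat0, lon1, lat1):
    """Initial bearing (deg clockwise from true North) and distance (m)."""
    de, dn = enu_displacement(lon0, lat0, lon1, lat1)
    brg = np.degrees(np.arctan2(de, dn)) % 360.0
    return brg, np.hypot(de, dn)


def great_circle_distance(lon0, lat0, lon1, lat1, radius=EARTH_RADIUS):
    """Spherical haversine distance (m) — the exact-geodesic test mode."""
    p0, p1 = np.radians(np.asarray(lat0, float)), np.radians(np.asarray(lat1, float))
    dl = np.radians(np.asarray(lon1, float) - np.asarray(lon0, float))
    h = np.sin((p1 - p0) / 2) ** 2 + np.cos(p0) * np.cos(p1) * np.sin(dl / 2) ** 2
    return 2.0 * radius * np.arcsin(np.sqrt(h))


def project_local(lon, lat, lon0, lat0):
    """Project lon/lat arrays to the local E/N plane centred at (lon0, lat0)."""
    m_lat, m_lon = degree_lengths(lat0)
    x = (np.asarray(lon, dtype=float) - lon0) * m_lon
    y = (np.asarray(lat, dtype=float) - lat0) * m_lat
    return x, y


def distance_to_polyline_km(lon, lat, line: LineString, mode: str = "planar") -> np.ndarray:
    """Minimum distance (km) from point(s) to a lon/lat polyline.

    mode="planar"  — project everything to the local plane centred on the
                     query point and use exact planar point-segment distance.
    mode="geodesic" — brute force: densify the polyline (~100 m spacing) and
                     take the minimum great-circle distance to the vertices.
    """
    if line.is_empty:
        raise ValueError("coastline polyline is empty")
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    coords = np.asarray(line.coords)
    out = np.empty(lon.shape)
    if mode == "planar":
        for i, (lo, la) in enumerate(zip(lon, lat)):
            x, y = project_local(coords[:, 0], coords[:, 1], lo, la)
            out[i] = Point(0.0, 0.0).distance(LineString(np.column_stack([x, y])))
        out /= 1000.0
    elif mode == "geodesic":
        dense = _densify(coords, step_deg=0.001)
        for i, (lo, la) in enumerate(zip(lon, lat)):
            out[i] = great_circle_distance(lo, la, dense[:, 0], dense[:, 1]).min()
        out /= 1000.0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out if out.size > 1 else out[0]


def _densify(coords: np.ndarray, step_deg: float) -> np.ndarray:
    pieces = []
    for (x0, y0), (x1, y1) in zip(coords[:-1], coords[1:]):
        n = max(2, int(np.hypot(x1 - x0, y1 - y0) / step_deg) + 1)
        t = np.linspace(0.0, 1.0, n)
        pieces.append(np.column_stack([x0 + t * (x1 - x0), y0 + t * (y1 - y0)]))
    return np.vstack(pieces)
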