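"""Azimuthal-equidistant projection on a sphere.

Local planar frame (x east, y north, km) centred on an arbitrary reference
point. Distances from the centre are exact great-circle distances; at the
<=300 km working ranges of a central-place forager the shape distortion is
far below GPS noise.
"""
from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def aeqd_forward(lat, lon, lat0: float, lon0: float):
    """Project WGS84 degrees to (x, y) km in the frame centred at (lat0, lon0)."""
    lat = np.deg2rad(np.asarray(lat, dtype=float))
    lon = np.deg2rad(np.asarray(lon, dtype=float))
    la0, lo0 = np.deg2rad(lat0), np.deg2rad(lon0)
    dlon = lon - lo0
    cos_c = np.sin(la0) * np.sin(lat) + np.cos(la0) * np.cos(lat) * np.cos(dlon)
    cos_c = np.clip(cos_c, -1.0, 1.0)
    c = np.arccos(cos_c)  # angular distance from centre
    az = np.arctan2(
        np.sin(dlon) * np.cos(lat),
        np.cos(la0) * np.sin(lat) - np.sin(la0) * np.cos(lat) * np.cos(dlon),
    )
    d = EARTH_RADIUS_KM * c
    return d * np.sin(az), d * np.cos(az)


def aeqd_inverse(x, y, lat0: float, lon0: float):
    """Inverse projection: (x, y) km back to (lat, lon) degrees."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    la0, lo0 = np.deg2rad(lat0), np.deg2rad(lon0)
    d = np.hypot(x, y)
    c = d / EARTH_RADIUS_KM
    az = np.arctan2(x, y)
    # destination-point formula along the initial azimuth
    lat = np.arcsin(
        np.sin(la0) * np.cos(c) + np.cos(la0) * np.sin(c) * np.cos(az)
    )
    lon = lo0 + np.arctan2(
        np.sin(az) * np.sin(c) * np.cos(la0),
        np.cos(c) - np.sin(la0) * np.sin(lat),
    )
    lat = np.rad2deg(lat)
    lon = (np.rad2deg(lon) + 540.0) % 360.0 - 180.0
    # centre itself: az undefined but d=0 gives the centre back exactly
    return lat, lon
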