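"""Great-circle and tangent-plane geometry shared across the pipeline.

All distances are in kilometres on a sphere of radius 6371.0 km; coordinates
are WGS84 decimal degrees.  The tangent-plane projection is an azimuthal
equidistant map centred on a user-chosen origin: every projected point sits at
its true great-circle distance from the origin, in the direction of its true
initial bearing.  At the <=1000 km working scales of a Coral Sea telemetry
study the round-trip error is far below the positional error of the data.
"""
from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or numpy arrays (broadcasting applies).
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    if np.ndim(d) == 0:
        return float(d)
    return d


def project_xy(lon, lat, origin_lon, origin_lat):
    """Azimuthal-equidistant projection to (x, y) km about an origin.

    x is east, y is north.  Points should lie within ~15 degrees of the
    origin for the small-scale assumptions of the downstream analyses to
    hold, though the projection itself is global (antipode excluded).
    """
    lon = np.radians(np.asarray(lon, dtype=float))
    lat = np.radians(np.asarray(lat, dtype=float))
    lon0 = np.radians(float(origin_lon))
    lat0 = np.radians(float(origin_lat))
    dlon = lon - lon0
    cosc = np.sin(lat0) * np.sin(lat) + np.cos(lat0) * np.cos(lat) * np.cos(dlon)
    cosc = np.clip(cosc, -1.0, 1.0)
    c = np.arccos(cosc)  # angular distance from origin
    # k = c / sin(c); -> 1 as c -> 0
    with np.errstate(invalid="ignore", divide="ignore"):
        k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
    x = EARTH_RADIUS_KM * k * np.cos(lat) * np.sin(dlon)
    y = EARTH_RADIUS_KM * k * (np.cos(lat0) * np.sin(lat)
                               - np.sin(lat0) * np.cos(lat) * np.cos(dlon))
    return x, y


def unproject_xy(x, y, origin_lon, origin_lat):
    """Inverse of :func:`project_xy`; returns (lon, lat) in degrees."""
    x = np.asarray(x, dtype=float) / EARTH_RADIUS_KM
    y = np.asarray(y, dtype=float) / EARTH_RADIUS_KM
    lon0 = np.radians(float(origin_lon))
    lat0 = np.radians(float(origin_lat))
    c = np.hypot(x, y)
    safe_c = np.where(c > 1e-12, c, 1.0)
    sinc = np.sin(c)
    cosc = np.cos(c)
    lat = np.arcsin(np.clip(cosc * np.sin(lat0)
                            + np.where(c > 1e-12, y * sinc * np.cos(lat0) / safe_c, 0.0),
                            -1.0, 1.0))
    lon = lon0 + np.arctan2(x * sinc,
                            safe_c * np.cos(lat0) * cosc - y * np.sin(lat0) * sinc)
    lon = np.where(c > 1e-12, lon, lon0)
    lat = np.where(c > 1e-12, lat, lat0)
    return np.degrees(lon), np.degrees(lat)
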