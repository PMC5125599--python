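"""Great-circle geometry helpers.

All coordinates are decimal degrees (WGS84). Distances are haversine
great-circle distances on a sphere of radius 6371.0088 km (IUGG mean
Earth radius), which is the reproducible large-scale reading of
"straight-line distance between centroids" for a study area spanning
several hundred kilometres.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088

__all__ = ["EARTH_RADIUS_KM", "haversine_km", "validate_coords", "offset_km"]


def validate_coords(lat, lon) -> None:
    """Raise ValueError if any latitude/longitude is outside valid bounds."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if not (np.all(np.isfinite(lat)) and np.all(np.isfinite(lon))):
        raise ValueError("non-finite coordinate")
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude out of range [-90, 90]")
    if np.any(np.abs(lon) > 180.0):
        raise ValueError("longitude out of range [-180, 180]")


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between (lat1, lon1) and (lat2, lon2).

    Accepts scalars or broadcastable arrays; returns float for scalar input.
    """
    validate_coords(lat1, lon1)
    validate_coords(lat2, lon2)
    p1, l1, p2, l2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dphi = p2 - p1
    dlam = l2 - l1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    return float(d) if np.ndim(d) == 0 else d


def offset_km(lat, lon, east_km, north_km):
    """Displace a point by (east, north) kilometres using a local tangent plane.

    Adequate for the few tens of km used when jittering locations around a
    population centroid; not intended for long-range navigation.
    """
    validate_coords(lat, lon)
    dlat = north_km / 111.32
    dlon = east_km / (111.32 * max(np.cos(np.radians(lat)), 1e-6))
    return lat + dlat, lon + dlon
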