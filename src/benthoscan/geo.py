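"""Great-circle geometry shared across modules.

All coordinates are WGS84 decimal degrees; distances are metres on a
spherical Earth (R = 6371 km), which is accurate to well under a metre over
the ≤10 km transects this package targets.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_000.0


def haversine_m(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in metres between (lon1, lat1) and (lon2, lat2).

    Accepts scalars or broadcastable arrays of decimal degrees.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_haversine_m(lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
    """Full n x n great-circle distance matrix (metres)."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    return haversine_m(lon[:, None], lat[:, None], lon[None, :], lat[None, :])


def destination_east_m(lon: np.ndarray, lat: float, distance_m: np.ndarray) -> np.ndarray:
    """Longitude reached by moving ``distance_m`` due east along a parallel."""
    dlon = np.degrees(np.asarray(distance_m, dtype=float) / (EARTH_RADIUS_M * np.cos(np.radians(lat))))
    return np.asarray(lon, dtype=float) + dlon
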