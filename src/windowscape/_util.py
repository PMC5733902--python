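"""Shared numerical helpers."""
from __future__ import annotations

import numpy as np

#: Earth radius used for all great-circle distances (km).
EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or broadcastable arrays.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    # clip guards against rounding for antipodal points
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def pairwise_haversine_km(lons, lats):
    """Symmetric n x n great-circle distance matrix (km)."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    return haversine_km(lons[:, None], lats[:, None], lons[None, :], lats[None, :])


def validate_coords(lons, lats):
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    if np.any(~np.isfinite(lons)) or np.any(~np.isfinite(lats)):
        raise ValueError("non-finite coordinates")
    if np.any(np.abs(lats) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    if np.any(np.abs(lons) > 180.0):
        raise ValueError("longitude outside [-180, 180]")
    return lons, lats


def condensed_index_matrix(n: int) -> np.ndarray:
    """n x n integer matrix mapping (i, j) to the condensed (upper-triangle)
    vector position of that pair; the diagonal holds -1."""
    m = np.full((n, n), -1, dtype=np.int64)
    iu = np.triu_indices(n, k=1)
    m[iu] = np.arange(iu[0].size)
    m[(iu[1], iu[0])] = m[iu]
    return m
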