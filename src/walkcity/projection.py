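"""Local planar projection for geographic coordinates.

All analysis runs in a planar metric frame. Inputs supplied in geographic
coordinates (e.g. GTFS ``stop_lat``/``stop_lon``) are projected with a local
equirectangular transform anchored at a reference origin: accurate to well
under a metre over the extent of a single city, which is all the distance
thresholds here require.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_000.0


def lonlat_to_xy(lon, lat, lon0: float = 0.0, lat0: float = 0.0):
    """Project geographic degrees to local planar metres.

    ``x`` grows east, ``y`` grows north; the origin ``(lon0, lat0)`` maps
    to ``(0, 0)``.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    k = np.cos(np.radians(lat0))
    x = np.radians(lon - lon0) * EARTH_RADIUS_M * k
    y = np.radians(lat - lat0) * EARTH_RADIUS_M
    return x, y


def xy_to_lonlat(x, y, lon0: float = 0.0, lat0: float = 0.0):
    """Inverse of :func:`lonlat_to_xy`."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    k = np.cos(np.radians(lat0))
    lon = lon0 + np.degrees(x / (EARTH_RADIUS_M * k))
    lat = lat0 + np.degrees(y / EARTH_RADIUS_M)
    return lon, lat
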