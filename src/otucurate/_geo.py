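"""Spherical geodesy helpers: haversine distance and a local azimuthal
equidistant projection.

All distances are in kilometres, coordinates in WGS84 decimal degrees
(longitude east-positive).  At the ~200 km working scale the spherical
approximation is accurate to well under the 0.5 km tolerance used by the
spatial validation tests.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or numpy arrays (broadcasting applies).
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


class AzimuthalEquidistant:
    """Local azimuthal equidistant projection centred on (lat0, lon0).

    Distances from the centre are exact; distances between off-centre
    points distort slowly with distance from the centre.
    """

    def __init__(self, lat0: float, lon0: float):
        self.lat0 = float(lat0)
        self.lon0 = float(lon0)
        self._phi0 = np.radians(self.lat0)
        self._lam0 = np.radians(self.lon0)

    def forward(self, lat, lon):
        """Project (lat, lon) degrees -> (x, y) km in the local plane."""
        phi = np.radians(np.asarray(lat, dtype=float))
        lam = np.radians(np.asarray(lon, dtype=float))
        dlam = lam - self._lam0
        cos_c = np.sin(self._phi0) * np.sin(phi) + np.cos(self._phi0) * np.cos(phi) * np.cos(dlam)
        c = np.arccos(np.clip(cos_c, -1.0, 1.0))
        # k = c / sin(c), with the c -> 0 limit of 1
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
        x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(dlam)
        y = EARTH_RADIUS_KM * k * (np.cos(self._phi0) * np.sin(phi) - np.sin(self._phi0) * np.cos(phi) * np.cos(dlam))
        return x, y
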