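"""Local projection between geographic (lon/lat, WGS84) and planar feet.

Building morphology features and occupancy rates are defined in feet and
square feet, while footprints are delivered in geographic coordinates.  For
the desk-scale extents this package targets (a few kilometres across) a
local equirectangular projection -- longitude scaled by cos(lat0), both
axes scaled to feet on the WGS84 sphere -- is length-preserving to well
under 0.1% and, being affine in (lon, lat), preserves area ratios exactly.

The reference latitude is taken from the data unless supplied; the policy
object records it so every run can log the projection it used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: WGS84 equatorial radius expressed in international feet.
EARTH_RADIUS_FT = 6_378_137.0 / 0.3048

#: Metres per international foot.
FT_PER_M = 1 / 0.3048


@dataclass(frozen=True)
class ProjectionPolicy:
    """Local equirectangular projection anchored at (lon0, lat0)."""

    lon0: float
    lat0: float

    @classmethod
    def for_bounds(cls, lon_min: float, lat_min: float, lon_max: float, lat_max: float) -> "ProjectionPolicy":
        if not (-90.0 < (lat_min + lat_max) / 2 < 90.0):
            raise ValueError("cannot resolve a local projection at the poles")
        return cls(lon0=(lon_min + lon_max) / 2, lat0=(lat_min + lat_max) / 2)

    @property
    def _kx(self) -> float:
        return EARTH_RADIUS_FT * math.cos(math.radians(self.lat0)) * math.pi / 180.0

    @property
    def _ky(self) -> float:
        return EARTH_RADIUS_FT * math.pi / 180.0

    def to_feet(self, lon, lat):
        """Project geographic coordinates to local planar feet."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        return (lon - self.lon0) * self._kx, (lat - self.lat0) * self._ky

    def to_geographic(self, x_ft, y_ft):
        x_ft = np.asarray(x_ft, dtype=float)
        y_ft = np.asarray(y_ft, dtype=float)
        return x_ft / self._kx + self.lon0, y_ft / self._ky + self.lat0

    def describe(self) -> dict:
        return {
            "kind": "local_equirectangular_feet",
            "lon0": self.lon0,
            "lat0": self.lat0,
        }


def project_geometry(geom, policy: ProjectionPolicy):
    """Return a copy of a shapely geometry with coordinates in local feet."""
    import shapely

    def _tx(coords):
        x, y = policy.to_feet(coords[:, 0], coords[:, 1])
        return np.column_stack([x, y])

    return shapely.transform(geom, _tx)
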