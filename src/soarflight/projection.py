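"""Map projections for converting geographic fixes to planar meters.

Telemetry arrives as (longitude, latitude, altitude MSL).  Movement
modelling needs planar east/north coordinates in meters, so fixes are
projected with the North America Albers Equal Area Conic projection
(GRS80 ellipsoid; standard parallels 20 N and 60 N, central meridian
96 W, latitude of origin 40 N).  The closed-form ellipsoidal equations
follow Snyder (1987, "Map Projections: A Working Manual", section 14);
the inverse recovers latitude from the authalic quantity q by Newton
iteration.

Synthetic data is generated directly in planar coordinates, so an
identity "projection" is provided for that path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidInputError

# GRS80 ellipsoid
_A = 6378137.0
_E2 = 0.0066943800229007876


def _q(sin_phi: np.ndarray) -> np.ndarray:
    """Authalic q for geodetic latitude (Snyder 3-12)."""
    e = np.sqrt(_E2)
    return (1.0 - _E2) * (
        sin_phi / (1.0 - _E2 * sin_phi**2)
        - (1.0 / (2.0 * e)) * np.log((1.0 - e * sin_phi) / (1.0 + e * sin_phi))
    )


@dataclass(frozen=True)
class AlbersProjection:
    """Albers Equal Area Conic on the GRS80 ellipsoid.

    Defaults are the North America Albers parameters used for
    continental-US telemetry.
    """

    lat_origin: float = 40.0
    lon_origin: float = -96.0
    lat_parallel_1: float = 20.0
    lat_parallel_2: float = 60.0

    def _constants(self):
        phi1 = np.radians(self.lat_parallel_1)
        phi2 = np.radians(self.lat_parallel_2)
        phi0 = np.radians(self.lat_origin)
        m1 = np.cos(phi1) / np.sqrt(1.0 - _E2 * np.sin(phi1) ** 2)
        m2 = np.cos(phi2) / np.sqrt(1.0 - _E2 * np.sin(phi2) ** 2)
        q0 = _q(np.sin(phi0))
        q1 = _q(np.sin(phi1))
        q2 = _q(np.sin(phi2))
        n = (m1**2 - m2**2) / (q2 - q1)
        C = m1**2 + n * q1
        rho0 = _A * np.sqrt(C - n * q0) / n
        return n, C, rho0

    def forward(self, lon, lat):
        """Geographic degrees -> planar (x east, y north) in meters."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        if np.any(np.abs(lat) > 90.0) or np.any(np.abs(lon) > 360.0):
            raise InvalidInputError("longitude/latitude out of valid range")
        n, C, rho0 = self._constants()
        q = _q(np.sin(np.radians(lat)))
        rho = _A * np.sqrt(C - n * q) / n
        theta = n * np.radians(lon - self.lon_origin)
        x = rho * np.sin(theta)
        y = rho0 - rho * np.cos(theta)
        return x, y

    def inverse(self, x, y):
        """Planar meters -> geographic degrees (lon, lat)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        n, C, rho0 = self._constants()
        rho = np.hypot(x, rho0 - y)
        theta = np.arctan2(x, rho0 - y)
        lon = self.lon_origin + np.degrees(theta / n)
        q = (C - (rho * n / _A) ** 2) / n
        # Newton iteration for latitude from authalic q (Snyder 3-16)
        phi = np.arcsin(np.clip(q / 2.0, -1.0, 1.0))
        e = np.sqrt(_E2)
        for _ in range(10):
            s = np.sin(phi)
            num = q / (1.0 - _E2) - s / (1.0 - _E2 * s**2) + (
                1.0 / (2.0 * e)
            ) * np.log((1.0 - e * s) / (1.0 + e * s))
            dphi = ((1.0 - _E2 * s**2) ** 2 / (2.0 * np.cos(phi))) * num
            phi = phi + dphi
            if np.all(np.abs(dphi) < 1e-14):
                break
        return lon, np.degrees(phi)


@dataclass(frozen=True)
class IdentityProjection:
    """Pass-through projection for inputs that are already planar meters."""

    def forward(self, lon, lat):
        return np.asarray(lon, dtype=float), np.asarray(lat, dtype=float)

    def inverse(self, x, y):
        return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def get_projection(name: str):
    """Look up a projection by config name ('albers' or 'identity')."""
    name = name.lower()
    if name in ("albers", "na_albers", "albers_conic"):
        return AlbersProjection()
    if name in ("identity", "planar", "none"):
        return IdentityProjection()
    raise InvalidInputError(f"unknown projection {name!r}")
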