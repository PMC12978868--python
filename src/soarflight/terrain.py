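"""Terrain and wind grids, slope/aspect, and the orographic updraft field.

Conventions used throughout the package:

* Planar coordinates: x east, y north, meters.  A grid node ``(ix, iy)``
  sits at ``(origin_x + ix * spacing, origin_y + iy * spacing)`` and 2D
  arrays are indexed ``[iy, ix]`` (row = northing index, increasing
  northward).
* Compass angles: degrees clockwise from north.  Wind direction uses the
  meteorological "from" convention (0 deg = wind from the north).  Aspect
  is the facing (downhill) direction of a slope, 0 deg = north-facing,
  reported in [-180, 180].
* Orographic updraft at a point with wind speed w, wind direction phi_w,
  ground slope phi_s and aspect phi_a is

      wo = max(0, w * sin(phi_s) * cos(phi_w - phi_a))

  i.e. terrain-deflected lift where the wind blows onto the slope face;
  downdrafts are clipped to zero.  The nodewise field is then smoothed
  with a Gaussian filter (default length scale 250 m) to remove abrupt
  variation from the crude estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter

from .errors import InvalidInputError, OutOfDomainError

__all__ = [
    "TerrainGrid",
    "WindField",
    "UpdraftField",
    "compute_slope_aspect",
    "bilinear_sample",
    "orographic_updraft",
    "build_updraft_field",
    "wind_components",
    "read_ascii_grid",
    "write_ascii_grid",
]


@dataclass
class TerrainGrid:
    """Regular elevation raster with derived slope and aspect.

    Attributes
    ----------
    origin_xy : (float, float)
        Planar coordinates (m) of the south-west grid node.
    spacing : float
        Uniform cell size (m).
    elevation : ndarray, shape (ny, nx)
        Ground elevation above mean sea level (m).
    slope : ndarray or None
        Ground slope in degrees, [0, 90].
    aspect : ndarray or None
        Downhill facing direction in degrees, [-180, 180], 0 = north.
    flat_mask : ndarray or None
        True where the gradient vanished and aspect is conventional (0).
    """

    origin_xy: tuple[float, float]
    spacing: float
    elevation: np.ndarray
    slope: Optional[np.ndarray] = None
    aspect: Optional[np.ndarray] = None
    flat_mask: Optional[np.ndarray] = None

    def __post_init__(self):
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.spacing <= 0:
            raise InvalidInputError("grid spacing must be positive")
        if self.elevation.ndim != 2:
            raise InvalidInputError("elevation must be a 2D array")
        if not np.all(np.isfinite(self.elevation)):
            raise InvalidInputError("elevation must be finite everywhere")

    @property
    def shape(self) -> tuple[int, int]:
        return self.elevation.shape

    @property
    def x_coords(self) -> np.ndarray:
        return self.origin_xy[0] + self.spacing * np.arange(self.shape[1])

    @property
    def y_coords(self) -> np.ndarray:
        return self.origin_xy[1] + self.spacing * np.arange(self.shape[0])

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the node lattice."""
        x = self.x_coords
        y = self.y_coords
        return (x[0], y[0], x[-1], y[-1])

    def contains(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.bounds
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)


def compute_slope_aspect(terrain: TerrainGrid) -> TerrainGrid:
    """Fill ``slope``/``aspect`` from finite differences of elevation.

    Central differences in the interior, one-sided at the edges
    (``numpy.gradient``).  Aspect is the compass direction of steepest
    descent; on perfectly flat cells it is set to 0 with ``flat_mask``
    raised (inert downstream: the updraft formula has sin(slope) = 0).
    """
    ny, nx = terrain.shape
    if ny < 3 or nx < 3:
        raise InvalidInputError("slope/aspect needs a grid of at least 3x3")
    dz_dy, dz_dx = np.gradient(terrain.elevation, terrain.spacing)
    grad_mag = np.hypot(dz_dx, dz_dy)
    slope = np.degrees(np.arctan(grad_mag))
    flat = grad_mag == 0.0
    # downhill vector is -grad; compass angle of (ex, ey) is atan2(ex, ey)
    aspect = np.degrees(np.arctan2(-dz_dx, -dz_dy))
    aspect[aspect == -180.0] = 180.0  # -0 gradient artefact; range is (-180, 180]
    aspect[flat] = 0.0
    terrain.slope = slope
    terrain.aspect = aspect
    terrain.flat_mask = flat
    return terrain


def bilinear_sample(
    grid: np.ndarray,
    x,
    y,
    origin_xy: tuple[float, float],
    spacing: float,
):
    """Bilinearly interpolate a gridded field at planar points.

    Parameters mirror :class:`TerrainGrid`: ``grid`` is ``(ny, nx)`` with
    rows indexed by northing.  Raises :class:`OutOfDomainError` for
    queries outside the node lattice, listing the offending indices.
    """
    grid = np.asarray(grid, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    scalar = x.ndim == 0 and y.ndim == 0
    x, y = np.broadcast_arrays(np.atleast_1d(x), np.atleast_1d(y))
    ny, nx = grid.shape
    ys = origin_xy[1] + spacing * np.arange(ny)
    xs = origin_xy[0] + spacing * np.arange(nx)
    inside = (x >= xs[0]) & (x <= xs[-1]) & (y >= ys[0]) & (y <= ys[-1])
    if not np.all(inside):
        bad = np.flatnonzero(~inside)
        raise OutOfDomainError(
            f"{bad.size} query point(s) outside grid bounds", indices=bad
        )
    interp = RegularGridInterpolator((ys, xs), grid, method="linear")
    vals = interp(np.column_stack([y.ravel(), x.ravel()])).reshape(x.shape)
    return float(vals[0]) if scalar else vals


@dataclass
class WindField:
    """Wind speed/direction at 80 m AGL: constant or hourly gridded layers.

    A constant wind is ``WindField(speed=8.0, direction=270.0)``.  A
    gridded wind supplies ``times`` (seconds, one per layer) plus
    ``speed``/``direction`` arrays of shape ``(nt, ny, nx)`` on the grid
    defined by ``origin_xy``/``spacing``.  Sampling is bilinear in space
    and linear in time; direction interpolates along the shorter arc.
    """

    speed: float | np.ndarray
    direction: float | np.ndarray
    times: Optional[Sequence[float]] = None
    origin_xy: Optional[tuple[float, float]] = None
    spacing: Optional[float] = None

    def __post_init__(self):
        if np.any(np.asarray(self.speed, dtype=float) < 0):
            raise InvalidInputError("wind speed must be non-negative")
        self.direction = np.mod(np.asarray(self.direction, dtype=float), 360.0)
        if self.is_gridded:
            self.speed = np.asarray(self.speed, dtype=float)
            self.times = np.asarray(self.times, dtype=float)
            if self.speed.ndim != 3 or self.direction.ndim != 3:
                raise InvalidInputError("gridded wind needs (nt, ny, nx) arrays")
            if self.origin_xy is None or self.spacing is None:
                raise InvalidInputError("gridded wind needs origin_xy and spacing")

    @property
    def is_gridded(self) -> bool:
        return self.times is not None

    def _time_weights(self, t: float):
        times = self.times
        if t <= times[0]:
            return 0, 0, 0.0
        if t >= times[-1]:
            return len(times) - 1, len(times) - 1, 0.0
        i1 = int(np.searchsorted(times, t, side="right"))
        i0 = i1 - 1
        frac = (t - times[i0]) / (times[i1] - times[i0])
        return i0, i1, float(frac)

    def sample(self, x, y, t: float = 0.0):
        """Return (speed, direction) at planar points and time ``t``."""
        if not self.is_gridded:
            x = np.asarray(x, dtype=float)
            w = np.full(x.shape, float(self.speed))
            d = np.full(x.shape, float(self.direction))
            if x.ndim == 0:
                return float(self.speed), float(self.direction)
            return w, d
        i0, i1, frac = self._time_weights(t)
        w0 = bilinear_sample(self.speed[i0], x, y, self.origin_xy, self.spacing)
        d0 = bilinear_sample(self.direction[i0], x, y, self.origin_xy, self.spacing)
        if i0 == i1 or frac == 0.0:
            return w0, np.mod(d0, 360.0)
        w1 = bilinear_sample(self.speed[i1], x, y, self.origin_xy, self.spacing)
        d1 = bilinear_sample(self.direction[i1], x, y, self.origin_xy, self.spacing)
        w = (1.0 - frac) * w0 + frac * w1
        # interpolate direction along the shorter arc
        delta = np.mod(d1 - d0 + 180.0, 360.0) - 180.0
        d = np.mod(d0 + frac * delta, 360.0)
        return w, d


@dataclass
class UpdraftField:
    """Smoothed non-negative orographic updraft on a terrain lattice."""

    values: np.ndarray
    origin_xy: tuple[float, float]
    spacing: float
    smoothing_radius: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise InvalidInputError("updraft field must be non-negative")

    def sample(self, x, y):
        return bilinear_sample(self.values, x, y, self.origin_xy, self.spacing)

    def contains(self, x, y):
        ny, nx = self.values.shape
        xmax = self.origin_xy[0] + self.spacing * (nx - 1)
        ymax = self.origin_xy[1] + self.spacing * (ny - 1)
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.origin_xy[0]) & (x <= xmax)
            & (y >= self.origin_xy[1]) & (y <= ymax)
        )


def orographic_updraft(w, phi_w, slope, aspect):
    """Pointwise orographic updraft, negatives clipped to zero (m/s)."""
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise InvalidInputError("wind speed must be non-negative")
    raw = (
        w
        * np.sin(np.radians(np.asarray(slope, dtype=float)))
        * np.cos(np.radians(np.asarray(phi_w, dtype=float) - np.asarray(aspect, dtype=float)))
    )
    return np.maximum(raw, 0.0)


def build_updraft_field(
    terrain: TerrainGrid,
    wind: WindField,
    radius: float = 250.0,
    t: float = 0.0,
) -> UpdraftField:
    """Nodewise updraft, clipped at zero, then Gaussian smoothed.

    ``radius`` is the Gaussian standard deviation in meters, converted to
    cells by the grid spacing.  Clipping precedes smoothing, so the
    smoothed field stays within [0, max of the clipped field].
    """
    if radius < 0:
        raise InvalidInputError("smoothing radius must be non-negative")
    if terrain.slope is None or terrain.aspect is None:
        compute_slope_aspect(terrain)
    if wind.is_gridded:
        xg, yg = np.meshgrid(terrain.x_coords, terrain.y_coords)
        w, phi_w = wind.sample(xg, yg, t)
    else:
        w = float(wind.speed)
        phi_w = float(wind.direction)
    raw = orographic_updraft(w, phi_w, terrain.slope, terrain.aspect)
    sigma_cells = radius / terrain.spacing
    smoothed = gaussian_filter(raw, sigma=sigma_cells) if sigma_cells > 0 else raw
    smoothed = np.maximum(smoothed, 0.0)
    return UpdraftField(
        values=smoothed,
        origin_xy=terrain.origin_xy,
        spacing=terrain.spacing,
        smoothing_radius=radius,
    )


def wind_components(w, phi_w, heading):
    """Tailwind and crosswind relative to a compass heading.

        wt = w * cos(theta - phi_w),  wc = w * sin(theta - phi_w)

    so wt^2 + wc^2 = w^2 exactly.  Positive wc points clockwise of the
    heading.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise InvalidInputError("wind speed must be non-negative")
    rel = np.radians(np.asarray(heading, dtype=float) - np.asarray(phi_w, dtype=float))
    return w * np.cos(rel), w * np.sin(rel)


def read_ascii_grid(path) -> tuple[np.ndarray, tuple[float, float], float]:
    """Read an ESRI ASCII grid; returns (array[ny, nx], origin_xy, spacing).

    Rows in the file run north to south; the returned array is flipped to
    this package's south-origin row convention.  ``xllcorner``/``yllcorner``
    are taken as the coordinates of the south-west node.
    """
    header: dict[str, float] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    arr = np.array(rows, dtype=float)[::-1]
    if arr.shape != (int(header["nrows"]), int(header["ncols"])):
        raise InvalidInputError("ASCII grid data does not match header shape")
    origin = (header["xllcorner"], header["yllcorner"])
    return arr, origin, header["cellsize"]


def write_ascii_grid(path, array: np.ndarray, origin_xy, spacing: float) -> None:
    """Write a 2D field as an ESRI ASCII grid (north-to-south rows)."""
    array = np.asarray(array, dtype=float)
    ny, nx = array.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {nx}\n")
        fh.write(f"nrows {ny}\n")
        fh.write(f"xllcorner {float(origin_xy[0])!r}\n")
        fh.write(f"yllcorner {float(origin_xy[1])!r}\n")
        fh.write(f"cellsize {float(spacing)!r}\n")
        fh.write("NODATA_value -9999\n")
        for row in array[::-1]:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def load_terrain(path) -> TerrainGrid:
    """Read an ASCII-grid DEM and compute slope/aspect."""
    arr, origin, spacing = read_ascii_grid(path)
    return compute_slope_aspect(TerrainGrid(origin_xy=origin, spacing=spacing, elevation=arr))
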