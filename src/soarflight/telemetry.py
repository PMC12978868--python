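"""GPS fix ingestion, quality filtering, and track segmentation.

Raw telemetry is a time-ordered table of fixes (timestamp, longitude,
latitude, altitude MSL) per individual.  Preprocessing follows three
steps:

1. project geographic coordinates to planar east/north meters;
2. drop fixes with finite-difference horizontal speed below 1 m/s
   (mostly-stationary birds) and fixes implicated in vertical-speed
   changes of 6 m/s^2 or more (unrealistic altitude jumps);
3. segment into tracks split at time gaps above 10 s, keeping segments
   longer than 5 min with at least 50 fixes.

Fix tables are pandas DataFrames with columns ``t`` (s), ``px``/``py``
(m east/north) and ``pz`` (m MSL).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .projection import IdentityProjection, get_projection

#: default quality-filter thresholds
SPEED_MIN = 1.0          # m/s, horizontal
VZ_CHANGE_MAX = 6.0      # m/s^2, vertical-speed change
GAP_MAX = 10.0           # s, max in-track interval
DURATION_MIN = 300.0     # s, min track duration (exclusive)
POINTS_MIN = 50          # min fixes per track

FIX_COLUMNS = ["t", "px", "py", "pz"]


@dataclass
class Track:
    """One calibration-grade segment of planar fixes."""

    track_id: int
    fixes: pd.DataFrame

    def __post_init__(self):
        t = self.fixes["t"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise InvalidInputError("track timestamps must be strictly increasing")

    @property
    def duration(self) -> float:
        t = self.fixes["t"].to_numpy()
        return float(t[-1] - t[0])

    def __len__(self) -> int:
        return len(self.fixes)


def read_fixes(
    path,
    t_col: str = "t",
    lon_col: str = "lon",
    lat_col: str = "lat",
    alt_col: str = "alt_msl",
    sep: str = ",",
) -> pd.DataFrame:
    """Read a delimited-text fix table into canonical column names."""
    df = pd.read_csv(path, sep=sep)
    out = pd.DataFrame(
        {
            "t": df[t_col].astype(float),
            "lon": df[lon_col].astype(float),
            "lat": df[lat_col].astype(float),
            "alt_msl": df[alt_col].astype(float),
        }
    )
    return out


def project_fixes(fixes: pd.DataFrame, projection="albers") -> pd.DataFrame:
    """Project (lon, lat, alt) fixes to planar (px, py, pz).

    ``projection`` is a config name ('albers' for the North America
    Albers Equal Area Conic, 'identity' for already-planar synthetic
    input) or a projection object with a ``forward`` method.  Fixes with
    invalid coordinates are rejected record-by-record with a logged count.
    """
    proj = get_projection(projection) if isinstance(projection, str) else projection
    lon = fixes["lon"].to_numpy(dtype=float)
    lat = fixes["lat"].to_numpy(dtype=float)
    valid = np.isfinite(lon) & np.isfinite(lat)
    geographic = not isinstance(proj, IdentityProjection)
    if geographic:
        valid &= (np.abs(lat) <= 90.0) & (np.abs(lon) <= 360.0)
    n_bad = int((~valid).sum())
    if n_bad:
        warnings.warn(f"rejected {n_bad} fix(es) with invalid coordinates")
    fixes = fixes.loc[valid]
    px, py = proj.forward(fixes["lon"].to_numpy(), fixes["lat"].to_numpy())
    return pd.DataFrame(
        {
            "t": fixes["t"].to_numpy(dtype=float),
            "px": np.asarray(px, dtype=float),
            "py": np.asarray(py, dtype=float),
            "pz": fixes["alt_msl"].to_numpy(dtype=float),
        }
    )


def _filter_pass(df: pd.DataFrame, speed_min: float, vz_change_max: float):
    """One removal pass; returns (filtered df, n_removed)."""
    t = df["t"].to_numpy()
    px = df["px"].to_numpy()
    py = df["py"].to_numpy()
    pz = df["pz"].to_numpy()
    n = len(df)

    dt = np.diff(t)
    # horizontal speed: backward difference; forward difference for fix 0
    hstep = np.hypot(np.diff(px), np.diff(py))
    hspeed = np.empty(n)
    hspeed[1:] = hstep / dt
    hspeed[0] = hspeed[1] if n > 1 else np.inf
    slow = hspeed < speed_min

    # vertical-speed change: vz on intervals, its change at interior fixes;
    # the central fix of an offending triple is removed
    vz = np.diff(pz) / dt
    spike = np.zeros(n, dtype=bool)
    if n >= 3:
        dvz = np.diff(vz)
        step = 0.5 * (dt[:-1] + dt[1:])
        accel = np.abs(dvz) / step
        spike[1:-1] = accel >= vz_change_max

    keep = ~(slow | spike)
    return df.loc[keep], int(n - keep.sum())


def filter_fixes(
    fixes: pd.DataFrame,
    speed_min: float = SPEED_MIN,
    vz_change_max: float = VZ_CHANGE_MAX,
) -> pd.DataFrame:
    """Apply the horizontal-speed and vertical-spike filters to a fixed point.

    Removals change neighbouring finite differences, so passes repeat
    until no fix is removed; this makes the filter idempotent.  Exact
    duplicate timestamps are dropped first.  Fewer than 3 fixes are
    returned unchanged with a warning.
    """
    fixes = fixes.drop_duplicates(subset="t", keep="first")
    if len(fixes) < 3:
        warnings.warn("fewer than 3 fixes; filters not applied")
        return fixes.reset_index(drop=True)
    df = fixes
    while len(df) >= 3:
        df, removed = _filter_pass(df, speed_min, vz_change_max)
        if removed == 0:
            break
    return df.reset_index(drop=True)


def segment_tracks(
    fixes: pd.DataFrame,
    gap_max: float = GAP_MAX,
    duration_min: float = DURATION_MIN,
    points_min: int = POINTS_MIN,
    first_id: int = 0,
) -> list[Track]:
    """Split filtered fixes into tracks at gaps > ``gap_max`` seconds.

    Only segments with duration strictly above ``duration_min`` AND at
    least ``points_min`` fixes survive.  Fixes are never reordered or
    fabricated; an empty result is valid.
    """
    if len(fixes) == 0:
        return []
    t = fixes["t"].to_numpy()
    breaks = np.flatnonzero(np.diff(t) > gap_max) + 1
    segments = np.split(np.arange(len(fixes)), breaks)
    tracks = []
    for seg in segments:
        if len(seg) < points_min:
            continue
        sub = fixes.iloc[seg]
        duration = sub["t"].iloc[-1] - sub["t"].iloc[0]
        if duration <= duration_min:
            continue
        tracks.append(Track(track_id=first_id + len(tracks), fixes=sub.reset_index(drop=True)))
    return tracks


def preprocess(
    raw: pd.DataFrame,
    projection="albers",
    speed_min: float = SPEED_MIN,
    vz_change_max: float = VZ_CHANGE_MAX,
    gap_max: float = GAP_MAX,
    duration_min: float = DURATION_MIN,
    points_min: int = POINTS_MIN,
) -> list[Track]:
    """Full pipeline: project, filter, segment one individual's record."""
    planar = project_fixes(raw, projection)
    filtered = filter_fixes(planar, speed_min, vz_change_max)
    return segment_tracks(filtered, gap_max, duration_min, points_min)


def write_tracks(path, tracks: list[Track]) -> None:
    """Write tracks as delimited text with a track_id column."""
    frames = []
    for tr in tracks:
        df = tr.fixes.copy()
        df.insert(0, "track_id", tr.track_id)
        frames.append(df)
    out = pd.concat(frames) if frames else pd.DataFrame(columns=["track_id", *FIX_COLUMNS])
    out.to_csv(path, index=False)


def read_tracks(path) -> list[Track]:
    """Read tracks written by :func:`write_tracks`."""
    df = pd.read_csv(path)
    return [
        Track(track_id=int(tid), fixes=sub.drop(columns="track_id").reset_index(drop=True))
        for tid, sub in df.groupby("track_id", sort=True)
    ]
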