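"""Scoring simulated ensembles against reference tracks, and risk maps.

Predictive skill is measured by the radial (3D) distance between each
simulated path and the reference track at every time lag from the
common start, pooled over paths (and over reference tracks when several
are scored).  Quartiles of that distribution are reported both in
meters and in rotor diameters (D = 130 m, a typical land-based turbine),
the unit curtailment decisions care about.  The comparison standard is
the constant-velocity baseline: a bird assumed to keep its initial
heading and velocity, which is what fielded detect-and-curtail systems
use today.

Validation windows are drawn from the annotated track pool: fixed-length
segments (default 3 min) with at least 75% of their points inside the
rotor-swept zone, so they resemble the calibration data.  Condition
subsets stack cumulative filters — windy (wind >= 5 m/s, turbines
likely spinning), + rotor-swept zone (AGL < 200 m), + soaring
(orographic updraft >= 0.75 m/s).

A collision-risk map is the normalized presence density of simulated
rotor-swept-zone flight: nearest-node counts of simulated states on the
domain lattice within a time-lag window, Gaussian-smoothed (250 m
default) and scaled to [0, 1] by the maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import InvalidInputError
from .terrain import write_ascii_grid

__all__ = [
    "ROTOR_DIAMETER",
    "ValidationResult",
    "RiskMap",
    "radial_distance_series",
    "constant_velocity_baseline",
    "select_validation_tracks",
    "condition_subset",
    "risk_map",
]

ROTOR_DIAMETER = 130.0  # m

CONDITIONS = ("all", "windy", "windy+rsz", "windy+rsz+soaring")
WINDY_MIN = 5.0     # m/s, inclusive
SOARING_MIN = 0.75  # m/s, inclusive
RSZ_CEILING = 200.0


@dataclass
class ValidationResult:
    """Pooled radial-distance samples per time lag."""

    distances: pd.DataFrame  # columns: lag, path_id, distance (m)
    condition: str = "all"
    rotor_diameter: float = ROTOR_DIAMETER

    def quartiles(self) -> pd.DataFrame:
        """Q1/Q2/Q3 per lag, in meters and rotor diameters."""
        rows = []
        for lag, sub in self.distances.groupby("lag"):
            q1, q2, q3 = np.percentile(sub["distance"], [25, 50, 75])
            rows.append(
                {
                    "lag": lag, "condition": self.condition,
                    "q1_m": q1, "q2_m": q2, "q3_m": q3,
                    "q1_D": q1 / self.rotor_diameter,
                    "q2_D": q2 / self.rotor_diameter,
                    "q3_D": q3 / self.rotor_diameter,
                    "n": len(sub),
                }
            )
        return pd.DataFrame(rows)

    def median_at(self, lag: float) -> float:
        sub = self.distances[self.distances["lag"] == lag]
        if len(sub) == 0:
            raise InvalidInputError(f"no distance samples at lag {lag}")
        return float(np.median(sub["distance"]))


def radial_distance_series(
    paths: pd.DataFrame, reference: pd.DataFrame, horizontal_only: bool = False
) -> ValidationResult:
    """3D distances between simulated paths and a reference track per lag.

    Both inputs must be on the same 1-s clock starting at lag 0;
    truncated paths contribute while alive.  ``horizontal_only`` drops
    the vertical component.
    """
    ref_t = reference["t"].to_numpy(dtype=float)
    ref_t = ref_t - ref_t[0]
    ref = reference.assign(lag=ref_t).set_index("lag")
    sim_lags = np.unique(paths["t"].to_numpy(dtype=float))
    if not np.all(np.isin(sim_lags, ref_t)):
        raise InvalidInputError("simulated and reference clocks do not align")
    merged = paths.rename(columns={"t": "lag"}).join(
        ref[["px", "py", "pz"]], on="lag", rsuffix="_ref"
    )
    dx = merged["px"] - merged["px_ref"]
    dy = merged["py"] - merged["py_ref"]
    if horizontal_only:
        dist = np.hypot(dx, dy)
    else:
        dist = np.sqrt(dx**2 + dy**2 + (merged["pz"] - merged["pz_ref"]) ** 2)
    out = pd.DataFrame(
        {"lag": merged["lag"], "path_id": merged["path_id"], "distance": dist}
    )
    return ValidationResult(distances=out.reset_index(drop=True))


def constant_velocity_baseline(start: pd.Series | dict, duration: float, T: float = 1.0) -> pd.DataFrame:
    """Straight-line 3D extrapolation of the initial velocity vector."""
    for c in ("vx", "vy", "vz"):
        if not np.isfinite(float(start[c])):
            raise InvalidInputError("start state velocity must be finite")
    t = np.arange(0.0, duration + T / 2, T)
    return pd.DataFrame(
        {
            "path_id": 0,
            "t": t,
            "px": float(start["px"]) + float(start["vx"]) * t,
            "py": float(start["py"]) + float(start["vy"]) * t,
            "pz": float(start["pz"]) + float(start["vz"]) * t,
        }
    )


def select_validation_tracks(
    tracks: Sequence[pd.DataFrame],
    n: int,
    duration: float = 180.0,
    rsz_fraction: float = 0.75,
    rng: np.random.Generator | int = 0,
) -> list[pd.DataFrame]:
    """Sample fixed-length validation windows from annotated tracks.

    Windows of exactly ``duration`` seconds (duration + 1 states at 1-s
    cadence) whose fraction of rotor-swept-zone points is at least
    ``rsz_fraction`` (inclusive) are eligible; ``n`` are drawn uniformly
    without replacement.  If fewer are eligible, all are returned with a
    warning.  Returned windows have their clock re-zeroed.
    """
    import warnings

    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    win = int(round(duration)) + 1
    eligible: list[tuple[int, int]] = []
    for ti, df in enumerate(tracks):
        if len(df) < win:
            continue
        rsz = df["rsz"].to_numpy(dtype=float)
        csum = np.concatenate([[0.0], np.cumsum(rsz)])
        frac = (csum[win:] - csum[:-win]) / win
        for si in np.flatnonzero(frac >= rsz_fraction):
            eligible.append((ti, int(si)))
    if len(eligible) < n:
        warnings.warn(
            f"only {len(eligible)} eligible validation windows (requested {n})"
        )
        chosen = eligible
    else:
        pick = rng.choice(len(eligible), size=n, replace=False)
        chosen = [eligible[i] for i in pick]
    out = []
    for ti, si in chosen:
        sub = tracks[ti].iloc[si : si + win].reset_index(drop=True).copy()
        sub["t"] = sub["t"] - sub["t"].iloc[0]
        out.append(sub)
    return out


def condition_subset(records: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Apply the cumulative windy / rotor-swept-zone / soaring filters."""
    if condition not in CONDITIONS:
        raise InvalidInputError(
            f"unknown condition {condition!r}; expected one of {CONDITIONS}"
        )
    mask = np.ones(len(records), dtype=bool)
    if condition != "all":
        mask &= records["w"].to_numpy(dtype=float) >= WINDY_MIN
    if condition in ("windy+rsz", "windy+rsz+soaring"):
        mask &= records["h_agl"].to_numpy(dtype=float) < RSZ_CEILING
    if condition == "windy+rsz+soaring":
        mask &= records["wo"].to_numpy(dtype=float) >= SOARING_MIN
    return records.loc[mask].reset_index(drop=True)


@dataclass
class RiskMap:
    """Normalized presence density of simulated rotor-swept-zone flight."""

    values: np.ndarray            # smoothed, in [0, 1]
    counts: np.ndarray            # raw nearest-node counts (conserved)
    origin_xy: tuple[float, float]
    spacing: float
    lag_window: tuple[float, float]
    rsz_only: bool

    def save_ascii(self, path) -> None:
        write_ascii_grid(path, self.values, self.origin_xy, self.spacing)

    def save_matrix(self, path) -> None:
        np.savetxt(path, self.values)


def risk_map(
    paths: pd.DataFrame,
    origin_xy: tuple[float, float],
    spacing: float,
    shape: tuple[int, int],
    rsz_only: bool = True,
    lag_window: tuple[float, float] = (0.0, 180.0),
    smoothing_radius: float = 250.0,
) -> RiskMap:
    """Build a collision-risk map from simulated path states.

    States with ``lag_window[0] <= t <= lag_window[1]`` (and in the
    rotor-swept zone when ``rsz_only``) are assigned to their nearest
    grid node; the counts are Gaussian-smoothed (sigma =
    ``smoothing_radius`` meters) and divided by the maximum.  All-zero
    counts yield an all-zero map.
    """
    lo, hi = lag_window
    if hi <= lo:
        raise InvalidInputError("empty time-lag window")
    t = paths["t"].to_numpy(dtype=float)
    mask = (t >= lo) & (t <= hi)
    if rsz_only:
        mask &= paths["h_agl"].to_numpy(dtype=float) < RSZ_CEILING
    sub = paths.loc[mask]
    ny, nx = shape
    counts = np.zeros((ny, nx))
    if len(sub):
        ix = np.rint((sub["px"].to_numpy(dtype=float) - origin_xy[0]) / spacing).astype(int)
        iy = np.rint((sub["py"].to_numpy(dtype=float) - origin_xy[1]) / spacing).astype(int)
        inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        np.add.at(counts, (iy[inside], ix[inside]), 1.0)
    if counts.max() > 0:
        smoothed = gaussian_filter(counts, sigma=smoothing_radius / spacing)
        values = smoothed / smoothed.max()
    else:
        values = counts.copy()
    return RiskMap(
        values=values,
        counts=counts,
        origin_xy=origin_xy,
        spacing=spacing,
        lag_window=lag_window,
        rsz_only=rsz_only,
    )
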