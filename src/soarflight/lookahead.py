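"""Look-ahead geometry, updraft differences, and the heading-rate law.

A soaring bird reacts to updraft availability it can see ahead, not just
under its wings.  The look-ahead region discretizes the line of sight
into points at bearings ``heading + alpha`` for alpha in {0, +-15, +-30,
+-60} deg and ranges d in {50, 100, 200, 300} m — 28 points, 24 of them
off-axis.  For each off-axis point the updraft difference

    dwo(alpha, d) = wo(alpha, d) - wo(0, d)

measures how much more lift sits at that bearing than dead ahead.  The
empirical law relating heading rate to these differences is

    omega = c_omega * dwo(alpha, d) / (d * alpha_rad)

i.e. the difference normalized by the arc length from the heading to
alpha at range d.  ``discover_relation`` reproduces the discovery
procedure: per (alpha, d), bin dwo between its 1st and 99th percentile,
equalize bin occupancy by random subsampling, take the median heading
rate per bin, fit a line through the bin medians, and finally collapse
the 24 slopes onto the single coefficient c_omega by regressing them on
1 / (d * alpha_rad) through the origin.

At simulation time the 24 normalized differences are averaged with equal
weight into the single covariate Lambda; a look-ahead point outside the
updraft field raises :class:`OutOfDomainError`, which the simulator
treats as path termination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, InvalidInputError, OutOfDomainError
from .terrain import UpdraftField, bilinear_sample

__all__ = [
    "LookaheadSpec",
    "RelationFit",
    "lookahead_points",
    "lookahead_deltas",
    "lookahead_covariate",
    "build_lookahead_table",
    "discover_relation",
]

DEFAULT_ANGLES = (0.0, 15.0, -15.0, 30.0, -30.0, 60.0, -60.0)
DEFAULT_DISTANCES = (50.0, 100.0, 200.0, 300.0)


@dataclass(frozen=True)
class LookaheadSpec:
    """Angle/distance lattice of the look-ahead region."""

    angles: tuple[float, ...] = DEFAULT_ANGLES
    distances: tuple[float, ...] = DEFAULT_DISTANCES

    def __post_init__(self):
        angs = set(self.angles)
        if any(-a not in angs for a in angs):
            raise InvalidInputError("look-ahead angle set must be symmetric about 0")
        if any(d <= 0 for d in self.distances):
            raise InvalidInputError("look-ahead distances must be positive")

    @property
    def n_points(self) -> int:
        return len(self.angles) * len(self.distances)

    @property
    def pairs(self) -> list[tuple[float, float]]:
        """All (alpha, d) pairs, on-axis included."""
        return [(a, d) for a in self.angles for d in self.distances]

    @property
    def offaxis_pairs(self) -> list[tuple[float, float]]:
        return [(a, d) for a in self.angles if a != 0.0 for d in self.distances]


def pair_column(alpha: float, d: float) -> str:
    """Canonical column name for the updraft difference of one pair."""
    return f"dwo_a{int(alpha):+d}_d{int(d)}"


def lookahead_points(px, py, heading, spec: LookaheadSpec = LookaheadSpec()) -> np.ndarray:
    """Planar positions of the look-ahead lattice.

    Supports scalar or array px/py/heading; returns shape
    ``(..., n_points, 2)`` ordered as ``spec.pairs``.  Bearings are
    measured clockwise from north, so the point for (alpha, d) is at
    ``(px + d sin(heading + alpha), py + d cos(heading + alpha))``.
    """
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    heading = np.asarray(heading, dtype=float)
    alphas = np.array([a for a, _ in spec.pairs])
    dists = np.array([d for _, d in spec.pairs])
    bearing = np.radians(heading[..., None] + alphas)
    x = px[..., None] + dists * np.sin(bearing)
    y = py[..., None] + dists * np.cos(bearing)
    return np.stack([x, y], axis=-1)


def lookahead_deltas(
    updraft: UpdraftField, px, py, heading, spec: LookaheadSpec = LookaheadSpec()
) -> np.ndarray:
    """Updraft differences dwo(alpha, d) over the off-axis pairs.

    Returns shape ``(..., n_offaxis)`` ordered as ``spec.offaxis_pairs``.
    Raises :class:`OutOfDomainError` if any of the lattice points falls
    outside the updraft field.
    """
    pts = lookahead_points(px, py, heading, spec)
    wo = updraft.sample(pts[..., 0], pts[..., 1])
    wo = np.asarray(wo)
    pairs = spec.pairs
    centre = {d: i for i, (a, d) in enumerate(pairs) if a == 0.0}
    off = [i for i, (a, _) in enumerate(pairs) if a != 0.0]
    ref = np.stack([wo[..., centre[d]] for _, d in spec.offaxis_pairs], axis=-1)
    return wo[..., off] - ref


def lookahead_covariate(
    updraft: UpdraftField, px, py, heading, spec: LookaheadSpec = LookaheadSpec()
):
    """The collapsed look-ahead covariate Lambda.

    Mean over the off-axis pairs of ``dwo(alpha, d) / (d * alpha_rad)``
    (alpha in radians, signed).  Positive Lambda means more lift
    clockwise of the current heading.
    """
    deltas = lookahead_deltas(updraft, px, py, heading, spec)
    norm = np.array([d * np.radians(a) for a, d in spec.offaxis_pairs])
    return np.mean(deltas / norm, axis=-1)


def build_lookahead_table(
    annotated_tracks,
    updraft: UpdraftField,
    spec: LookaheadSpec = LookaheadSpec(),
    rsz_only: bool = True,
) -> pd.DataFrame:
    """Pair per-point updraft differences with the next-step heading rate.

    For every annotated track, each record at time t_k contributes its 24
    dwo values (columns named by :func:`pair_column`) and the heading
    rate observed one second later (column ``omega_next``).  Records
    whose look-ahead lattice leaves the field are dropped, as are
    non-rotor-swept-zone records when ``rsz_only``.
    """
    if isinstance(annotated_tracks, pd.DataFrame):
        annotated_tracks = [annotated_tracks]
    frames = []
    cols = [pair_column(a, d) for a, d in spec.offaxis_pairs]
    for df in annotated_tracks:
        if len(df) < 2:
            continue
        px = df["px"].to_numpy(dtype=float)[:-1]
        py = df["py"].to_numpy(dtype=float)[:-1]
        heading = df["heading"].to_numpy(dtype=float)[:-1]
        omega_next = df["omega"].to_numpy(dtype=float)[1:]
        pts = lookahead_points(px, py, heading, spec)
        ok = np.all(updraft.contains(pts[..., 0], pts[..., 1]), axis=-1)
        if rsz_only and "rsz" in df:
            ok &= df["rsz"].to_numpy()[:-1]
        ok &= np.isfinite(omega_next)
        if not np.any(ok):
            continue
        deltas = lookahead_deltas(updraft, px[ok], py[ok], heading[ok], spec)
        sub = pd.DataFrame(deltas, columns=cols)
        sub["omega_next"] = omega_next[ok]
        frames.append(sub)
    if not frames:
        return pd.DataFrame(columns=[*cols, "omega_next"])
    return pd.concat(frames, ignore_index=True)


def add_lambda(
    df: pd.DataFrame,
    updraft: UpdraftField,
    spec: LookaheadSpec = LookaheadSpec(),
) -> pd.DataFrame:
    """Attach the collapsed covariate as a ``lam`` column to a track table.

    Rows whose look-ahead lattice leaves the updraft field get NaN (such
    rows are dropped by the calibration design builder).
    """
    px = df["px"].to_numpy(dtype=float)
    py = df["py"].to_numpy(dtype=float)
    heading = df["heading"].to_numpy(dtype=float)
    pts = lookahead_points(px, py, heading, spec)
    ok = np.all(updraft.contains(pts[..., 0], pts[..., 1]), axis=-1)
    lam = np.full(len(df), np.nan)
    if np.any(ok):
        lam[ok] = lookahead_covariate(updraft, px[ok], py[ok], heading[ok], spec)
    out = df.copy()
    out["lam"] = lam
    return out


@dataclass
class RelationFit:
    """Result of the look-ahead law discovery.

    ``slopes`` has one row per off-axis (alpha, d) pair: the fitted
    linear slope of median heading rate against dwo, the pair's
    normalization arc length d * alpha_rad, and the normalized slope
    (slope * d * alpha_rad) whose collapse onto a constant is the law.
    ``c_omega`` is the origin-constrained regression of slopes on
    1/(d * alpha_rad) — deg/s per (m/s / m rad).
    """

    spec: LookaheadSpec
    c_omega: float
    slopes: pd.DataFrame
    bins: pd.DataFrame = field(repr=False)
    n_bins: int = 0
    samples_per_bin: int = 0
    seed: int = 0

    @property
    def collapse_residuals(self) -> np.ndarray:
        """Relative deviation of each normalized slope from c_omega."""
        norm = self.slopes["normalized_slope"].to_numpy()
        return (norm - self.c_omega) / self.c_omega if self.c_omega != 0 else norm

    def to_dict(self) -> dict:
        return {
            "angles": list(self.spec.angles),
            "distances": list(self.spec.distances),
            "c_omega": self.c_omega,
            "n_bins": self.n_bins,
            "samples_per_bin": self.samples_per_bin,
            "seed": self.seed,
            "slopes": self.slopes.to_dict(orient="list"),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RelationFit":
        return cls(
            spec=LookaheadSpec(tuple(d["angles"]), tuple(d["distances"])),
            c_omega=float(d["c_omega"]),
            slopes=pd.DataFrame(d["slopes"]),
            bins=pd.DataFrame(),
            n_bins=int(d["n_bins"]),
            samples_per_bin=int(d["samples_per_bin"]),
            seed=int(d["seed"]),
        )


def _binned_medians(values, omega, n_bins, samples_per_bin, rng):
    """Equal-occupancy bin medians between the 1st and 99th percentile.

    Returns (centers, medians, used n_bins, used samples_per_bin) or
    None when no binning with >= 2 occupied bins exists.
    """
    lo, hi = np.percentile(values, [1.0, 99.0])
    if hi <= lo:
        return None
    span = (values >= lo) & (values <= hi)
    values = values[span]
    omega = omega[span]
    while n_bins >= 2:
        edges = np.linspace(lo, hi, n_bins + 1)
        idx = np.clip(np.searchsorted(edges, values, side="right") - 1, 0, n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins)
        if np.all(counts > 0):
            break
        n_bins -= 1
        warnings.warn(f"empty look-ahead bin; reducing to {n_bins} bins")
    else:
        return None
    take = int(counts.min()) if samples_per_bin is None else min(samples_per_bin, int(counts.min()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    medians = np.empty(n_bins)
    for b in range(n_bins):
        members = np.flatnonzero(idx == b)
        chosen = rng.choice(members, size=take, replace=False)
        medians[b] = np.median(omega[chosen])
    return centers, medians, n_bins, take


def discover_relation(
    records: pd.DataFrame,
    n_bins: int = 15,
    samples_per_bin: int | None = None,
    seed: int = 0,
    spec: LookaheadSpec = LookaheadSpec(),
    min_records: int = 1000,
    omega_col: str = "omega_next",
) -> RelationFit:
    """Run the binning/median/collapse discovery on a look-ahead table.

    ``records`` is the output of :func:`build_lookahead_table` (or any
    table with the pair columns and a heading-rate response).  Raises
    :class:`InsufficientDataError` below ``min_records`` usable rows.
    """
    records = records.dropna(subset=[omega_col])
    if len(records) < min_records:
        raise InsufficientDataError(
            f"{len(records)} usable records < required {min_records}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    bin_rows = []
    for alpha, d in spec.offaxis_pairs:
        col = pair_column(alpha, d)
        vals = records[col].to_numpy(dtype=float)
        om = records[omega_col].to_numpy(dtype=float)
        finite = np.isfinite(vals)
        res = _binned_medians(vals[finite], om[finite], n_bins, samples_per_bin, rng)
        if res is None:
            warnings.warn(f"no usable binning for pair ({alpha}, {d}); skipped")
            continue
        centers, medians, used_bins, used_take = res
        slope, intercept = np.polyfit(centers, medians, 1)
        arc = d * np.radians(alpha)
        rows.append(
            {
                "alpha": alpha,
                "d": d,
                "slope": slope,
                "intercept": intercept,
                "arc_length": arc,
                "normalized_slope": slope * arc,
                "n_bins": used_bins,
                "samples_per_bin": used_take,
            }
        )
        for c, m in zip(centers, medians):
            bin_rows.append({"alpha": alpha, "d": d, "bin_center": c, "median_omega": m})
    if not rows:
        raise InsufficientDataError("no (alpha, d) pair produced a usable binning")
    slopes = pd.DataFrame(rows)
    x = 1.0 / slopes["arc_length"].to_numpy()
    s = slopes["slope"].to_numpy()
    c_omega = float(np.sum(s * x) / np.sum(x * x))
    return RelationFit(
        spec=spec,
        c_omega=c_omega,
        slopes=slopes,
        bins=pd.DataFrame(bin_rows),
        n_bins=n_bins,
        samples_per_bin=samples_per_bin or 0,
        seed=seed,
    )
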