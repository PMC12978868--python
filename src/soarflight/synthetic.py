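"""Synthetic terrain, wind, truth tracks, and GPS-degraded telemetry.

The eagle telemetry the movement model was designed for is not publicly
distributable, so this module generates everything that data would have
provided, with known ground truth:

* parametric ridge terrain (Gaussian-profile ridges over a base
  elevation, plus smooth correlated noise) on a regular ~10-m lattice;
* a constant wind scenario (speed/direction at 80 m AGL);
* "truth" tracks generated by the package's own path simulator driven
  by a truth movement model with known weights and a known look-ahead
  coefficient c_omega;
* GPS degradation: variable-interval subsampling (discrete 3-15 s,
  median 6 s, chosen so segments usually survive the 10-s gap rule) and
  additive Gaussian position noise (2 m per horizontal axis, 6 m
  vertical), emitted in the raw-fix format with planar coordinates and
  the identity projection.

Calibration-grade truth tracks default to 7 min so their degraded fixes
can pass the 5-min/50-point track rules; 3-min windows are cut from the
processed tracks at validation time.

Every operation takes an explicit seed; identical seeds give identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .markov import CovariateSpec, MarkovModel, PredictorModel
from .simulate import Environment, SimConfig, simulate_paths
from .terrain import TerrainGrid, WindField, build_updraft_field, compute_slope_aspect
from scipy.ndimage import gaussian_filter

__all__ = [
    "Ridge",
    "SyntheticScenario",
    "make_terrain",
    "make_truth_model",
    "make_environment",
    "make_starts",
    "make_truth_tracks",
    "degrade_to_gps",
]

#: sampling-interval distribution (s -> probability): median 6 s, about 80%
#: of intervals at or under 6 s (the bulk-telemetry cadence), 2% above the
#: 10-s gap rule so multi-minute segments usually survive it
DEFAULT_INTERVALS = {
    3: 0.10, 4: 0.10, 5: 0.15, 6: 0.45, 7: 0.05,
    8: 0.05, 9: 0.04, 10: 0.04, 12: 0.01, 15: 0.01,
}


@dataclass(frozen=True)
class Ridge:
    """One Gaussian-profile ridge: height * exp(-dist^2 / (2 width^2))."""

    center_x: float
    height: float
    width: float
    axis: str = "ns"  # "ns": runs north-south (center_x is its x); "ew": east-west


@dataclass(frozen=True)
class SyntheticScenario:
    """Study conditions for the synthetic end-to-end experiments."""

    domain_size: tuple[float, float] = (8000.0, 16000.0)  # m (x, y)
    spacing: float = 10.0
    base_elevation: float = 300.0
    ridges: tuple[Ridge, ...] = (Ridge(center_x=4000.0, height=250.0, width=350.0),)
    noise_amplitude: float = 60.0     # m, ridgeline relief (summits/saddles)
    noise_scale: float = 700.0        # m, relief correlation length
    wind_speed: float = 10.0          # m/s at 80 m AGL
    wind_direction: float = 270.0     # deg, "from" convention (westerly)
    c_omega: float = 30.0             # truth look-ahead coefficient
    gps_noise: dict = field(default_factory=lambda: {"horizontal": 2.0, "vertical": 6.0})
    intervals: dict = field(default_factory=lambda: dict(DEFAULT_INTERVALS))
    n_tracks: int = 200
    duration: float = 420.0           # s per calibration truth track
    seed: int = 0


def make_discovery_records(
    n: int,
    c_omega: float = 30.0,
    seed: int = 0,
    lam_scale: float = 0.004,
    pair_noise_frac: float = 0.1,
    omega_noise: float = 0.3,
) -> "pd.DataFrame":
    """Self-generated records for look-ahead law recovery checks.

    Each record carries one shared look-ahead gradient Lambda; every
    off-axis pair's updraft difference is Lambda times its arc length
    (plus fractional noise), and the next-step heading rate follows the
    collapsed law omega = c_omega * Lambda + noise.  On such records the
    per-pair slope of omega against dwo is exactly c_omega / arc, so the
    discovery procedure should collapse back to c_omega.
    """
    from .lookahead import LookaheadSpec, pair_column

    spec = LookaheadSpec()
    rng = np.random.default_rng(seed)
    lam = rng.normal(0.0, lam_scale, n)
    cols = {}
    for a, d in spec.offaxis_pairs:
        arc = d * np.radians(a)
        cols[pair_column(a, d)] = lam * arc + rng.normal(
            0.0, pair_noise_frac * lam_scale * abs(arc), n
        )
    cols["omega_next"] = c_omega * lam + rng.normal(0.0, omega_noise, n)
    return pd.DataFrame(cols)


def make_terrain(scenario: SyntheticScenario, seed: int | None = None) -> TerrainGrid:
    """Deterministic parametric terrain with slope/aspect computed."""
    seed = scenario.seed if seed is None else seed
    sx, sy = scenario.domain_size
    nx = int(round(sx / scenario.spacing)) + 1
    ny = int(round(sy / scenario.spacing)) + 1
    x = scenario.spacing * np.arange(nx)
    y = scenario.spacing * np.arange(ny)
    xg, yg = np.meshgrid(x, y)
    z = np.full((ny, nx), scenario.base_elevation)
    for r in scenario.ridges:
        dist = (xg - r.center_x) if r.axis == "ns" else (yg - r.center_x)
        z = z + r.height * np.exp(-(dist**2) / (2.0 * r.width**2))
    if scenario.noise_amplitude > 0:
        rng = np.random.default_rng(seed)
        rough = rng.standard_normal((ny, nx))
        rough = gaussian_filter(rough, sigma=scenario.noise_scale / scenario.spacing)
        sd = rough.std()
        if sd > 0:
            z = z + scenario.noise_amplitude * rough / sd
    return compute_slope_aspect(
        TerrainGrid(origin_xy=(0.0, 0.0), spacing=scenario.spacing, elevation=z)
    )


def make_truth_model(scenario: SyntheticScenario) -> MarkovModel:
    """The generating movement model with known weights.

    Weight choices (units follow the covariates): horizontal speed is a
    stable autoregression with stationary mean around 11 m/s, nudged by
    tailwind and updraft; vertical speed seeks an equilibrium altitude
    of roughly 90 m AGL over strong updraft and sinks elsewhere; heading
    rate is the pure look-ahead law — c_omega times the collapsed
    covariate plus Gaussian noise, with no self-persistence and no wind
    terms, the cleanest expression of the steering relation the
    discovery procedure targets.  Noise strengths are homoscedastic
    apart from a small updraft term on vertical speed.
    """
    def pm(name, use_lam, beta_mean, beta_err, sigma_min):
        spec = CovariateSpec(predictor=name, use_lookahead=use_lam)
        return PredictorModel(
            predictor=name,
            spec=spec,
            beta_mean=np.array(beta_mean),
            beta_err=np.array(beta_err),
            sigma_min=sigma_min,
            error_scale="sigma",
        )

    # column order: intercept, wc, wt, wo, h_agl, lag5, lag10, lag30[, lam]
    preds = {
        "vz": pm(
            "vz", False,
            [-0.10, 0.0, 0.0, 0.12, -0.0015, 0.45, 0.20, 0.05],
            [0.30, 0.0, 0.0, 0.05, 0.0, 0.0, 0.0, 0.0],
            0.05,
        ),
        "vh": pm(
            "vh", False,
            [1.00, 0.0, 0.02, 0.08, 0.0, 0.55, 0.25, 0.10],
            [0.40, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
            0.05,
        ),
        "omega": pm(
            "omega", True,
            [0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, scenario.c_omega],
            [1.20, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
            0.05,
        ),
    }
    return MarkovModel(
        predictors=preds,
        c_omega=scenario.c_omega,
        T=1.0,
        metadata={"truth": True, "scenario_seed": scenario.seed},
    )


def make_environment(scenario: SyntheticScenario, terrain: TerrainGrid | None = None) -> Environment:
    terrain = make_terrain(scenario) if terrain is None else terrain
    wind = WindField(speed=scenario.wind_speed, direction=scenario.wind_direction)
    updraft = build_updraft_field(terrain, wind)
    return Environment(terrain=terrain, wind=wind, updraft=updraft)


def make_starts(
    env: Environment,
    n: int,
    rng: np.random.Generator,
    agl_range: tuple[float, float] = (60.0, 150.0),
    updraft_quantile: float = 0.85,
    margin: float = 1000.0,
) -> list[dict]:
    """Start states in the rotor-swept zone over windward (high-updraft) slopes.

    Positions are sampled from grid nodes whose smoothed updraft exceeds
    the given quantile, at least ``margin`` meters from the domain edge;
    altitudes sit ``agl_range`` above ground; headings are uniform;
    speeds are drawn near cruising.  Returned dicts are deterministic
    start "posteriors" (zero variance) for the simulator.
    """
    up = env.updraft
    ny, nx = up.values.shape
    xs = up.origin_xy[0] + up.spacing * np.arange(nx)
    ys = up.origin_xy[1] + up.spacing * np.arange(ny)
    xmin, xmax = xs[0] + margin, xs[-1] - margin
    ymin, ymax = ys[0] + margin, ys[-1] - margin
    xg, yg = np.meshgrid(xs, ys)
    box = (xg >= xmin) & (xg <= xmax) & (yg >= ymin) & (yg <= ymax)
    if not np.any(box):
        raise ValueError("margin leaves no interior start region")
    thresh = np.quantile(up.values[box], updraft_quantile)
    ok = box & (up.values >= thresh)
    cand = np.flatnonzero(ok.ravel())
    if cand.size == 0:
        raise ValueError("no candidate start nodes; loosen quantile or margin")
    pick = rng.choice(cand, size=n, replace=True)
    iy, ix = np.unravel_index(pick, up.values.shape)
    starts = []
    for j in range(n):
        px = float(xs[ix[j]])
        py = float(ys[iy[j]])
        hg = float(env.terrain.elevation[iy[j], ix[j]])
        heading = float(rng.uniform(0.0, 360.0))
        vh = float(np.clip(rng.normal(11.0, 1.5), 6.0, 16.0))
        th = np.radians(heading)
        starts.append(
            {
                "px": px, "py": py,
                "pz": hg + float(rng.uniform(*agl_range)),
                "vx": vh * np.sin(th), "vy": vh * np.cos(th),
                "vz": float(rng.normal(0.0, 0.3)),
                "ax": 0.0, "ay": 0.0, "az": 0.0,
            }
        )
    return starts


def make_truth_tracks(
    scenario: SyntheticScenario,
    env: Environment | None = None,
    model: MarkovModel | None = None,
    n_tracks: int | None = None,
    duration: float | None = None,
    starts: list[dict] | None = None,
) -> list[pd.DataFrame]:
    """Noiseless 1-s truth tracks generated by the path simulator.

    Returns one DataFrame per track (t, px, py, pz, heading, vh, vz,
    omega, h_agl).  Tracks whose look-ahead lattice exits the domain end
    early and are kept as-is.
    """
    env = make_environment(scenario) if env is None else env
    model = make_truth_model(scenario) if model is None else model
    n_tracks = scenario.n_tracks if n_tracks is None else n_tracks
    duration = scenario.duration if duration is None else duration
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1]))
    if starts is None:
        starts = make_starts(env, n_tracks, rng)
    cfg = SimConfig(duration=duration, n_paths=n_tracks, seed=scenario.seed + 2)
    paths = simulate_paths(starts, env, model, cfg)
    return [
        sub.drop(columns="path_id").reset_index(drop=True)
        for _, sub in paths.groupby("path_id", sort=True)
    ]


def degrade_to_gps(
    truth_tracks: list[pd.DataFrame],
    scenario: SyntheticScenario,
    seed: int | None = None,
) -> list[pd.DataFrame]:
    """Emulate the GPS observation process on truth tracks.

    Inter-fix intervals are drawn from the scenario's discrete
    distribution; independent Gaussian noise (2 m per horizontal axis,
    6 m vertical by default) corrupts the positions.  Output is one
    raw-fix table per track (t, lon, lat, alt_msl) carrying planar
    meters, to be ingested with the identity projection.
    """
    seed = scenario.seed + 3 if seed is None else seed
    rng = np.random.default_rng(seed)
    vals = np.array(sorted(scenario.intervals))
    probs = np.array([scenario.intervals[v] for v in vals], dtype=float)
    probs = probs / probs.sum()
    sh = scenario.gps_noise["horizontal"]
    sv = scenario.gps_noise["vertical"]
    out = []
    for tr in truth_tracks:
        t = tr["t"].to_numpy(dtype=float)
        n = len(t)
        idx = [0]
        while True:
            nxt = idx[-1] + int(rng.choice(vals, p=probs))
            if nxt >= n:
                break
            idx.append(nxt)
        idx = np.array(idx)
        fixes = pd.DataFrame(
            {
                "t": t[idx],
                "lon": tr["px"].to_numpy(dtype=float)[idx] + sh * rng.standard_normal(len(idx)),
                "lat": tr["py"].to_numpy(dtype=float)[idx] + sh * rng.standard_normal(len(idx)),
                "alt_msl": tr["pz"].to_numpy(dtype=float)[idx] + sv * rng.standard_normal(len(idx)),
            }
        )
        out.append(fixes)
    return out
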