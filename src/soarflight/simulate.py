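"""Stochastic 3D path simulation from a calibrated movement model.

Starting from an uncertain initial state (the smoothed posterior at the
first second of a reference track), each path evolves at T = 1 s: the
covariates at the current location (tailwind, crosswind, orographic
updraft, altitude AGL, 30 s of predictor history, and the collapsed
look-ahead covariate for heading rate) feed the calibrated mean and
error models, new predictor values are drawn from the resulting
Gaussians, and position/heading advance as

    p_x += T * vh * sin(theta),  p_y += T * vh * cos(theta),
    p_z += T * vz,               theta += T * omega,

with the pre-step heading steering the displacement and the freshly
drawn predictors applied over the step.  A path terminates early when
any of its 28 look-ahead points leaves the domain (the bird can no
longer "see" inside the modelled world).

Each path draws from its own random substream spawned from the ensemble
seed, so path i is bit-reproducible regardless of how many paths run or
when the others terminate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .lookahead import LookaheadSpec, lookahead_covariate, lookahead_points
from .markov import MarkovModel, PREDICTORS
from .terrain import TerrainGrid, UpdraftField, WindField, bilinear_sample

__all__ = ["SimConfig", "Environment", "sample_initial_state", "step", "simulate_paths"]

PATH_COLUMNS = ["path_id", "t", "px", "py", "pz", "heading", "vh", "vz", "omega", "h_agl"]


@dataclass(frozen=True)
class Environment:
    """Static terrain/wind/updraft bundle a simulation runs over."""

    terrain: TerrainGrid
    wind: WindField
    updraft: UpdraftField
    lookahead: LookaheadSpec = LookaheadSpec()
    wind_time: float = 0.0


@dataclass(frozen=True)
class SimConfig:
    T: float = 1.0
    duration: float = 180.0
    n_paths: int = 100
    seed: int = 0
    vh_floor: float = 0.1  # m/s; keeps heading dynamics defined
    # generous physical envelopes for a large soaring raptor; they keep a
    # marginally unstable calibrated autoregression from diverging
    vz_bound: float = 20.0     # m/s
    vh_bound: float = 40.0     # m/s
    omega_bound: float = 60.0  # deg/s

    def __post_init__(self):
        if self.T <= 0:
            raise InvalidInputError("time step must be positive")
        if self.n_paths < 1:
            raise InvalidInputError("n_paths must be at least 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.T))


def sample_initial_state(posterior: pd.Series | dict, rng: np.random.Generator) -> dict:
    """Draw one initial kinematic state from a smoothed-posterior row.

    ``posterior`` carries means px..az and variances var_px..var_az (a
    row of :func:`soarflight.smoother.smooth_track` output).  Each
    component is drawn independently; zero or missing variances are
    treated as deterministic.  Heading, horizontal speed, and heading
    rate derive from the sampled velocities/accelerations.
    """
    comp = {}
    for c in ("px", "py", "pz", "vx", "vy", "vz", "ax", "ay", "az"):
        mean = float(posterior[c])
        var = float(posterior.get(f"var_{c}", 0.0) or 0.0)
        comp[c] = mean + np.sqrt(var) * rng.standard_normal() if var > 0 else mean
    vh = float(np.hypot(comp["vx"], comp["vy"]))
    heading = float(np.degrees(np.arctan2(comp["vx"], comp["vy"])) % 360.0)
    omega = (
        float(np.degrees((comp["ax"] * comp["vy"] - comp["ay"] * comp["vx"]) / vh**2))
        if vh > 0
        else 0.0
    )
    return {
        "px": comp["px"], "py": comp["py"], "pz": comp["pz"],
        "heading": heading, "vh": vh, "vz": comp["vz"], "omega": omega,
    }


class _Ensemble:
    """Vectorized lockstep state for n paths (internal)."""

    def __init__(self, states: list[dict], model: MarkovModel, rngs):
        n = len(states)
        self.n = n
        self.rngs = rngs
        self.px = np.array([s["px"] for s in states])
        self.py = np.array([s["py"] for s in states])
        self.pz = np.array([s["pz"] for s in states])
        self.heading = np.array([s["heading"] for s in states])
        self.alive = np.ones(n, dtype=bool)
        max_lag = max(max(model.predictors[p].spec.lags) for p in PREDICTORS)
        self.max_lag = max_lag
        # buffers[p][:, 0] is the current value, [:, lag] the value lag steps back
        self.buffers = {
            p: np.tile(np.array([[s[p]] for s in states]), (1, max_lag + 1))
            for p in PREDICTORS
        }

    def current(self, p: str) -> np.ndarray:
        return self.buffers[p][:, 0]

    def push(self, p: str, values: np.ndarray, mask: np.ndarray) -> None:
        buf = self.buffers[p]
        buf[mask] = np.roll(buf[mask], 1, axis=1)
        buf[mask, 0] = values[mask]


def _covariates(ens: _Ensemble, env: Environment, mask: np.ndarray):
    """Covariate dict at the current location for alive paths (masked)."""
    from .terrain import wind_components

    px, py = ens.px[mask], ens.py[mask]
    w, phi_w = env.wind.sample(px, py, env.wind_time) if env.wind.is_gridded else env.wind.sample(px, py)
    wt, wc = wind_components(w, phi_w, ens.heading[mask])
    hg = bilinear_sample(env.terrain.elevation, px, py, env.terrain.origin_xy, env.terrain.spacing)
    wo = env.updraft.sample(px, py)
    lam = lookahead_covariate(env.updraft, px, py, ens.heading[mask], env.lookahead)
    cov = {
        "intercept": np.ones(mask.sum()),
        "wc": np.atleast_1d(wc),
        "wt": np.atleast_1d(wt),
        "wo": np.atleast_1d(wo),
        "h_agl": ens.pz[mask] - np.atleast_1d(hg),
        "lam": np.atleast_1d(lam),
    }
    return cov


def _lookahead_alive(ens: _Ensemble, env: Environment) -> np.ndarray:
    """Paths whose position and full look-ahead lattice are in the domain."""
    pts = lookahead_points(ens.px, ens.py, ens.heading, env.lookahead)
    ok = np.all(env.updraft.contains(pts[..., 0], pts[..., 1]), axis=-1)
    return ok & env.updraft.contains(ens.px, ens.py)


def _advance(ens: _Ensemble, env: Environment, model: MarkovModel, cfg: SimConfig, mask: np.ndarray):
    """One lockstep advance of the masked paths."""
    cov = _covariates(ens, env, mask)
    draws = {}
    idx = np.flatnonzero(mask)
    for p in PREDICTORS:
        pm = model.predictors[p]
        cols_mean = pm.spec.mean_columns
        cols_err = pm.spec.error_columns

        def col(c):
            if c.startswith(f"{p}_lag"):
                lag = int(c.rsplit("lag", 1)[1])
                return ens.buffers[p][mask, lag]
            return cov[c]

        Xm = np.column_stack([col(c) for c in cols_mean])
        Xe = np.column_stack([col(c) for c in cols_err])
        mean = Xm @ pm.beta_mean
        sig = Xe @ pm.beta_err
        if pm.error_scale == "sigma2":
            sig = np.sqrt(np.maximum(sig, 0.0))
        sig = np.maximum(sig, pm.sigma_min)
        eps = np.array([ens.rngs[i].standard_normal() for i in idx])
        draws[p] = mean + sig * eps
    draws["vh"] = np.clip(draws["vh"], cfg.vh_floor, cfg.vh_bound)
    draws["vz"] = np.clip(draws["vz"], -cfg.vz_bound, cfg.vz_bound)
    draws["omega"] = np.clip(draws["omega"], -cfg.omega_bound, cfg.omega_bound)

    th = np.radians(ens.heading[mask])
    ens.px[mask] += cfg.T * draws["vh"] * np.sin(th)
    ens.py[mask] += cfg.T * draws["vh"] * np.cos(th)
    ens.pz[mask] += cfg.T * draws["vz"]
    ens.heading[mask] = (ens.heading[mask] + cfg.T * draws["omega"]) % 360.0
    for p in PREDICTORS:
        full = np.zeros(ens.n)
        full[mask] = draws[p]
        ens.push(p, full, mask)


def step(
    state: dict,
    env: Environment,
    model: MarkovModel,
    rng: np.random.Generator,
    cfg: SimConfig = SimConfig(n_paths=1),
    buffers: dict | None = None,
) -> dict | None:
    """Advance a single path state by one time step.

    ``state`` is a dict with px, py, pz, heading, vh, vz, omega (as from
    :func:`sample_initial_state`).  Returns the new state dict, or
    ``None`` when a look-ahead point left the domain (termination).
    ``buffers`` optionally carries lag history between calls (arrays of
    shape (1, max_lag + 1)); without it the history is seeded constant
    from the current state.
    """
    ens = _Ensemble([state], model, [rng])
    if buffers is not None:
        ens.buffers = buffers
    if not _lookahead_alive(ens, env)[0]:
        return None
    _advance(ens, env, model, cfg, np.ones(1, dtype=bool))
    hg = bilinear_sample(env.terrain.elevation, ens.px[0], ens.py[0], env.terrain.origin_xy, env.terrain.spacing)
    out = {
        "px": float(ens.px[0]), "py": float(ens.py[0]), "pz": float(ens.pz[0]),
        "heading": float(ens.heading[0]),
        "vh": float(ens.current("vh")[0]),
        "vz": float(ens.current("vz")[0]),
        "omega": float(ens.current("omega")[0]),
        "h_agl": float(ens.pz[0] - hg),
        "buffers": ens.buffers,
    }
    return out


def simulate_paths(
    start: pd.Series | dict,
    env: Environment,
    model: MarkovModel,
    config: SimConfig = SimConfig(),
) -> pd.DataFrame:
    """Simulate an ensemble of stochastic paths from one start posterior.

    Returns a long DataFrame (path_id, t, px, py, pz, heading, vh, vz,
    omega, h_agl) with one row per alive path per second, including the
    initial state at t = 0.  Paths are advanced in lockstep but draw
    from per-path substreams of ``config.seed``; a path whose look-ahead
    lattice exits the domain stops contributing rows.  If the start
    state's own lattice is already outside, the result is empty.

    ``start`` may also be a sequence of ``n_paths`` posteriors, one per
    path (used e.g. to generate independent truth tracks in one run).
    """
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_paths)
    rngs = [np.random.default_rng(s) for s in seeds]
    if isinstance(start, (list, tuple)):
        if len(start) != config.n_paths:
            raise InvalidInputError("need one start posterior per path")
        states = [sample_initial_state(start[i], rngs[i]) for i in range(config.n_paths)]
    else:
        states = [sample_initial_state(start, rngs[i]) for i in range(config.n_paths)]
    ens = _Ensemble(states, model, rngs)

    records = []

    def record(t: float, mask: np.ndarray):
        hg = bilinear_sample(
            env.terrain.elevation, ens.px[mask], ens.py[mask],
            env.terrain.origin_xy, env.terrain.spacing,
        )
        ids = np.flatnonzero(mask)
        records.append(
            pd.DataFrame(
                {
                    "path_id": ids,
                    "t": t,
                    "px": ens.px[mask], "py": ens.py[mask], "pz": ens.pz[mask],
                    "heading": ens.heading[mask],
                    "vh": ens.current("vh")[mask],
                    "vz": ens.current("vz")[mask],
                    "omega": ens.current("omega")[mask],
                    "h_agl": ens.pz[mask] - np.atleast_1d(hg),
                }
            )
        )

    ens.alive &= env.updraft.contains(ens.px, ens.py)
    ens.alive &= _lookahead_alive(ens, env)
    if not np.any(ens.alive):
        return pd.DataFrame(columns=PATH_COLUMNS)
    record(0.0, ens.alive)
    for k in range(config.n_steps):
        ens.alive &= _lookahead_alive(ens, env)
        if not np.any(ens.alive):
            break
        _advance(ens, env, model, config, ens.alive)
        record((k + 1) * config.T, ens.alive)
    out = pd.concat(records, ignore_index=True)
    return out.sort_values(["path_id", "t"], kind="stable").reset_index(drop=True)


def write_paths(path, paths: pd.DataFrame) -> None:
    paths.to_csv(path, index=False)


def read_paths(path) -> pd.DataFrame:
    return pd.read_csv(path)
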