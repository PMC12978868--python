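import numpy as np
import pandas as pd
import pytest

from soarflight import TerrainGrid, WindField, compute_slope_aspect, build_updraft_field
from soarflight.simulate import Environment


@pytest.fixture
def flat_terrain():
    """Flat 2 km x 2 km grid at 100 m MSL, 20 m spacing."""
    z = np.full((101, 101), 100.0)
    return compute_slope_aspect(TerrainGrid(origin_xy=(0.0, 0.0), spacing=20.0, elevation=z))


@pytest.fixture
def ridge_terrain():
    """North-south Gaussian ridge (200 m high, 300 m wide) in a 4x4 km box."""
    spacing = 20.0
    n = 201
    x = spacing * np.arange(n)
    z = 100.0 + 200.0 * np.exp(-((x - 2000.0) ** 2) / (2 * 300.0**2))
    elev = np.tile(z, (n, 1))
    return compute_slope_aspect(TerrainGrid(origin_xy=(0.0, 0.0), spacing=spacing, elevation=elev))


@pytest.fixture
def ridge_env(ridge_terrain):
    """Ridge terrain under a steady 10 m/s westerly wind."""
    wind = WindField(speed=10.0, direction=270.0)
    updraft = build_updraft_field(ridge_terrain, wind)
    return Environment(terrain=ridge_terrain, wind=wind, updraft=updraft)


@pytest.fixture
def flat_env(flat_terrain):
    wind = WindField(speed=8.0, direction=270.0)
    updraft = build_updraft_field(flat_terrain, wind)
    return Environment(terrain=flat_terrain, wind=wind, updraft=updraft)


def constant_velocity_fixes(duration=360, dt=1.0, vx=10.0, vy=0.0, vz=0.0, pz0=150.0):
    t = np.arange(0.0, duration, dt)
    return pd.DataFrame({"t": t, "px": vx * t, "py": vy * t, "pz": pz0 + vz * t})
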