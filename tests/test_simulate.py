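import numpy as np
import pandas as pd
import pytest

from soarflight import CovariateSpec, MarkovModel, SimConfig, sample_initial_state, simulate_paths
from soarflight.markov import PredictorModel
from soarflight.simulate import step


def toy_model(vz=0.0, vh=10.0, omega=0.0, c_omega=0.0, lag5=0.0, sigma=1e-12):
    """Near-deterministic model: each predictor pinned at a constant via the
    intercept (optionally with a lag-5 term or the look-ahead covariate)."""
    def pm(name, const, use_lam=False, extra_lam=0.0):
        spec = CovariateSpec(predictor=name, use_lookahead=use_lam)
        beta = np.zeros(len(spec.mean_columns))
        beta[0] = const
        if lag5 and name == "vh":
            beta[spec.mean_columns.index("vh_lag5")] = lag5
        if use_lam:
            beta[spec.mean_columns.index("lam")] = extra_lam
        err = np.zeros(len(spec.error_columns))
        err[0] = sigma
        return PredictorModel(name, spec, beta, err, sigma_min=max(sigma, 1e-12))

    return MarkovModel(
        predictors={
            "vz": pm("vz", vz),
            "vh": pm("vh", vh),
            "omega": pm("omega", omega, use_lam=True, extra_lam=c_omega),
        },
        c_omega=c_omega,
    )


def _posterior(px=1000.0, py=1000.0, pz=250.0, vx=0.0, vy=10.0, vz=0.0, **var):
    base = {"px": px, "py": py, "pz": pz, "vx": vx, "vy": vy, "vz": vz,
            "ax": 0.0, "ay": 0.0, "az": 0.0}
    base.update({f"var_{k}": 0.0 for k in list(base)})
    base.update(var)
    return pd.Series(base)


class TestInitialState:
    def test_zero_variance_returns_posterior_mean(self):
        s = sample_initial_state(_posterior(vx=3.0, vy=4.0), np.random.default_rng(0))
        assert s["px"] == 1000.0 and s["vh"] == pytest.approx(5.0)
        assert s["heading"] == pytest.approx(np.degrees(np.arctan2(3, 4)))

    def test_fixed_seed_reproducible(self):
        p = _posterior(var_px=25.0, var_vy=4.0)
        s1 = sample_initial_state(p, np.random.default_rng(42))
        s2 = sample_initial_state(p, np.random.default_rng(42))
        assert s1 == s2

    def test_monte_carlo_mean_converges_to_posterior_mean(self):
        p = _posterior(var_px=100.0)
        rng = np.random.default_rng(1)
        draws = np.array([sample_initial_state(p, rng)["px"] for _ in range(10_000)])
        se = 10.0 / np.sqrt(10_000)
        assert abs(draws.mean() - 1000.0) < 3 * se


class TestStep:
    def test_eastward_step_moves_east_only(self, flat_env):
        model = toy_model(vh=10.0)
        s = {"px": 1000.0, "py": 1000.0, "pz": 250.0, "heading": 90.0,
             "vh": 10.0, "vz": 0.0, "omega": 0.0}
        out = step(s, flat_env, model, np.random.default_rng(0))
        assert out["px"] == pytest.approx(1010.0)
        assert out["py"] == pytest.approx(1000.0)

    def test_descent_rate_applied(self, flat_env):
        model = toy_model(vz=-1.0, vh=10.0)
        s = {"px": 1000.0, "py": 1000.0, "pz": 250.0, "heading": 0.0,
             "vh": 10.0, "vz": -1.0, "omega": 0.0}
        out = step(s, flat_env, model, np.random.default_rng(0))
        assert out["pz"] == pytest.approx(249.0)

    def test_lookahead_exit_signals_termination(self, flat_env):
        model = toy_model()
        s = {"px": 100.0, "py": 1000.0, "pz": 250.0, "heading": 270.0,
             "vh": 10.0, "vz": 0.0, "omega": 0.0}  # 300-m lattice exits west
        assert step(s, flat_env, model, np.random.default_rng(0)) is None


class TestPathEnsembles:
    def test_circular_motion_closure(self, flat_env):
        """Constant heading rate traces a closed regular polygon: 40 steps of
        9 deg/s sweep a full turn; closure error stays under 2% of the
        radius vh / omega_rad."""
        model = toy_model(vh=12.0, omega=9.0)
        start = _posterior(vy=12.0)
        paths = simulate_paths(start, flat_env, model,
                               SimConfig(n_paths=1, duration=40.0, seed=0))
        p = paths[paths["path_id"] == 0]
        radius = 12.0 / np.radians(9.0)
        closure = np.hypot(p["px"].iloc[-1] - p["px"].iloc[0],
                           p["py"].iloc[-1] - p["py"].iloc[0])
        assert closure < 0.02 * radius

    def test_step_displacement_equals_vh_T(self, flat_env):
        model = toy_model(vh=11.0, omega=5.0)
        paths = simulate_paths(_posterior(vy=11.0), flat_env, model,
                               SimConfig(n_paths=1, duration=30.0, seed=0))
        p = paths[paths["path_id"] == 0]
        steps = np.hypot(np.diff(p["px"]), np.diff(p["py"]))
        assert np.allclose(steps, p["vh"].to_numpy()[1:] * 1.0, rtol=1e-9)

    def test_bookkeeping_all_paths_full_length(self, flat_env):
        model = toy_model(vh=2.0)
        paths = simulate_paths(_posterior(vy=2.0), flat_env, model,
                               SimConfig(n_paths=20, duration=30.0, seed=3))
        counts = paths.groupby("path_id").size()
        assert len(counts) == 20 and set(counts) == {31}

    def test_same_seed_bit_identical(self, flat_env):
        model = toy_model(vh=10.0, sigma=0.5)
        cfg = SimConfig(n_paths=5, duration=20.0, seed=9)
        p1 = simulate_paths(_posterior(var_px=4.0), flat_env, model, cfg)
        p2 = simulate_paths(_posterior(var_px=4.0), flat_env, model, cfg)
        pd.testing.assert_frame_equal(p1, p2)

    def test_path_reproducible_regardless_of_ensemble_size(self, flat_env):
        """Path 0 draws from its own substream, so adding more paths does
        not change it."""
        model = toy_model(vh=10.0, sigma=0.5)
        p1 = simulate_paths(_posterior(var_px=4.0), flat_env, model,
                            SimConfig(n_paths=1, duration=20.0, seed=9))
        p8 = simulate_paths(_posterior(var_px=4.0), flat_env, model,
                            SimConfig(n_paths=8, duration=20.0, seed=9))
        pd.testing.assert_frame_equal(p1, p8[p8["path_id"] == 0].reset_index(drop=True))

    def test_start_heading_outward_terminates_quickly(self, flat_env):
        model = toy_model(vh=10.0)
        start = _posterior(px=450.0, py=1000.0, vx=-10.0, vy=0.0)  # 450 m from west edge
        paths = simulate_paths(start, flat_env, model,
                               SimConfig(n_paths=1, duration=60.0, seed=0))
        # lattice reaches 300 m ahead: terminates within ~15 steps
        assert paths["t"].max() <= 16.0

    def test_start_lattice_outside_gives_empty_result(self, flat_env):
        start = _posterior(px=100.0, py=1000.0, vx=-10.0, vy=0.0)
        paths = simulate_paths(start, flat_env, toy_model(),
                               SimConfig(n_paths=3, duration=10.0, seed=0))
        assert len(paths) == 0

    def test_stationary_variance_of_induced_autoregression(self, flat_env):
        """With a pure lag-5 autoregression on vh, the simulated stationary
        variance matches sigma^2 / (1 - a^2) within Monte-Carlo error."""
        a, sigma = 0.6, 0.3
        model = toy_model(vh=10.0 * (1 - a), lag5=a, sigma=sigma)
        paths = simulate_paths(_posterior(px=1000, py=1000, vy=10.0), flat_env, model,
                               SimConfig(n_paths=30, duration=60.0, seed=5,
                                         vh_floor=0.0))
        vh = paths[paths["t"] > 30]["vh"].to_numpy()
        expected = sigma**2 / (1 - a**2)
        assert np.var(vh) == pytest.approx(expected, rel=0.25)

    def test_paths_concentrate_on_windward_side(self, ridge_env):
        """Over a ridge in crosswind, a look-ahead steering model occupies
        the windward (updraft) side more than a no-look-ahead ablation."""
        def occupancy_ratio(c_omega):
            model = toy_model(vh=10.0, c_omega=c_omega, sigma=0.8)
            start = _posterior(px=1820.0, py=2000.0, pz=320.0, vx=0.0, vy=10.0)
            paths = simulate_paths(start, ridge_env, model,
                                   SimConfig(n_paths=40, duration=120.0, seed=11))
            crest = 2000.0
            windward = (paths["px"] < crest).sum()   # wind is westerly
            leeward = (paths["px"] > crest).sum()
            return windward / max(leeward, 1)

        assert occupancy_ratio(300.0) > 1.0
        assert occupancy_ratio(300.0) > occupancy_ratio(0.0)
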