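import numpy as np
import pandas as pd
import pytest

from soarflight import (
    condition_subset,
    constant_velocity_baseline,
    radial_distance_series,
    risk_map,
    select_validation_tracks,
)
from soarflight.errors import InvalidInputError


def _path(t, px, py, pz, path_id=0):
    return pd.DataFrame({"path_id": path_id, "t": t, "px": px, "py": py, "pz": pz})


def _ref(n=61, vx=10.0):
    t = np.arange(float(n))
    return pd.DataFrame({"t": t, "px": vx * t, "py": 0 * t, "pz": 200 + 0 * t})


class TestRadialDistance:
    def test_identical_paths_give_zero(self):
        ref = _ref()
        sim = _path(ref["t"], ref["px"], ref["py"], ref["pz"])
        res = radial_distance_series(sim, ref)
        assert np.all(res.distances["distance"] == 0.0)

    def test_constant_offset_is_pythagorean(self):
        ref = _ref()
        sim = _path(ref["t"], ref["px"] + 30.0, ref["py"] + 40.0, ref["pz"])
        res = radial_distance_series(sim, ref)
        assert np.allclose(res.distances["distance"], 50.0)
        q = res.quartiles()
        assert np.allclose(q["q2_D"], 50.0 / 130.0)

    def test_horizontal_only_option(self):
        ref = _ref()
        sim = _path(ref["t"], ref["px"], ref["py"], ref["pz"] + 70.0)
        res3 = radial_distance_series(sim, ref)
        res2 = radial_distance_series(sim, ref, horizontal_only=True)
        assert np.allclose(res3.distances["distance"], 70.0)
        assert np.allclose(res2.distances["distance"], 0.0)

    def test_gaussian_cloud_median_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        ref = _ref(2)
        sigma = 12.0
        offsets = rng.normal(0, sigma, size=(300, 3))
        sims = pd.concat([
            _path(ref["t"], ref["px"] + o[0], ref["py"] + o[1], ref["pz"] + o[2], path_id=i)
            for i, o in enumerate(offsets)
        ])
        res = radial_distance_series(sims, ref)
        got = res.median_at(0.0)
        oracle = np.median(np.linalg.norm(offsets, axis=1))  # direct recomputation
        assert got == pytest.approx(oracle)

    def test_truncated_paths_contribute_while_alive(self):
        ref = _ref(11)
        sim = _path(np.arange(5.0), ref["px"][:5], ref["py"][:5], ref["pz"][:5])
        res = radial_distance_series(sim, ref)
        assert set(res.distances["lag"]) == set(np.arange(5.0))

    def test_clock_mismatch_rejected(self):
        ref = _ref(11)
        sim = _path(np.arange(5.0) + 0.5, np.zeros(5), np.zeros(5), np.zeros(5))
        with pytest.raises(InvalidInputError):
            radial_distance_series(sim, ref)


class TestBaseline:
    def test_straight_line_extrapolation(self):
        start = {"px": 0.0, "py": 0.0, "pz": 100.0, "vx": 10.0, "vy": 0.0, "vz": 0.0}
        base = constant_velocity_baseline(start, 10.0)
        assert np.allclose(base["px"], 10.0 * np.arange(11.0))
        assert np.allclose(base["py"], 0.0) and np.allclose(base["pz"], 100.0)

    def test_reference_at_start_velocity_has_zero_error(self):
        ref = _ref()
        start = {"px": 0.0, "py": 0.0, "pz": 200.0, "vx": 10.0, "vy": 0.0, "vz": 0.0}
        base = constant_velocity_baseline(start, 60.0)
        res = radial_distance_series(base, ref)
        assert np.allclose(res.distances["distance"], 0.0, atol=1e-9)

    def test_turning_reference_matches_chord_geometry(self):
        """Against a circling reference the straight baseline's error is the
        chord-to-arc separation, known in closed form."""
        R, om = 500.0, 0.02  # rad/s
        t = np.arange(0.0, 40.0)
        ref = pd.DataFrame({"t": t, "px": R * np.sin(om * t),
                            "py": R - R * np.cos(om * t), "pz": 100 + 0 * t})
        start = {"px": 0.0, "py": 0.0, "pz": 100.0, "vx": R * om, "vy": 0.0, "vz": 0.0}
        base = constant_velocity_baseline(start, 39.0)
        res = radial_distance_series(base, ref)
        d = res.distances.sort_values("lag")["distance"].to_numpy()
        expected = np.hypot(R * om * t - R * np.sin(om * t), R - R * np.cos(om * t))
        assert np.allclose(d, expected, atol=1e-6)

    def test_nonfinite_start_velocity_rejected(self):
        with pytest.raises(InvalidInputError):
            constant_velocity_baseline({"px": 0, "py": 0, "pz": 0,
                                        "vx": np.nan, "vy": 0, "vz": 0}, 10.0)


def _annotated_track(n, rsz_pattern):
    return pd.DataFrame({
        "t": np.arange(float(n)),
        "px": np.zeros(n), "py": np.zeros(n), "pz": np.zeros(n),
        "rsz": rsz_pattern,
        "h_agl": np.where(rsz_pattern, 100.0, 300.0),
        "w": np.full(n, 6.0), "wo": np.full(n, 1.0),
    })


class TestWindowSelection:
    def test_track_above_rsz_is_ineligible(self):
        tr = _annotated_track(400, np.zeros(400, dtype=bool))
        with pytest.warns(UserWarning):
            out = select_validation_tracks([tr], n=5, duration=180.0)
        assert out == []

    def test_exactly_75_percent_rsz_is_eligible(self):
        n = 181
        pattern = np.zeros(400, dtype=bool)
        k = int(np.ceil(0.75 * n))
        pattern[:k] = True  # first window has exactly >= 75% rsz
        tr = _annotated_track(400, pattern)
        out = select_validation_tracks([tr], n=1, duration=180.0, rng=0)
        assert len(out) == 1 and len(out[0]) == n
        assert out[0]["t"].iloc[0] == 0.0  # clock re-zeroed

    def test_fixed_seed_reproducible_selection(self):
        tr = _annotated_track(600, np.ones(600, dtype=bool))
        a = select_validation_tracks([tr], n=3, duration=180.0, rng=7)
        b = select_validation_tracks([tr], n=3, duration=180.0, rng=7)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)


class TestConditionSubsets:
    def _records(self):
        return pd.DataFrame({
            "w": [5.0, 6.0, 6.0, 4.0],
            "h_agl": [100.0, 250.0, 100.0, 100.0],
            "wo": [0.8, 0.8, 0.75, 2.0],
        })

    def test_windy_boundary_inclusive(self):
        out = condition_subset(self._records(), "windy")
        assert len(out) == 3  # w = 5.0 retained, w = 4.0 dropped

    def test_cumulative_rsz_filter(self):
        out = condition_subset(self._records(), "windy+rsz")
        assert len(out) == 2

    def test_cumulative_soaring_filter_inclusive(self):
        out = condition_subset(self._records(), "windy+rsz+soaring")
        assert len(out) == 2  # wo = 0.75 retained

    def test_unknown_condition_rejected(self):
        with pytest.raises(InvalidInputError):
            condition_subset(self._records(), "calm")


class TestRiskMap:
    GRID = dict(origin_xy=(0.0, 0.0), spacing=10.0, shape=(101, 101))

    def _stationary(self, n=60, x=500.0, y=500.0, h_agl=100.0):
        return pd.DataFrame({
            "path_id": 0, "t": np.arange(float(n)),
            "px": np.full(n, x), "py": np.full(n, y),
            "h_agl": np.full(n, h_agl),
        })

    def test_counts_conserved_before_smoothing(self):
        rng = np.random.default_rng(0)
        n = 500
        paths = pd.DataFrame({
            "path_id": 0, "t": rng.uniform(0, 180, n),
            "px": rng.uniform(0, 1000, n), "py": rng.uniform(0, 1000, n),
            "h_agl": rng.uniform(0, 150, n),
        })
        rm = risk_map(paths, lag_window=(0.0, 180.0), **self.GRID)
        assert rm.counts.sum() == n

    def test_stationary_path_peaks_at_one_at_its_node(self):
        rm = risk_map(self._stationary(), lag_window=(0.0, 60.0), **self.GRID)
        assert rm.values.max() == pytest.approx(1.0)
        iy, ix = np.unravel_index(rm.values.argmax(), rm.values.shape)
        assert (ix, iy) == (50, 50)

    def test_two_parallel_paths_give_symmetric_ridges(self):
        a = self._stationary(x=300.0)
        b = self._stationary(x=700.0).assign(path_id=1)
        rm = risk_map(pd.concat([a, b]), lag_window=(0.0, 60.0), **self.GRID)
        assert np.allclose(rm.values, rm.values[:, ::-1], atol=1e-9)

    def test_rsz_only_excludes_high_flight(self):
        rm = risk_map(self._stationary(h_agl=250.0), rsz_only=True,
                      lag_window=(0.0, 60.0), **self.GRID)
        assert rm.counts.sum() == 0 and np.all(rm.values == 0.0)

    def test_normalization_invariant_under_duplication(self):
        p = self._stationary()
        rm1 = risk_map(p, lag_window=(0.0, 60.0), **self.GRID)
        rm2 = risk_map(pd.concat([p, p.assign(path_id=1)]), lag_window=(0.0, 60.0), **self.GRID)
        assert np.allclose(rm1.values, rm2.values)

    def test_lag_window_filters_states(self):
        p = self._stationary(n=60)
        rm = risk_map(p, lag_window=(0.0, 29.0), **self.GRID)
        assert rm.counts.sum() == 30

    def test_empty_lag_window_rejected(self):
        with pytest.raises(InvalidInputError):
            risk_map(self._stationary(), lag_window=(10.0, 10.0), **self.GRID)

    def test_ascii_export(self, tmp_path):
        rm = risk_map(self._stationary(), lag_window=(0.0, 60.0), **self.GRID)
        out = tmp_path / "risk.asc"
        rm.save_ascii(out)
        from soarflight import read_ascii_grid
        vals, origin, spacing = read_ascii_grid(out)
        assert np.array_equal(vals, rm.values)
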