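import numpy as np
import pandas as pd
import pytest

from soarflight import CovariateSpec, MarkovModel, build_design, calibrate, fit_error, fit_mean
from soarflight.errors import InsufficientDataError, InvalidInputError, RankDeficientError
from soarflight.markov import HALF_NORMAL, PredictorModel, default_spec


def _annotated(n, rng=None, h_agl=100.0):
    rng = rng or np.random.default_rng(0)
    agl = h_agl + rng.uniform(-40.0, 40.0, n)
    return pd.DataFrame({
        "t": np.arange(n, dtype=float),
        "wc": rng.normal(0, 3, n), "wt": rng.normal(0, 3, n),
        "wo": rng.uniform(0, 2, n), "h_agl": agl,
        "vz": rng.normal(0, 1, n), "vh": rng.normal(10, 1, n),
        "omega": rng.normal(0, 2, n), "lam": rng.normal(0, 0.01, n),
        "rsz": agl < 200.0,
    })


class TestDesign:
    def test_row_count_accounts_for_burn_in_and_offset(self):
        X, y = build_design(_annotated(180), "vh")
        assert len(X) == 180 - 31  # 30-s lag history + 1-s response offset

    def test_above_rsz_rows_dropped(self):
        X, y = build_design(_annotated(180, h_agl=250.0), "vh")
        assert len(X) == 0

    def test_response_is_next_step_covariates_are_current(self):
        df = _annotated(60)
        X, y = build_design(df, "omega")
        # row j corresponds to covariate time k = 30 + j
        assert y[0] == df["omega"][31]
        assert X["wc"].iloc[0] == df["wc"][30]
        assert X["omega_lag5"].iloc[0] == df["omega"][25]
        assert X["omega_lag30"].iloc[0] == df["omega"][0]
        assert "lam" in X.columns  # heading rate carries the look-ahead covariate

    def test_lam_absent_from_other_predictors_and_error_model(self):
        spec = default_spec("omega")
        assert "lam" in spec.mean_columns and "lam" not in spec.error_columns
        assert "lam" not in default_spec("vh").mean_columns

    def test_unknown_predictor_rejected(self):
        with pytest.raises(InvalidInputError):
            CovariateSpec(predictor="speed")

    def test_constant_covariate_track_has_zero_variance_columns(self):
        df = _annotated(120)
        df["wo"] = 1.5
        X, _ = build_design(df, "vh")
        assert X["wo"].std() == 0.0 and X["intercept"].std() == 0.0


class TestMeanFit:
    def test_noiseless_recovery_to_machine_precision(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(500, 4)), columns=list("abcd"))
        beta = np.array([1.5, -2.0, 0.3, 7.0])
        y = X.to_numpy() @ beta
        est, resid = fit_mean(X, y)
        assert np.allclose(est, beta, atol=1e-10)
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_noisy_recovery_within_three_standard_errors(self):
        # a 3-sigma bound fails ~1% of the time per coefficient by design,
        # so check the sampling distribution over replicates instead of
        # betting a single draw
        beta = np.array([0.5, -1.0, 2.0])
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 5_000
            X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
            y = X.to_numpy() @ beta + rng.normal(0, 1.0, n)
            est, resid = fit_mean(X, y)
            XtX_inv = np.linalg.inv(X.to_numpy().T @ X.to_numpy())
            se = np.sqrt(np.diag(XtX_inv) * resid.var())
            hits += bool(np.all(np.abs(est - beta) < 3 * se))
        assert hits >= 18  # ~0.8% expected failure rate per replicate

    def test_duplicated_column_raises_naming_culprits(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.normal(size=(100, 2)), columns=["a", "b"])
        X["b_copy"] = X["b"]
        with pytest.raises(RankDeficientError) as exc:
            fit_mean(X, rng.normal(size=100))
        assert "b" in exc.value.columns and "b_copy" in exc.value.columns

    def test_too_few_rows_rejected(self):
        X = pd.DataFrame(np.eye(3), columns=list("abc"))
        with pytest.raises(InsufficientDataError):
            fit_mean(X, np.ones(3))


class TestErrorFit:
    def test_homoscedastic_intercept_recovery(self):
        """E|eps| = sigma sqrt(2/pi); the half-normal correction undoes it."""
        rng = np.random.default_rng(4)
        n = 50_000
        X = pd.DataFrame({"intercept": np.ones(n)})
        resid = rng.normal(0, 2.0, n)
        beta, s_min, scale = fit_error(X, resid)
        assert scale == "sigma"
        assert beta[0] == pytest.approx(2.0, rel=0.02)

    def test_zero_residuals_give_zero_weights(self):
        X = pd.DataFrame({"intercept": np.ones(10)})
        beta, s_min, _ = fit_error(X, np.zeros(10))
        assert np.all(beta == 0.0) and s_min > 0

    def test_linear_sigma_structure_recovered(self):
        rng = np.random.default_rng(5)
        n = 100_000
        z = rng.uniform(0, 4, n)
        sigma = 0.5 + 0.8 * z
        X = pd.DataFrame({"intercept": np.ones(n), "z": z})
        resid = sigma * rng.standard_normal(n)
        beta, _, _ = fit_error(X, resid)
        assert beta[1] == pytest.approx(0.8, rel=0.10)
        assert beta[0] == pytest.approx(0.5, rel=0.10)

    def test_squared_method_returns_variance_scale(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"intercept": np.ones(10_000)})
        beta, _, scale = fit_error(X, rng.normal(0, 3.0, 10_000), method="squared")
        assert scale == "sigma2"
        assert beta[0] == pytest.approx(9.0, rel=0.05)

    def test_half_normal_constant(self):
        assert HALF_NORMAL == pytest.approx(np.sqrt(np.pi / 2))


class TestCalibrate:
    def test_calibration_is_deterministic(self):
        tracks = [_annotated(150, np.random.default_rng(s)) for s in range(3)]
        m1 = calibrate(tracks)
        m2 = calibrate(tracks)
        assert m1.to_dict() == m2.to_dict()

    def test_single_short_track_fails_explicitly(self):
        with pytest.raises(InsufficientDataError):
            calibrate(_annotated(36))

    def test_sigma_predictions_floored_on_calibration_data(self):
        tracks = [_annotated(200, np.random.default_rng(s)) for s in range(2)]
        model = calibrate(tracks)
        for name, pm in model.predictors.items():
            X, _ = build_design(tracks, name, pm.spec)
            assert np.all(pm.predict_sigma(X) >= pm.sigma_min)

    def test_model_file_roundtrip_bit_exact(self, tmp_path):
        tracks = [_annotated(200, np.random.default_rng(s)) for s in range(2)]
        model = calibrate(tracks)
        p = tmp_path / "model.json"
        model.save(p)
        back = MarkovModel.load(p)
        for name in model.predictors:
            assert np.array_equal(back.predictors[name].beta_mean,
                                  model.predictors[name].beta_mean)
            assert np.array_equal(back.predictors[name].beta_err,
                                  model.predictors[name].beta_err)
            assert back.predictors[name].sigma_min == model.predictors[name].sigma_min
        assert back.c_omega == model.c_omega

    def test_coefficient_error_shrinks_with_sample_size(self):
        """Median absolute coefficient error decreases as calibration grows."""
        beta = {"intercept": 0.2, "wc": 0.05, "wo": 0.4,
                "vz_lag5": 0.4, "vz_lag10": 0.2, "vz_lag30": 0.1}
        errs = []
        for n in (1_000, 10_000, 100_000):
            rng = np.random.default_rng(100 + n)
            df = _annotated(n, rng)
            spec = default_spec("vz")
            # overwrite the response so it follows a known linear law
            X, _ = build_design(df, "vz", spec)
            truth = np.array([beta.get(c, 0.0) for c in spec.mean_columns])
            y = X.to_numpy() @ truth + rng.normal(0, 0.5, len(X))
            est, _ = fit_mean(X, y)
            errs.append(np.median(np.abs(est - truth)))
        assert errs[0] > errs[1] > errs[2]


class TestRecoveryOnTruthTracks:
    def test_generating_weights_recovered_without_degradation(self, ridge_env):
        """Calibrating directly on simulator-generated 1-s tracks recovers
        the generating mean weights (the machinery-correctness control)."""
        from soarflight.lookahead import add_lambda
        from soarflight.synthetic import SyntheticScenario, make_starts, make_truth_model
        from soarflight.simulate import SimConfig, simulate_paths
        from soarflight.terrain import wind_components

        sc = SyntheticScenario(seed=3)
        model = make_truth_model(sc)
        rng = np.random.default_rng(5)
        starts = make_starts(ridge_env, 30, rng, margin=600.0)
        paths = simulate_paths(starts, ridge_env, model,
                               SimConfig(n_paths=30, duration=240.0, seed=8))
        tracks = []
        for _, sub in paths.groupby("path_id"):
            d = sub.reset_index(drop=True)
            wt, wc = wind_components(10.0, 270.0, d["heading"].to_numpy())
            d["wt"], d["wc"], d["w"] = wt, wc, 10.0
            d["wo"] = ridge_env.updraft.sample(d["px"].to_numpy(), d["py"].to_numpy())
            tracks.append(add_lambda(d, ridge_env.updraft))
        fitted = calibrate(tracks, relation=None)
        # use_lookahead False without a relation; compare shared columns
        for name in ("vz", "vh"):
            est = fitted.predictors[name].beta_mean
            tru = model.predictors[name].beta_mean
            big = np.abs(tru) > 0.05
            assert np.allclose(est[big], tru[big], rtol=0.15, atol=0.05)
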