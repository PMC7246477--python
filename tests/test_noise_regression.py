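import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trafficimpact import acoustics, noise, synthetic
from trafficimpact.ingest import compute_flows


def _synthetic_series(n=2000, lam_car=11011.0, lam_tr=138191.0, bg=4e6,
                      drift_amp=0.0, shape=None, seed=0):
    """15-min intensity series from the linear traffic-noise model."""
    rng = np.random.default_rng(seed)
    q_car = rng.gamma(6.0, 10.0, n)
    q_tr = rng.gamma(4.0, 1.5, n)
    t = np.arange(n) / 96.0
    drift = 1.0 + drift_amp * np.sin(2 * np.pi * t / t[-1])
    I = lam_car * q_car + lam_tr * q_tr + bg * drift
    if shape is not None:
        I = I * rng.gamma(shape, 1.0 / shape, n)
    return I, q_car, q_tr, t


class TestSegregatedFit:
    def test_exact_recovery_on_noise_free_data(self):
        I, qc, qt, t = _synthetic_series()
        fit = noise.fit_noise_model(I, qc, qt, t)
        assert fit.lambdas["car"].value == pytest.approx(11011.0, rel=1e-6)
        assert fit.lambdas["tr"].value == pytest.approx(138191.0, rel=1e-6)
        assert fit.dispersion == pytest.approx(0.0, abs=1e-10)

    def test_recovery_under_gamma_noise(self):
        I, qc, qt, t = _synthetic_series(n=9000, shape=20.0, seed=1)
        fit = noise.fit_noise_model(I, qc, qt, t)
        assert fit.lambdas["tr"].value == pytest.approx(138191.0, rel=0.10)
        assert fit.lambdas["car"].value == pytest.approx(11011.0, rel=0.10)
        assert fit.lambdas["tr"].ci_lower < 138191.0 < fit.lambdas["tr"].ci_upper

    def test_round_trip_through_sample_generator(self):
        """Refitting on the generator's noise-free output recovers lambda exactly."""
        cfg = synthetic.ScenarioConfig(end_date=pd.Timestamp("2017-06-22").date(),
                                       sound_gamma_shape=None, drift_amplitude=0.0,
                                       rng_seed=4)
        ev = synthetic.generate_vehicle_events(cfg)
        span = (pd.Timestamp(cfg.start_date), pd.Timestamp(cfg.end_date))
        flows = compute_flows(ev, "15min", span=span)
        samples = synthetic.generate_noise_series(flows, cfg)
        quarter = acoustics.leq_15min(samples)
        joined = flows.join(quarter, how="inner")
        fit = noise.fit_noise_model(joined["intensity_ratio"], joined["q_car"],
                                    joined["q_tr"])
        assert fit.lambdas["car"].value == pytest.approx(cfg.lambda_car, rel=1e-6)
        assert fit.lambdas["tr"].value == pytest.approx(cfg.lambda_tr, rel=1e-6)

    def test_perfect_collinearity_rejected(self):
        I, qc, _, t = _synthetic_series()
        with pytest.raises(ValueError, match="collinear"):
            noise.fit_noise_model(I, qc, 2.0 * qc, t)

    def test_nonpositive_intensity_rejected(self):
        I, qc, qt, t = _synthetic_series(n=100)
        I[3] = -5.0
        with pytest.raises(ValueError, match="positive"):
            noise.fit_noise_model(I, qc, qt, t)


class TestTotalFit:
    def test_equal_lambdas_reduce_to_total_model(self):
        I, qc, qt, t = _synthetic_series(lam_car=30000.0, lam_tr=30000.0)
        fit = noise.fit_noise_model_total(I, qc + qt, t)
        assert fit.lambdas["tot"].value == pytest.approx(30000.0, rel=1e-6)

    def test_total_lambda_lies_between_car_and_truck(self):
        I, qc, qt, t = _synthetic_series(shape=50.0, seed=2)
        fit = noise.fit_noise_model_total(I, qc + qt, t)
        assert 11011.0 < fit.lambdas["tot"].value < 138191.0

    def test_zero_flow_series_rejected(self):
        I = np.full(100, 4e6)
        with pytest.raises(ValueError, match="inestimable"):
            noise.fit_noise_model_total(I, np.zeros(100))


class TestSlopes:
    @pytest.mark.parametrize("lam,median_leq,expected", [
        (138191.0, 67.4, 25.1),   # trucks, low-flow street
        (11011.0, 67.4, 2.0),     # cars, low-flow street
        (60275.0, 73.7, 2.6),     # trucks, interstate ramp
        (9175.0, 73.7, 0.4),      # total flow, interstate ramp
        (-1679.0, 73.7, -0.1),    # cars, interstate ramp (negative, reported as-is)
    ])
    def test_published_slope_arithmetic(self, lam, median_leq, expected):
        assert round(noise.slope_from_lambda(lam, median_leq), 1) == expected

    def test_zero_lambda_zero_slope(self):
        assert noise.slope_from_lambda(0.0, 67.4) == 0.0

    def test_slopes_scale_linearly_in_lambda_and_inversely_in_intensity(self):
        s = noise.slope_from_lambda(1000.0, 60.0)
        assert noise.slope_from_lambda(2000.0, 60.0) == pytest.approx(2 * s)
        # +10 dB median = 10x intensity = slope / 10
        assert noise.slope_from_lambda(1000.0, 70.0) == pytest.approx(s / 10)

    def test_slope_coefficients_from_fit(self):
        I, qc, qt, t = _synthetic_series()
        fit = noise.fit_noise_model(I, qc, qt, t)
        slopes = noise.slope_coefficients(fit)
        manual = noise.slope_from_lambda(fit.lambdas["tr"].value, fit.median_leq)
        assert slopes.slopes["tr"] == pytest.approx(manual)
        assert fit.median_leq == pytest.approx(
            10 * np.log10(np.median(I)), abs=1e-10)


class TestLambdaRatio:
    def test_published_truck_car_ratio(self):
        I, qc, qt, t = _synthetic_series()
        fit = noise.fit_noise_model(I, qc, qt, t)
        assert round(noise.lambda_ratio(fit), 1) == 12.6  # 138191 / 11011

    def test_equal_lambdas_unit_ratio(self):
        I, qc, qt, t = _synthetic_series(lam_car=5e4, lam_tr=5e4)
        fit = noise.fit_noise_model(I, qc, qt, t)
        assert noise.lambda_ratio(fit) == pytest.approx(1.0, rel=1e-6)

    def test_configured_ratio_recovered_within_ci(self):
        I, qc, qt, t = _synthetic_series(lam_car=2e4, lam_tr=1.6e5, shape=30.0, seed=7)
        fit = noise.fit_noise_model(I, qc, qt, t)
        assert noise.lambda_ratio(fit) == pytest.approx(8.0, rel=0.15)


class TestCollinearity:
    def test_proportional_series(self):
        q = np.linspace(10, 100, 50)
        assert noise.collinearity(q, 2 * q) == pytest.approx(1.0)

    def test_independent_series_near_zero(self, rng):
        a, b = rng.gamma(5, 10, 1000), rng.gamma(5, 2, 1000)
        assert abs(noise.collinearity(a, b)) < 0.1

    def test_antiphase_profiles_negative(self):
        h = np.arange(96)
        day = np.sin(2 * np.pi * h / 96)
        assert noise.collinearity(100 + 50 * day, 10 - 5 * day) < 0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            noise.collinearity(np.ones(10), np.arange(10.0))


class TestDeltas:
    def test_zero_change(self):
        assert noise.delta_intensity(11011, 138191, 0, 0) == 0.0
        assert noise.delta_leq({"tr": 25.1, "car": 2.0}, {"tr": 0.0, "car": 0.0}) == 0.0

    def test_hand_arithmetic(self):
        d = noise.delta_leq({"tr": 25.1, "car": 2.0}, {"tr": 2.0, "car": 10.0})
        assert d == pytest.approx(25.1 * 0.02 + 2.0 * 0.10)
        assert d == pytest.approx(0.702)

    def test_taylor_form_exact_under_linear_model(self):
        lam_car, lam_tr = 11011.0, 138191.0
        q0 = {"car": 50.0, "tr": 5.0}
        dq = {"car": 12.0, "tr": 3.0}
        I0 = lam_car * q0["car"] + lam_tr * q0["tr"] + 4e6
        I1 = lam_car * (q0["car"] + dq["car"]) + lam_tr * (q0["tr"] + dq["tr"]) + 4e6
        assert noise.delta_intensity(lam_car, lam_tr, dq["car"], dq["tr"]) \
            == pytest.approx(I1 - I0, rel=1e-12)

    def test_missing_slope_key_rejected(self):
        with pytest.raises(KeyError):
            noise.delta_leq({"tr": 25.1}, {"tr": 1.0, "car": 1.0})


class TestQuantileResiduals:
    def test_standard_normal_under_correct_specification(self):
        I, qc, qt, t = _synthetic_series(n=4000, shape=20.0, seed=11)
        fit = noise.fit_noise_model(I, qc, qt, t)
        r = noise.quantile_residuals(fit)
        assert abs(r.mean()) < 0.06
        assert r.std() == pytest.approx(1.0, abs=0.06)
        # roughly symmetric tails
        assert abs((r > 1.96).mean() - (r < -1.96).mean()) < 0.02

    def test_skewed_under_wrong_error_model(self):
        # additive heavy one-sided noise violates the Gamma assumption
        rng = np.random.default_rng(0)
        I, qc, qt, t = _synthetic_series(n=2000)
        I = I + rng.exponential(2e6, len(I))
        fit = noise.fit_noise_model(I, qc, qt, t)
        r = noise.quantile_residuals(fit)
        assert abs(stats.skew(r)) > 0.5

    def test_degenerate_fit_rejected(self):
        I, qc, qt, t = _synthetic_series(n=100)
        fit = noise.fit_noise_model(I, qc, qt, t)   # noise-free: dispersion 0
        with pytest.raises(ValueError, match="residual"):
            noise.quantile_residuals(fit)


def test_coefficient_table_round_trip():
    I, qc, qt, t = _synthetic_series(shape=40.0, seed=3)
    fits = {"site4": noise.fit_noise_model(I, qc, qt, t),
            "site4_tot": noise.fit_noise_model_total(I, qc + qt, t)}
    table = noise.coefficient_table(fits)
    assert set(table["model"]) == {"Q_tr + Q_car", "Q_tot"}
    seg = table[table.model == "Q_tr + Q_car"].iloc[0]
    assert seg["lambda_tr_sig"] in ("*", "***")
    assert seg["slope_tr"] == round(
        noise.slope_from_lambda(seg["lambda_tr"], seg["median_leq"]), 1)
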