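"""Estimators: calibration chain, ratio estimators, alpha/Gamma fits."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fractaldiff import (
    CalibratedMSDFit,
    DegenerateDataError,
    FreeMSDFit,
    InconsistentDataError,
    InfeasibleObservationError,
    InsufficientDataError,
    InvalidInputError,
    MSDSeries,
    NoiseSpec,
    SinglePointMSDFit,
    SingularExponentError,
    WalkParameters,
    alpha_from_single_point,
    diffusion_coefficient,
    estimate_lambda_two_point,
    fit_alpha_gamma,
    fit_free,
    gamma_over_D_from_ratio,
    generate_msd_series,
    msd,
    msd_longtime,
    tau_from_anomalous_ratio,
    tau_from_lambda_D,
)


class TestTwoPointLambda:
    def test_quadratic_example(self):
        # alpha=1 closed form with lambda=tau=1: x1=2 at t=4, x2=4 at t=12
        assert estimate_lambda_two_point(4, 4, 12, 16) == pytest.approx(1.0, rel=1e-12)

    def test_dimensional_scaling(self):
        base = estimate_lambda_two_point(4, 4, 12, 16)
        for c in (0.01, 3.7):
            scaled = estimate_lambda_two_point(4, 4 * c**2, 12, 16 * c**2)
            assert scaled == pytest.approx(c * base, rel=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(lam=st.floats(0.01, 10.0), tau=st.floats(1e-4, 10.0),
           n1=st.floats(0.1, 50.0), factor=st.floats(1.5, 50.0))
    def test_exact_on_model_data(self, lam, tau, n1, factor):
        """The estimator is exact, not asymptotic, on noiseless ordinary
        diffusion from the crossover model, for any two times."""
        p = WalkParameters(lam, tau, alpha=1.0)
        t1, t2 = n1 * tau, n1 * factor * tau
        est = estimate_lambda_two_point(t1, msd(t1, p), t2, msd(t2, p))
        assert est == pytest.approx(lam, rel=1e-7)

    def test_round_trip_specific(self):
        p = WalkParameters(0.3, 0.01, alpha=1.0)
        t1, t2 = 0.04, 0.12
        est = estimate_lambda_two_point(t1, msd(t1, p), t2, msd(t2, p))
        assert est == pytest.approx(0.3, rel=1e-9)

    def test_ballistic_points_degenerate(self):
        # msd proportional to t^2: sqrt(msd2)/sqrt(msd1) = t2/t1
        with pytest.raises(DegenerateDataError):
            estimate_lambda_two_point(1.0, 4.0, 3.0, 36.0)

    def test_sublinear_points_inconsistent(self):
        # growth slower than the diffusive branch allows -> negative lambda
        with pytest.raises(InconsistentDataError):
            estimate_lambda_two_point(4.0, 4.0, 12.0, 8.0)

    def test_bad_ordering_rejected(self):
        with pytest.raises(InvalidInputError):
            estimate_lambda_two_point(5.0, 4.0, 3.0, 16.0)
        with pytest.raises(InvalidInputError):
            estimate_lambda_two_point(1.0, 16.0, 3.0, 4.0)


class TestTauEstimators:
    def test_tau_from_lambda_D(self, bilayer_params):
        tau = tau_from_lambda_D(bilayer_params["lambda_mfp"], bilayer_params["D"])
        assert tau == pytest.approx(3.77e-4, abs=0.01e-4)
        assert tau_from_lambda_D(1.0, 0.5) == pytest.approx(1.0)

    def test_round_trip_with_D(self):
        p = WalkParameters(0.11, 0.007)
        assert tau_from_lambda_D(p.lambda_mfp, diffusion_coefficient(p)) == \
            pytest.approx(p.tau, rel=1e-14)

    def test_ratio_estimator_porous_glass(self):
        tau = tau_from_anomalous_ratio(8.5, 1.95, 0.3)
        assert tau == pytest.approx(1.58e-2, abs=0.005e-2)

    def test_unit_ratio_gives_half_time(self):
        for alpha in (0.5, 1.5, 1.95):
            assert tau_from_anomalous_ratio(1.0, alpha, 0.8) == pytest.approx(0.4)

    @pytest.mark.parametrize("alpha, tau", [(0.6, 2e-3), (1.4, 5e-2), (1.95, 1e-2)])
    def test_ratio_forward_inverse_consistency(self, alpha, tau):
        """A ratio generated from the long-time asymptotics with known tau
        must invert back to that tau."""
        t = 0.5
        ratio = (2.0 * tau / t) ** (1.0 - alpha)
        assert tau_from_anomalous_ratio(ratio, alpha, t) == pytest.approx(tau, rel=1e-12)

    def test_singular_and_invalid(self):
        with pytest.raises(SingularExponentError):
            tau_from_anomalous_ratio(2.0, 1.0, 0.3)
        with pytest.raises(InvalidInputError):
            tau_from_anomalous_ratio(-1.0, 1.5, 0.3)
        with pytest.raises(InvalidInputError):
            tau_from_anomalous_ratio(2.0, 1.5, 0.0)


class TestGammaOverDFromRatio:
    def test_porous_glass_value(self):
        assert gamma_over_D_from_ratio(8.5, 1.95, 0.3) == pytest.approx(27.0, abs=0.5)

    def test_alpha1_identity(self):
        assert gamma_over_D_from_ratio(3.3, 1.0, 17.0) == pytest.approx(3.3)

    def test_universal_consistency_with_tau(self):
        """Gamma/D from the ratio times tau^(alpha-1), with tau from the
        same ratio, lands on the universal curve 2^(1-alpha) exactly."""
        for ratio, alpha, t in [(8.5, 1.95, 0.3), (0.2, 0.6, 1.2)]:
            tau = tau_from_anomalous_ratio(ratio, alpha, t)
            god = gamma_over_D_from_ratio(ratio, alpha, t)
            assert god * tau ** (alpha - 1.0) == pytest.approx(
                2.0 ** (1.0 - alpha), rel=1e-10)


class TestSinglePoint:
    def test_round_trip(self):
        p = WalkParameters(1.0, 1.0, alpha=0.7)
        res = alpha_from_single_point(100.0, msd(100.0, p), 1.0, 1.0)
        assert res.alpha_hat == pytest.approx(0.7, abs=1e-6)
        assert res.method == "single_point"
        assert res.residual_norm == 0.0

    def test_ordinary_diffusion_gives_gamma_equals_D(self):
        p = WalkParameters(0.5, 0.02, alpha=1.0)
        res = alpha_from_single_point(1.0, msd(1.0, p), 0.5, 0.02)
        assert res.alpha_hat == pytest.approx(1.0, abs=1e-8)
        assert res.gamma_hat == pytest.approx(diffusion_coefficient(p), rel=1e-6)

    def test_bilayer_shortest_time(self, bilayer_params):
        """Reconstructing the observation from the printed normalized value
        0.803 (alpha = 0.862, Gamma = 1.54) recovers that parameter pair."""
        t = 0.035
        obs = 0.803 * 4.0 * 1.54 * t**0.862
        res = alpha_from_single_point(t, obs, bilayer_params["lambda_mfp"],
                                      bilayer_params["tau"])
        assert res.alpha_hat == pytest.approx(0.862, abs=0.005)
        assert res.gamma_hat == pytest.approx(1.54, abs=0.03)

    def test_observation_above_ballistic_bound(self):
        with pytest.raises(InfeasibleObservationError):
            alpha_from_single_point(1.0, 100.0, 1.0, 1.0)

    def test_closure_holds_exactly(self):
        """Every calibrated fit lies on Gamma = D (2 tau)^(1-alpha)."""
        lam, tau = 0.0559, 3.77e-4
        D = lam**2 / (2 * tau)
        p = WalkParameters(lam, tau, alpha=0.63)
        res = alpha_from_single_point(0.035, msd(0.035, p), lam, tau)
        assert res.gamma_hat == pytest.approx(
            D * (2 * tau) ** (1 - res.alpha_hat), rel=1e-12)


class TestCalibratedFit:
    times4 = np.array([0.035, 0.07, 0.105, 0.14])

    def test_noiseless_round_trip(self, bilayer_params):
        lam, tau = bilayer_params["lambda_mfp"], bilayer_params["tau"]
        p = WalkParameters(lam, tau, alpha=0.78)
        series = MSDSeries(self.times4, np.asarray(msd(self.times4, p)))
        res = fit_alpha_gamma(series, lam, tau)
        assert res.alpha_hat == pytest.approx(0.78, abs=1e-6)
        assert res.method == "least_squares"
        assert res.n_points == 4

    def test_alpha1_gamma_equals_D(self):
        p = WalkParameters(0.3, 0.004, alpha=1.0)
        t = np.geomspace(0.01, 1.0, 6)
        series = MSDSeries(t, np.asarray(msd(t, p)))
        res = fit_alpha_gamma(series, 0.3, 0.004)
        assert res.gamma_hat == pytest.approx(
            diffusion_coefficient(p), rel=1e-6)

    def test_noisy_mean_recovery(self, bilayer_params):
        """200 noisy 4-point series at CV = 2%: the mean alpha estimate
        stays within 0.02 of the generating exponent."""
        lam, tau = bilayer_params["lambda_mfp"], bilayer_params["tau"]
        p = WalkParameters(lam, tau, alpha=0.78)
        hats = []
        for seed in range(200):
            s = generate_msd_series(p, self.times4, NoiseSpec(cv=0.02, seed=seed))
            hats.append(fit_alpha_gamma(s, lam, tau).alpha_hat)
        assert abs(np.mean(hats) - 0.78) < 0.02

    @pytest.mark.parametrize("alpha", [0.5, 0.8, 1.2, 1.8])
    def test_recovery_across_exponents(self, alpha):
        """100 seeds, CV = 5%, 8 points/decade over two decades of t/tau:
        median absolute alpha error below 0.03."""
        lam, tau = 1.0, 1.0
        p = WalkParameters(lam, tau, alpha=alpha)
        times = np.geomspace(10.0, 1000.0, 17)
        errs = []
        for seed in range(100):
            s = generate_msd_series(p, times, NoiseSpec(cv=0.05, seed=seed))
            errs.append(abs(fit_alpha_gamma(s, lam, tau).alpha_hat - alpha))
        assert np.median(errs) < 0.03

    def test_asymptotic_law_data_bias(self, bilayer_params):
        """Short-period data generated from the long-time power law alone
        are above the full crossover curve, so the full-model fit
        overestimates the generating exponent: the same mismatch, in
        reverse, makes pure power-law fits of short-period experiments
        underestimate alpha."""
        lam, tau = bilayer_params["lambda_mfp"], bilayer_params["tau"]
        alpha_true = 0.78
        p = WalkParameters(lam, tau, alpha=alpha_true)
        asymptotic = np.asarray(msd_longtime(self.times4, p))
        full = np.asarray(msd(self.times4, p))
        assert np.all(asymptotic > full)  # power law overshoots at short t
        res = fit_alpha_gamma(MSDSeries(self.times4, asymptotic), lam, tau)
        assert res.alpha_hat > alpha_true

    def test_insufficient_data(self):
        series = MSDSeries(np.array([0.1]), np.array([0.5]))
        with pytest.raises(InsufficientDataError):
            fit_alpha_gamma(series, 1.0, 1.0)

    def test_dimensionality_conversion(self):
        """A 3D series fits to the same parameters as its 2D reduction."""
        p = WalkParameters(0.2, 0.01, alpha=0.9)
        t = np.geomspace(0.05, 5.0, 8)
        m3 = np.asarray(msd(t, p, dimensionality=3))
        res = fit_alpha_gamma(MSDSeries(t, m3, dimensionality=3), 0.2, 0.01)
        assert res.alpha_hat == pytest.approx(0.9, abs=1e-6)


class TestFreeFit:
    def test_sub_diffusive_round_trip(self):
        lam, tau, alpha = 0.0559, 3.77e-4, 0.871
        p = WalkParameters(lam, tau, alpha=alpha)
        D = diffusion_coefficient(p)
        t = np.array([0.035, 0.07, 0.105, 0.14])
        series = MSDSeries(t, np.asarray(msd(t, p)))
        res = fit_free(series, D)
        assert res.alpha_hat == pytest.approx(alpha, abs=1e-4)
        assert res.gamma_hat == pytest.approx(
            2.0**-alpha * lam**2 / tau**alpha, rel=1e-3)
        assert res.tau_used == pytest.approx(tau, rel=1e-3)
        assert res.method == "free_fit"

    def test_super_diffusive_round_trip(self):
        p = WalkParameters(1.0, 0.01, alpha=1.5)
        D = diffusion_coefficient(p)
        t = np.geomspace(0.05, 5.0, 8)
        series = MSDSeries(t, np.asarray(msd(t, p)))
        res = fit_free(series, D)
        assert res.alpha_hat == pytest.approx(1.5, abs=1e-4)
        assert res.tau_used == pytest.approx(0.01, rel=1e-3)

    def test_ordinary_diffusion_smooth(self):
        """The (alpha, ln tau) parameterization has no singularity at
        alpha = 1: ordinary-diffusion data fit cleanly."""
        p = WalkParameters(0.5, 0.02, alpha=1.0)
        D = diffusion_coefficient(p)
        t = np.geomspace(0.05, 20.0, 9)
        series = MSDSeries(t, np.asarray(msd(t, p)))
        res = fit_free(series, D)
        assert res.alpha_hat == pytest.approx(1.0, abs=1e-4)
        assert res.gamma_hat == pytest.approx(D, rel=1e-3)

    def test_insufficient_data(self):
        series = MSDSeries(np.array([0.1, 0.2]), np.array([0.5, 0.9]))
        with pytest.raises(InsufficientDataError):
            fit_free(series, 1.0)


class TestEstimatorAPI:
    """sklearn contract: get_params/set_params, clone-ability, predict."""

    def test_get_set_params(self):
        est = CalibratedMSDFit(lambda_mfp=0.5, tau=0.01)
        assert est.get_params()["lambda_mfp"] == 0.5
        est.set_params(tau=0.02)
        assert est.tau == 0.02

    def test_clone(self):
        from sklearn.base import clone
        est = FreeMSDFit(D=4.15)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_fit_predict_consistency(self):
        p = WalkParameters(1.0, 1.0, alpha=0.8)
        t = np.geomspace(5.0, 500.0, 10)
        y = np.asarray(msd(t, p))
        est = CalibratedMSDFit(lambda_mfp=1.0, tau=1.0).fit(t, y)
        assert est.alpha_ == pytest.approx(0.8, abs=1e-6)
        assert np.allclose(est.predict(t), y, rtol=1e-6)
        # column-vector X, as sklearn pipelines pass it
        est2 = SinglePointMSDFit(lambda_mfp=1.0, tau=1.0)
        est2.fit(t[:1].reshape(-1, 1), y[:1])
        assert est2.alpha_ == pytest.approx(0.8, abs=1e-6)

    def test_result_export_round_trip(self, tmp_path):
        p = WalkParameters(1.0, 1.0, alpha=0.8)
        t = np.geomspace(5.0, 500.0, 6)
        res = fit_alpha_gamma(MSDSeries(t, np.asarray(msd(t, p))), 1.0, 1.0)
        path = tmp_path / "fit.json"
        res.to_json(path)
        import json
        loaded = json.loads(path.read_text())
        assert loaded["alpha_hat"] == pytest.approx(0.8, abs=1e-6)
        tsv = res.to_tsv()
        assert tsv.splitlines()[0].split("\t")[0] == "alpha_hat"
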