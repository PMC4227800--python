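import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gqthermo import (
    BaselineCrossingError,
    CurveDesign,
    MeltingCurve,
    MeltingError,
    NormalizedProfile,
    NoTransitionError,
    TwoStateFit,
    fit_two_state,
    fraction_folded,
    normalize_curve,
    predict_signal,
    simulate_curve,
    tm_median,
)


class TestFractionFolded:
    def test_half_folded_at_tm(self):
        assert fraction_folded(-40.0, 323.2, 323.2) == pytest.approx(0.5, abs=1e-14)

    def test_value_at_25C_matches_van_t_hoff(self):
        # oracle: dG25 = dH*(1 - 298.15/323.2) = -3.100 kcal/mol, then K/(1+K)
        assert fraction_folded(-40.0, 323.2, 298.15) == pytest.approx(
            0.9946888, abs=1e-6
        )

    def test_step_function_limit_for_infinite_enthalpy(self):
        assert fraction_folded(-4000.0, 323.2, 313.2) > 1 - 1e-12
        assert fraction_folded(-4000.0, 323.2, 333.2) < 1e-12

    @pytest.mark.parametrize("bad", [(-40, -1, 300), (-40, 300, 0.0), (0.0, 300, 300)])
    def test_domain_errors(self, bad):
        dH, Tm, T = bad
        with pytest.raises(MeltingError):
            fraction_folded(dH, Tm, T)

    @given(
        dH=st.floats(-120, -5),
        Tm=st.floats(290, 350),
    )
    @settings(deadline=None, max_examples=50)
    def test_half_point_and_monotonicity(self, dH, Tm):
        assert fraction_folded(dH, Tm, Tm) == pytest.approx(0.5, abs=1e-12)
        T = np.linspace(Tm - 30, Tm + 30, 61)
        theta = fraction_folded(dH, Tm, T)
        assert np.all(np.diff(theta) < 0)  # folding enthalpy negative: melts


class TestPredictSignal:
    def test_flat_baselines_at_tm(self):
        fit = TwoStateFit(dH=-40.0, Tm=323.2, baseline_folded=(1.0, 0.0),
                          baseline_unfolded=(0.0, 0.0))
        assert predict_signal(fit, 323.2) == pytest.approx(0.5, abs=1e-14)

    def test_fully_folded_limit_gives_folded_baseline(self):
        fit = TwoStateFit(dH=-400.0, Tm=323.2, baseline_folded=(2.0, -0.001),
                          baseline_unfolded=(0.3, 0.002))
        T = 283.15
        assert predict_signal(fit, T) == pytest.approx(2.0 - 0.001 * T, abs=1e-10)

    def test_round_trip_with_generator(self, noiseless_design, noiseless_curve):
        regenerated = predict_signal(
            noiseless_design.as_fit(), noiseless_curve.temperatures
        )
        assert np.max(np.abs(regenerated - noiseless_curve.signals)) <= 1e-10


class TestFitTwoState:
    def test_noiseless_recovery(self, noiseless_fit):
        assert noiseless_fit.converged
        assert noiseless_fit.dH == pytest.approx(-40.0, rel=1e-6)
        assert noiseless_fit.Tm == pytest.approx(323.2, rel=1e-6)

    def test_noiseless_recovery_recovers_baselines(self, noiseless_design,
                                                   noiseless_fit):
        bf0, bf1, bu0, bu1 = noiseless_design.baselines
        assert noiseless_fit.baseline_folded == pytest.approx((bf0, bf1), abs=1e-6)
        assert noiseless_fit.baseline_unfolded == pytest.approx((bu0, bu1), abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_noisy_recovery_within_3_kcal(self, seed):
        curve = simulate_curve(CurveDesign(noise_sd=0.02, seed=seed))
        fit = fit_two_state(curve, seed=seed)
        assert fit.dH == pytest.approx(-40.0, abs=3.0)
        assert fit.std_errors["dH"] > 0

    def test_affine_signal_rescaling_leaves_dh_tm(self, noiseless_curve,
                                                  noiseless_fit):
        scaled = MeltingCurve(
            temperatures=noiseless_curve.temperatures,
            signals=7.5 * noiseless_curve.signals - 3.0,
            condition=noiseless_curve.condition,
        )
        refit = fit_two_state(scaled)
        assert refit.dH == pytest.approx(noiseless_fit.dH, rel=1e-8)
        assert refit.Tm == pytest.approx(noiseless_fit.Tm, rel=1e-8)

    def test_flat_curve_raises_no_transition(self):
        T = np.linspace(283.15, 353.15, 50)
        curve = MeltingCurve(temperatures=T, signals=np.ones_like(T))
        with pytest.raises(NoTransitionError):
            fit_two_state(curve)

    def test_curve_validation(self):
        with pytest.raises(MeltingError):
            MeltingCurve(temperatures=np.array([1, 2, 3.0]),
                         signals=np.array([1, 2, 3.0]))  # too few points
        T = np.linspace(300, 310, 10)
        with pytest.raises(MeltingError):
            MeltingCurve(temperatures=T[::-1], signals=np.zeros(10))


class TestNormalizeAndTmMedian:
    def test_noiseless_theta_matches_model_pointwise(self, noiseless_curve,
                                                     noiseless_fit):
        prof = normalize_curve(noiseless_curve, noiseless_fit)
        model = fraction_folded(
            noiseless_fit.dH, noiseless_fit.Tm, noiseless_curve.temperatures
        )
        assert np.max(np.abs(prof.theta - model)) <= 1e-10

    def test_tm_median_matches_fit_tm_noiseless(self, noiseless_curve,
                                                noiseless_fit):
        prof = normalize_curve(noiseless_curve, noiseless_fit)
        assert tm_median(prof) == pytest.approx(noiseless_fit.Tm, abs=0.05)

    def test_crossing_on_grid_point_returned_exactly(self):
        T = np.linspace(300, 340, 41)
        theta = np.linspace(1, 0, 41)  # hits 0.5 exactly at T=320
        assert tm_median(NormalizedProfile(T, theta)) == pytest.approx(320.0)

    def test_tm_median_noisy_centred_within_half_kelvin(self):
        # the model-free crossing has ~0.3-0.4 K per-curve scatter at 2%
        # noise; the distributional claim is on its centre
        estimates = []
        for seed in range(20):
            curve = simulate_curve(CurveDesign(noise_sd=0.02, seed=seed))
            fit = fit_two_state(curve, seed=seed)
            estimates.append(tm_median(normalize_curve(curve, fit)))
        assert np.median(estimates) == pytest.approx(323.2, abs=0.5)

    def test_noisy_theta_residual_scales_with_noise(self):
        noise_sd = 0.02
        curve = simulate_curve(CurveDesign(noise_sd=noise_sd, seed=11))
        fit = fit_two_state(curve, seed=11)
        prof = normalize_curve(curve, fit)
        model = fraction_folded(fit.dH, fit.Tm, curve.temperatures)
        # baseline separation varies along the curve; mean |residual| should
        # sit near the injected amplitude-relative noise (x sqrt(2/pi) for
        # the half-normal mean), well within a factor of two
        mean_resid = np.mean(np.abs(prof.theta - model))
        assert 0.3 * noise_sd < mean_resid < 2.0 * noise_sd

    def test_baseline_crossing_rejected(self, noiseless_curve):
        bad = TwoStateFit(dH=-40.0, Tm=323.2, baseline_folded=(1.0, -0.01),
                          baseline_unfolded=(-2.0, 0.0))  # crosses at 300 K
        with pytest.raises(BaselineCrossingError):
            normalize_curve(noiseless_curve, bad)

    def test_no_crossing_raises(self):
        T = np.linspace(300, 340, 20)
        with pytest.raises(MeltingError):
            tm_median(NormalizedProfile(T, np.full(20, 0.9)))
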