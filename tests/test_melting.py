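"""Fraction-folded conversion of UV melting curves and Tm extraction."""

import numpy as np
import pytest

from g4ims.melting import (
    DEFAULT_WINDOWS,
    BaselineFit,
    MeltingCurve,
    fit_baselines,
    fraction_folded,
)
from g4ims.simulate import MeltingParams, make_melting_curve, two_state_theta

LOW, HIGH = DEFAULT_WINDOWS


def exact_baselines(params: MeltingParams) -> BaselineFit:
    """BaselineFit built from the generator's planted coefficients."""
    return BaselineFit(
        folded=params.folded_baseline,
        unfolded=params.unfolded_baseline,
        windows=DEFAULT_WINDOWS,
        folded_rms=0.0,
        unfolded_rms=0.0,
        noise_sd=0.0,
        poor_fit=False,
    )


class TestBaselines:
    def test_planted_baselines_recovered(self):
        params = MeltingParams(noise_sd=0.0)
        curve, _ = make_melting_curve(params)
        fit = fit_baselines(curve, LOW, HIGH)
        # tolerance reflects the logistic tail leaking into the windows
        assert fit.folded == pytest.approx(params.folded_baseline, abs=5e-3)
        assert fit.unfolded == pytest.approx(params.unfolded_baseline, abs=5e-3)
        assert not fit.poor_fit

    def test_flat_baselines(self):
        params = MeltingParams(
            noise_sd=0.0, folded_baseline=(0.5, 0.0), unfolded_baseline=(0.3, 0.0)
        )
        curve, _ = make_melting_curve(params)
        fit = fit_baselines(curve, LOW, HIGH)
        assert abs(fit.folded[1]) < 1e-4
        assert abs(fit.unfolded[1]) < 1e-4

    def test_window_overlapping_transition_flagged(self):
        curve, _ = make_melting_curve(MeltingParams(noise_sd=0.0))
        fit = fit_baselines(curve, (4.0, 58.0), (78.0, 90.0))
        assert fit.poor_fit

    def test_window_with_too_few_points_rejected(self):
        curve, _ = make_melting_curve(MeltingParams(noise_sd=0.0))
        with pytest.raises(ValueError):
            fit_baselines(curve, (4.0, 4.3), HIGH)

    def test_windows_outside_range_rejected(self):
        curve, _ = make_melting_curve(MeltingParams(noise_sd=0.0))
        with pytest.raises(ValueError):
            fit_baselines(curve, (-10.0, 20.0), HIGH)


class TestFractionFolded:
    def test_limits_exact(self):
        """A = L0 everywhere gives theta = 0; A = L1 gives theta = 1."""
        params = MeltingParams(noise_sd=0.0)
        t = np.arange(4.0, 90.0, 0.25)
        fit = exact_baselines(params)
        unfolded = MeltingCurve(t, fit.l0(t))
        assert np.all(fraction_folded(unfolded, fit).theta == 0.0)
        folded = MeltingCurve(t, fit.l1(t))
        assert np.all(fraction_folded(folded, fit).theta == 1.0)

    def test_noiseless_pointwise_recovery_with_exact_baselines(self):
        params = MeltingParams(noise_sd=0.0)
        curve, _ = make_melting_curve(params)
        frac = fraction_folded(curve, exact_baselines(params))
        truth = two_state_theta(curve.temperature_c, params.tm_c, params.dh_kj_mol)
        assert np.allclose(frac.theta, truth, atol=1e-12)
        # two-state curve is symmetric in 1/T, not T: ~0.01 degC residual
        assert frac.tm_c == pytest.approx(params.tm_c, abs=0.02)

    def test_theta_at_planted_tm_is_half(self):
        params = MeltingParams(noise_sd=0.0)
        curve, _ = make_melting_curve(params)
        fit = fit_baselines(curve, LOW, HIGH)
        frac = fraction_folded(curve, fit)
        theta_at_tm = np.interp(params.tm_c, frac.temperature_c, frac.theta)
        assert theta_at_tm == pytest.approx(0.5, abs=5e-3)

    def test_tm_recovery_bias_over_seeds(self):
        """Across 100 noisy curves the mean Tm error stays below 0.1 degC."""
        errors = []
        for seed in range(100):
            curve, truth = make_melting_curve(MeltingParams(), seed=seed)
            frac = fraction_folded(curve, fit_baselines(curve, LOW, HIGH))
            errors.append(frac.tm_c - truth["tm_c"])
        assert abs(float(np.mean(errors))) < 0.1

    def test_cooling_and_heating_agree(self):
        """A reversible two-state system shows zero hysteresis; ramp
        direction must not change Tm."""
        params = MeltingParams(noise_sd=0.0)
        heat, _ = make_melting_curve(params, ramp="heating")
        cool, _ = make_melting_curve(params, ramp="cooling")
        tm_h = fraction_folded(heat, fit_baselines(heat, LOW, HIGH)).tm_c
        tm_c = fraction_folded(cool, fit_baselines(cool, LOW, HIGH)).tm_c
        assert tm_h == pytest.approx(tm_c, abs=1e-9)

    def test_zero_amplitude_degenerate(self):
        """Coinciding baselines make Eq-style conversion impossible."""
        base = (0.4, -0.0005)
        params = MeltingParams(
            noise_sd=0.0, folded_baseline=base, unfolded_baseline=base
        )
        curve, _ = make_melting_curve(params)
        with pytest.raises(ValueError):
            fraction_folded(curve, exact_baselines(params))

    def test_affine_invariance(self):
        """theta is unchanged when A, L0, L1 undergo the same affine map."""
        params = MeltingParams(noise_sd=0.0)
        curve, _ = make_melting_curve(params)
        frac = fraction_folded(curve, fit_baselines(curve, LOW, HIGH))
        alpha, beta = 3.0, 0.7
        scaled = MeltingCurve(curve.temperature_c, alpha * curve.absorbance + beta)
        frac2 = fraction_folded(scaled, fit_baselines(scaled, LOW, HIGH))
        assert np.allclose(frac.theta, frac2.theta, atol=1e-9)

    def test_tm_absent_when_no_crossing(self):
        """A trace pinned at theta = 0.8 over the whole range has no Tm."""
        params = MeltingParams(noise_sd=0.0)
        fit = exact_baselines(params)
        t = np.arange(4.0, 90.0, 0.25)
        a = fit.l0(t) + 0.8 * (fit.l1(t) - fit.l0(t))
        frac = fraction_folded(MeltingCurve(t, a), fit)
        assert frac.tm_c is None
        assert np.allclose(frac.theta, 0.8)
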