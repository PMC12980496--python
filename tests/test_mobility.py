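"""Step-field CCS regression, single-field conversion, and the QC gate."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from g4ims.ions import IonSpecies, tg4t_reference_ion
from g4ims.mobility import (
    QC_REFERENCE_CCS_A2,
    STEP_FIELD_VOLTAGES,
    DriftTubeConfig,
    StepFieldSeries,
    calibration_factor,
    convert_atd,
    forward_drift_time,
    qc_gate,
    single_field_ccs,
    stepfield_fit,
)
from g4ims.simulate import make_atd, make_stepfield


def oracle_drift_time(ccs_a2, ion_mass_da, z, delta_v, cfg):
    """Independent hand evaluation of the low-field drift-time relation,
    written out constant by constant (no package helpers)."""
    kb, e, da = 1.380649e-23, 1.602176634e-19, 1.66053906660e-27
    mu = cfg.gas_mass_da * ion_mass_da / (cfg.gas_mass_da + ion_mass_da) * da
    n_density = cfg.N0 * (cfg.p_torr / cfg.p0_torr) * (cfg.T0 / cfg.T)
    slope = (
        (ccs_a2 * 1e-20)
        * (math.sqrt(mu) / z)
        * (16.0 * cfg.L**2 / (3.0 * e))
        * math.sqrt(kb * cfg.T / (2.0 * math.pi))
        * n_density
    )
    return slope / delta_v


class TestForwardModel:
    def test_number_density_printed_conditions(self, cfg):
        # 3.89 Torr at 296.15 K: ~1.268e23 m^-3
        assert cfg.number_density == pytest.approx(1.2685e23, rel=1e-3)

    def test_qc_ion_drift_time_at_650v(self, cfg):
        """QC ion at its literature CCS drifts ~13.0 ms at 650 V."""
        ion = tg4t_reference_ion()
        t = forward_drift_time(QC_REFERENCE_CCS_A2, ion, 650.0, 0.0, cfg)
        assert t == pytest.approx(
            oracle_drift_time(QC_REFERENCE_CCS_A2, ion.ion_mass, 5, 650.0, cfg),
            rel=1e-9,
        )
        assert t == pytest.approx(13.0e-3, abs=0.1e-3)

    def test_linearities(self, cfg):
        ion = tg4t_reference_ion()
        t0 = 0.4e-3
        t1 = forward_drift_time(788.0, ion, 650.0, t0, cfg)
        t2 = forward_drift_time(788.0, ion, 1300.0, t0, cfg)
        assert (t2 - t0) == pytest.approx((t1 - t0) / 2, rel=1e-12)
        t3 = forward_drift_time(1576.0, ion, 650.0, t0, cfg)
        assert (t3 - t0) == pytest.approx(2 * (t1 - t0), rel=1e-12)


class TestStepFieldFit:
    def test_qc_round_trip_noiseless(self, cfg):
        """Arrival times synthesized at the five printed voltages re-fit to
        the reference CCS within 0.1% and pass the QC gate."""
        ion = tg4t_reference_ion()
        series, _ = make_stepfield(ion, QC_REFERENCE_CCS_A2, 0.3e-3, cfg)
        fit = stepfield_fit(series, cfg)
        assert fit.ccs_a2 == pytest.approx(QC_REFERENCE_CCS_A2, rel=1e-3)
        assert fit.t0_s == pytest.approx(0.3e-3, rel=1e-6)
        assert qc_gate(fit)

    def test_uniform_time_shift_moves_only_intercept(self, cfg):
        ion = tg4t_reference_ion()
        series, _ = make_stepfield(ion, 788.0, 0.0, cfg)
        shifted = StepFieldSeries(series.voltages, series.t_arrival_s + 1e-3, ion)
        f0, f1 = stepfield_fit(series, cfg), stepfield_fit(shifted, cfg)
        assert f1.ccs_a2 == pytest.approx(f0.ccs_a2, rel=1e-9)
        assert f1.t0_s - f0.t0_s == pytest.approx(1e-3, rel=1e-6)

    @given(
        ccs=st.floats(300.0, 5000.0),
        t0_ms=st.floats(0.0, 2.0),
        z=st.integers(5, 25),
    )
    @settings(max_examples=60, deadline=None)
    def test_forward_fit_inverse_consistency(self, g4tn, cfg, ccs, t0_ms, z):
        """Fitting a forward-synthesized series recovers (CCS, t0) to
        numerical precision for any plausible ion."""
        ion = IonSpecies(g4tn, z=z, n_nh4=2)
        series, _ = make_stepfield(ion, ccs, t0_ms * 1e-3, cfg)
        fit = stepfield_fit(series, cfg)
        assert fit.ccs_a2 == pytest.approx(ccs, rel=1e-8)
        assert fit.t0_s == pytest.approx(t0_ms * 1e-3, abs=1e-12 + 1e-6 * t0_ms)

    def test_noisy_fit_unbiased(self, cfg):
        """1% arrival-time noise, 200 seeds: mean CCS within 1% of planted
        and the reported standard error consistent with the scatter."""
        ion = tg4t_reference_ion()
        fits = []
        for seed in range(200):
            series, _ = make_stepfield(
                ion, 788.0, 0.3e-3, cfg, noise_frac=0.01, seed=seed
            )
            fits.append(stepfield_fit(series, cfg))
        ccs = np.array([f.ccs_a2 for f in fits])
        assert ccs.mean() == pytest.approx(788.0, rel=0.01)
        reported_se = np.mean([f.ccs_se_a2 for f in fits])
        assert 0.5 < reported_se / ccs.std() < 2.0

    def test_too_few_points_rejected(self, cfg):
        ion = tg4t_reference_ion()
        series, _ = make_stepfield(ion, 788.0, 0.0, cfg, voltages=(650.0, 700.0))
        with pytest.raises(ValueError):
            stepfield_fit(series, cfg)

    def test_negative_slope_rejected(self, cfg):
        ion = tg4t_reference_ion()
        v = np.array(STEP_FIELD_VOLTAGES)
        # arrival times increasing with voltage => negative slope vs 1/dV
        series = StepFieldSeries(v, v * 1e-6, ion)
        with pytest.raises(ValueError):
            stepfield_fit(series, cfg)

    def test_ms_csv_round_trip(self, cfg, tmp_path):
        """File convention is ms; internal units are seconds."""
        import pandas as pd

        ion = tg4t_reference_ion()
        series, _ = make_stepfield(ion, 788.0, 0.3e-3, cfg)
        path = tmp_path / "sf.csv"
        pd.DataFrame(
            {
                "delta_v_volts": series.voltages,
                "t_arrival_ms": series.t_arrival_s * 1e3,
            }
        ).to_csv(path, index=False)
        fit = stepfield_fit(StepFieldSeries.from_csv(path, ion), cfg)
        assert fit.ccs_a2 == pytest.approx(788.0, rel=1e-9)


class TestSingleField:
    def test_reference_identity(self, cfg):
        """Applying the factor to the reference ion's own arrival time
        returns the step-field CCS exactly."""
        ion = tg4t_reference_ion()
        series, _ = make_stepfield(ion, 788.0, 0.0, cfg)
        fit = stepfield_fit(series, cfg)
        tA_ref = float(series.t_arrival_s[0])
        factor = calibration_factor(fit, tA_ref, ion, cfg)
        assert single_field_ccs(tA_ref, factor, ion, cfg) == pytest.approx(
            fit.ccs_a2, rel=1e-12
        )

    def test_ccs_proportional_to_charge(self, g4tn, cfg):
        ion8 = IonSpecies(g4tn, z=8, n_nh4=2)
        ion16 = IonSpecies(g4tn, z=16, n_nh4=2)
        ref = tg4t_reference_ion()
        series, _ = make_stepfield(ref, 788.0, 0.0, cfg)
        fit = stepfield_fit(series, cfg)
        factor = calibration_factor(fit, float(series.t_arrival_s[0]), ref, cfg)
        c8 = single_field_ccs(5e-3, factor, ion8, cfg)
        c16 = single_field_ccs(5e-3, factor, ion16, cfg)
        # same arrival time, (almost) same reduced mass, doubled charge
        assert c16 / c8 == pytest.approx(2.0, rel=1e-3)

    def test_second_species_planted_ccs_recovered(self, g4tn, cfg):
        """A second ion synthesized with the same t0=0 forward model
        converts back to its planted CCS within 0.1%."""
        ref = tg4t_reference_ion()
        series, _ = make_stepfield(ref, 788.0, 0.0, cfg)
        fit = stepfield_fit(series, cfg)
        factor = calibration_factor(fit, float(series.t_arrival_s[0]), ref, cfg)
        ion = IonSpecies(g4tn, z=16, n_nh4=2)
        tA = forward_drift_time(2800.0, ion, 650.0, 0.0, cfg)
        assert single_field_ccs(tA, factor, ion, cfg) == pytest.approx(
            2800.0, rel=1e-3
        )

    def test_convert_atd_bimodal_and_conserving(self, g4tn, cfg):
        from g4ims.conformers import find_modes

        ref = tg4t_reference_ion()
        series, _ = make_stepfield(ref, 788.0, 0.0, cfg)
        fit = stepfield_fit(series, cfg)
        factor = calibration_factor(fit, float(series.t_arrival_s[0]), ref, cfg)
        ion = IonSpecies(g4tn, z=18, n_nh4=0)
        t, y, _ = make_atd(ion, [(2800.0, 50.0, 0.6), (3500.0, 50.0, 0.4)], factor, cfg)
        ccsd = convert_atd(t, y, factor, ion, cfg)
        assert ccsd.total_intensity() == pytest.approx(float(y.sum()), rel=1e-12)
        modes = find_modes(ccsd)
        assert len(modes) == 2
        for (got, _), planted in zip(modes, (2800.0, 3500.0)):
            assert abs(got - planted) <= 2 * ccsd.bin_width

    def test_gas_mismatch_rejected(self, cfg):
        ion = tg4t_reference_ion()
        series, _ = make_stepfield(ion, 788.0, 0.0, cfg)
        fit = stepfield_fit(series, cfg)
        factor = calibration_factor(fit, float(series.t_arrival_s[0]), ion, cfg)
        n2 = DriftTubeConfig(gas_mass_da=28.0134)
        with pytest.raises(ValueError):
            single_field_ccs(5e-3, factor, ion, n2)


class TestQCGate:
    @pytest.mark.parametrize(
        "ccs, expected",
        [(788.0, True), (784.9, False), (785.0, True), (791.0, True), (791.1, False)],
    )
    def test_closed_window(self, ccs, expected):
        ion = tg4t_reference_ion()
        fit_like = type("F", (), {"ccs_a2": ccs})()
        assert qc_gate(fit_like) is expected
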