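"""Digital-twin physics: pump law, valve law, gas pocket, simulation."""

import math

import numpy as np
import pytest

import mitrasim as ms
from mitrasim.twin import SimulationError


class TestPumpFlow:
    def test_closed_cycle_integrates_to_zero(self, quiet_config):
        t = np.linspace(0.0, quiet_config.period_s, 20001)
        q = ms.pump_flow(t, quiet_config)
        assert np.trapezoid(q, t) == pytest.approx(0.0, abs=1e-3)

    def test_ejection_lobe_delivers_stroke_volume(self, quiet_config):
        t_sys = quiet_config.systolic_fraction * quiet_config.period_s
        t = np.linspace(0.0, t_sys, 20001)
        q = ms.pump_flow(t, quiet_config)
        assert np.trapezoid(q, t) == pytest.approx(70.0, rel=1e-6)

    def test_peak_ejection_flow_closed_form(self):
        cfg = ms.RigConfig(sv_pump_ml=70.0, hr_bpm=80.0, systolic_fraction=0.35)
        t_sys = 0.35 * 0.75
        expected_peak = 0.5 * math.pi * 70.0 / t_sys  # ~419 ml/s
        assert ms.pump_flow(t_sys / 2.0, cfg) == pytest.approx(expected_peak)
        assert expected_peak == pytest.approx(419.0, abs=0.5)


class TestOrificeFlow:
    def test_no_gradient_no_flow(self):
        assert ms.orifice_flow(0.0, 1.0) == 0.0

    def test_closed_orifice(self):
        assert ms.orifice_flow(100.0, 0.0) == 0.0

    def test_hand_computed_magnitude(self):
        # 1 cm2, 100 mmHg, rho 1060: A * sqrt(2 * 13332.2 / 1060) * 100 ml/s
        expected = 100.0 * math.sqrt(2.0 * 100.0 * 133.322 / 1060.0)
        assert ms.orifice_flow(100.0, 1.0, 1060.0) == pytest.approx(expected, rel=1e-3)
        assert expected == pytest.approx(501.6, abs=0.1)

    def test_antisymmetric_in_gradient(self):
        assert ms.orifice_flow(-50.0, 2.0) == pytest.approx(-ms.orifice_flow(50.0, 2.0))

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            ms.orifice_flow(10.0, -1.0)


class TestIdealGasPocket:
    def test_reference_pressure_no_compression(self):
        assert ms.ideal_gas_pocket(130.0, 782.0, 782.0) == pytest.approx(130.0)

    def test_compression_worked_example(self):
        compression = 130.0 - ms.ideal_gas_pocket(130.0, 782.0, 819.0)
        assert compression == pytest.approx(130.0 * (1 - 782.0 / 819.0), rel=1e-12)
        assert compression == pytest.approx(5.87, abs=0.01)

    def test_rigid_system(self):
        assert ms.ideal_gas_pocket(0.0, 782.0, 900.0) == 0.0

    def test_nonpositive_pressure_rejected(self):
        with pytest.raises(ValueError):
            ms.ideal_gas_pocket(130.0, 0.0, 819.0)
        with pytest.raises(ValueError):
            ms.ideal_gas_pocket(130.0, 782.0, -5.0)


class TestSimulate:
    def test_competent_valve_has_no_backflow(self, quiet_run):
        _, truth = quiet_run
        assert np.all(truth.mitral_backflow_ml < 1e-6)

    def test_deterministic_given_seed(self):
        cfg = ms.RigConfig(duration_s=4.0, seed=123)
        s1, t1 = ms.simulate(cfg)
        s2, t2 = ms.simulate(cfg)
        assert np.array_equal(s1.p_lv_abs, s2.p_lv_abs)
        assert np.array_equal(s1.p_la_abs, s2.p_la_abs)
        assert np.array_equal(s1.q_aortic, s2.q_aortic)
        assert np.array_equal(t1.mitral_backflow_ml, t2.mitral_backflow_ml)

    def test_zero_noise_matches_resampled_solution(self, quiet_config):
        stream, _ = ms.simulate(quiet_config)
        # different seed, still noise-free: identical streams
        stream2, _ = ms.simulate(quiet_config.replace(seed=99))
        assert np.array_equal(stream.p_lv_abs, stream2.p_lv_abs)
        # noise actually perturbs the series
        noisy, _ = ms.simulate(quiet_config.replace(noise_sd_mmhg=0.5))
        assert not np.array_equal(stream.p_lv_abs, noisy.p_lv_abs)
        assert np.std(noisy.p_lv_abs - stream.p_lv_abs) == pytest.approx(0.5, rel=0.1)

    def test_volume_conservation_per_cycle(self):
        for cv, ero in ((130.0, 0.0), (130.0, 0.3), (0.0, 0.2), (40.0, 0.1)):
            cfg = ms.RigConfig(
                cv_ml=cv, mv_ero_cm2=ero, duration_s=5.0,
                noise_sd_mmhg=0.0, noise_sd_ml_s=0.0,
            )
            _, truth = ms.simulate(cfg)
            assert np.max(np.abs(truth.conservation_residual_ml())) < 0.5

    def test_backflow_monotone_in_ero(self):
        backflows = []
        for ero in (0.0, 0.1, 0.2, 0.4):
            cfg = ms.RigConfig(
                mv_ero_cm2=ero, duration_s=5.0,
                noise_sd_mmhg=0.0, noise_sd_ml_s=0.0,
            )
            _, truth = ms.simulate(cfg)
            backflows.append(truth.mitral_backflow_ml.mean())
        assert all(b2 >= b1 for b1, b2 in zip(backflows, backflows[1:]))
        assert backflows[-1] > backflows[0] + 10.0

    def test_unstable_regime_raises(self):
        # step far too coarse for the Windkessel time constant
        cfg = ms.RigConfig(
            duration_s=2.0, dt_s=5e-3,
            c_reservoir_ml_per_mmhg=0.01, r_peripheral_mmhg_s_per_ml=0.05,
        )
        with pytest.raises(SimulationError, match="dt_s"):
            ms.simulate(cfg)

    def test_stream_grid_and_metadata(self, quiet_run, quiet_config):
        stream, _ = quiet_run
        assert np.allclose(np.diff(stream.t), 1.0 / quiet_config.fs_hz)
        assert stream.meta["noise_free"] is True
        assert stream.meta["transient_cycles_discarded"] >= 3
        assert np.all(stream.p_lv_abs > 0)


class TestCalibrateAfterload:
    def test_reaches_target(self):
        cfg = ms.RigConfig(mv_ero_cm2=0.0, r_peripheral_mmhg_s_per_ml=1.2)
        out = ms.calibrate_afterload(cfg, 120.0, tol_mmhg=3.0)
        stream, _ = ms.simulate(
            out.replace(noise_sd_mmhg=0.0, noise_sd_ml_s=0.0, duration_s=8.0)
        )
        from mitrasim.beats import measure_sbp

        assert 117.0 <= measure_sbp(stream, expected_hr=80.0) <= 123.0

    def test_fixed_point_returns_config_unchanged(self):
        cfg = ms.RigConfig()
        stream, _ = ms.simulate(
            cfg.replace(noise_sd_mmhg=0.0, noise_sd_ml_s=0.0, duration_s=8.0)
        )
        from mitrasim.beats import measure_sbp

        current = measure_sbp(stream, expected_hr=80.0)
        out = ms.calibrate_afterload(cfg, current, tol_mmhg=3.0)
        assert out == cfg

    def test_resistance_monotone_in_target(self):
        cfg = ms.RigConfig()
        lo = ms.calibrate_afterload(cfg, 100.0, tol_mmhg=2.0)
        hi = ms.calibrate_afterload(cfg, 130.0, tol_mmhg=2.0)
        assert (
            hi.r_peripheral_mmhg_s_per_ml >= lo.r_peripheral_mmhg_s_per_ml
        )

    def test_unreachable_target_raises(self):
        with pytest.raises(ms.CalibrationError):
            ms.calibrate_afterload(ms.RigConfig(), 400.0)
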