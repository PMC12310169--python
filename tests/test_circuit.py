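"""Drive-circuit model: resonance, shaping, ODE simulation, waveform fits."""

import numpy as np
import pytest

from magstim.circuit import (
    CAPACITOR_BANK_NF,
    DEFAULT_INDUCTANCE,
    TUNED_FREQUENCIES,
    CircuitConfig,
    PulseSpec,
    WaveformTrace,
    bench_tuned_configs,
    find_resonance,
    fit_current_waveform,
    fit_voltage_amplitude,
    natural_time_constant,
    pulse_duration,
    resonant_frequency,
    series_resistance,
    shaped_voltage,
    simulate_current,
)


class TestNaturalTimeConstant:
    def test_two_l_over_r(self):
        cfg = CircuitConfig(L=0.87e-3, R=2.757, C=23.3e-9, tuned=True)
        tau = natural_time_constant(cfg)
        assert tau == pytest.approx(631e-6, rel=1e-3)
        # the study's longest natural ramp-up, expressed in stimulus cycles
        assert tau * 35400 == pytest.approx(22.3, abs=0.05)

    def test_r_proportionality(self):
        lo = natural_time_constant(CircuitConfig(L=1e-3, R=1.0, C=1e-6, tuned=True))
        hi = natural_time_constant(CircuitConfig(L=1e-3, R=2.0, C=1e-6, tuned=True))
        assert lo == 2 * hi

    def test_untuned_rejected(self):
        with pytest.raises(ValueError):
            natural_time_constant(CircuitConfig(L=1e-3, R=1.0, tuned=False))


class TestResonantFrequency:
    def test_bank_settings(self):
        assert resonant_frequency(0.87e-3, 45.6e-9) == pytest.approx(25.3e3, rel=2e-3)
        assert resonant_frequency(0.87e-3, 3.73e-9) == pytest.approx(88.1e3, rel=4e-3)

    def test_capacitance_scaling(self):
        f1 = resonant_frequency(1e-3, 1e-8)
        f2 = resonant_frequency(1e-3, 4e-8)
        assert f1 == pytest.approx(2 * f2, rel=1e-12)

    def test_derived_inductance_consistent_with_bank(self):
        # the high-frequency (C, f_res) pairs all imply ~the same inductance
        implied = [
            1.0 / ((2 * np.pi * f) ** 2 * (c * 1e-9))
            for c, f in zip(CAPACITOR_BANK_NF, TUNED_FREQUENCIES)
            if f >= 8e3
        ]
        assert np.mean(implied) == pytest.approx(DEFAULT_INDUCTANCE, rel=0.01)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            resonant_frequency(0.0, 1e-9)


class TestShapedVoltage:
    def test_matched_tau_degenerates_to_step_sinusoid(self):
        cfg = CircuitConfig(L=0.87e-3, R=2.757, C=45.6e-9, tuned=True)
        tau_nat = natural_time_constant(cfg)
        f = 25300.0
        spec = PulseSpec(f=f, n_cycles=8, tau_des_cycles=tau_nat * f, V0=3.0)
        v = shaped_voltage(spec, cfg)
        assert np.allclose(v.values, 3.0 * np.sin(2 * np.pi * f * v.times), atol=1e-12)

    def test_envelope_asymptote(self):
        cfg = CircuitConfig(L=0.87e-3, R=5.0, C=45.6e-9, tuned=True)
        spec = PulseSpec(f=25300.0, n_cycles=256, V0=2.0)
        v = shaped_voltage(spec, cfg)
        tail = v.values[int(0.9 * v.values.size):]
        assert np.max(np.abs(tail)) == pytest.approx(2.0, rel=1e-3)

    def test_overshoot_warns(self):
        cfg = CircuitConfig(L=0.87e-3, R=0.5, C=45.6e-9, tuned=True)  # tau_nat huge
        spec = PulseSpec(f=25300.0, n_cycles=8, tau_des_cycles=5.0)
        with pytest.warns(UserWarning, match="overshoot"):
            shaped_voltage(spec, cfg)


class TestSimulateAndFit:
    def test_step_drive_recovers_natural_time_constant(self):
        cfg, f = bench_tuned_configs()[5]  # 25.3 kHz setting
        tau_nat = natural_time_constant(cfg)
        spec = PulseSpec(f=f, n_cycles=128, tau_des_cycles=tau_nat * f, V0=10.0)
        i = simulate_current(cfg, shaped_voltage(spec, cfg))
        fit = fit_current_waveform(i, f_hint=f)
        assert fit.tau_fit == pytest.approx(tau_nat, rel=0.01)
        assert fit.I0_fit == pytest.approx(10.0 / cfg.R, rel=0.01)
        assert abs(np.degrees(fit.phi)) < 2.0

    def test_shaped_drive_achieves_25_cycles(self):
        cfg, f = bench_tuned_configs()[2]  # 4.04 kHz setting, tau_nat 12.7 cycles
        spec = PulseSpec(f=f, n_cycles=128, V0=10.0)
        i = simulate_current(cfg, shaped_voltage(spec, cfg))
        fit = fit_current_waveform(i, f_hint=f)
        assert fit.tau_cycles() == pytest.approx(25.0, rel=0.02)

    def test_untuned_low_frequency_shaping_and_phase(self):
        cfg = CircuitConfig(L=0.87e-3, R=0.1, tuned=False)
        f = 200.0
        spec = PulseSpec(f=f, n_cycles=128, V0=10.0)
        i = simulate_current(cfg, shaped_voltage(spec, cfg))
        fit = fit_current_waveform(i, f_hint=f)
        assert fit.tau_cycles() == pytest.approx(25.0, rel=0.02)
        expected_phi = -np.arctan(2 * np.pi * f * cfg.L / cfg.R)
        assert np.degrees(abs(fit.phi - expected_phi)) < 2.0

    def test_zero_voltage_gives_zero_current(self):
        cfg = CircuitConfig(L=1e-3, R=1.0, C=1e-7, tuned=True)
        t = np.arange(4096) / 1e6
        i = simulate_current(cfg, WaveformTrace(t, np.zeros_like(t), "voltage"))
        assert np.all(i.values == 0.0)

    def test_fit_round_trip_exact(self):
        f = 25300.0
        t = np.arange(int(128 * 256)) / (256 * f)
        y = 10.0 * (1 - np.exp(-t * f / 25.0)) * np.sin(2 * np.pi * f * t)
        fit = fit_current_waveform(WaveformTrace(t, y, "current"), f_hint=f)
        assert fit.I0_fit == pytest.approx(10.0, rel=1e-6)
        assert fit.tau_fit == pytest.approx(25.0 / f, rel=1e-6)
        assert fit.f_fit == pytest.approx(f, rel=1e-9)
        assert abs(fit.phi) < 1e-6

    def test_fit_noise_recovery_monte_carlo(self, rng):
        """1% amplitude white noise leaves I0 and tau within 2% (100 reps)."""
        f = 25300.0
        t = np.arange(int(100 * 128)) / (128 * f)
        clean = 10.0 * (1 - np.exp(-t * f / 25.0)) * np.sin(2 * np.pi * f * t)
        errs_I, errs_tau = [], []
        for _ in range(100):
            y = clean + 0.1 * rng.standard_normal(t.size)
            fit = fit_current_waveform(WaveformTrace(t, y, "current"), f_hint=f)
            errs_I.append(abs(fit.I0_fit - 10.0) / 10.0)
            errs_tau.append(abs(fit.tau_fit * f - 25.0) / 25.0)
        assert max(errs_I) < 0.02
        assert max(errs_tau) < 0.02


class TestSeriesResistance:
    def test_ratio_and_homogeneity(self):
        assert series_resistance(10.0, 100.0) == pytest.approx(0.1)
        assert series_resistance(20.0, 200.0) == pytest.approx(0.1)
        with pytest.raises(ValueError):
            series_resistance(10.0, 0.0)

    def test_recovers_circuit_resistance_from_fits(self):
        cfg, f = bench_tuned_configs()[4]
        spec = PulseSpec(f=f, n_cycles=128, V0=10.0)
        v = shaped_voltage(spec, cfg)
        i = simulate_current(cfg, v)
        V0 = fit_voltage_amplitude(v, f_hint=f)
        I0 = fit_current_waveform(i, f_hint=f).I0_fit
        assert series_resistance(V0, I0) == pytest.approx(cfg.R, rel=0.01)


class TestFindResonance:
    def test_sweep_localizes_resonance(self):
        cfg = CircuitConfig(L=0.87e-3, R=2.0, C=45.6e-9, tuned=True)
        truth = resonant_frequency(cfg.L, cfg.C)
        est = find_resonance(cfg, center=truth + 60.0, span=400.0, n_points=20)
        assert abs(est - truth) < 20.0

    def test_boundary_flagged(self):
        cfg = CircuitConfig(L=0.87e-3, R=2.0, C=45.6e-9, tuned=True)
        truth = resonant_frequency(cfg.L, cfg.C)
        with pytest.warns(UserWarning, match="boundary"):
            find_resonance(cfg, center=truth + 1000.0, span=400.0, n_points=20)

    def test_resistive_load_rejected(self):
        with pytest.raises(ValueError):
            find_resonance(CircuitConfig(L=1e-3, R=1.0, tuned=False), 1e3, 400.0)

    def test_grid_precision_scales_with_span(self):
        cfg = CircuitConfig(L=0.87e-3, R=2.0, C=45.6e-9, tuned=True)
        truth = resonant_frequency(cfg.L, cfg.C)
        wide = find_resonance(cfg, center=truth + 3.0, span=400.0, n_points=21)
        narrow = find_resonance(cfg, center=truth + 3.0, span=200.0, n_points=21)
        assert abs(narrow - truth) <= abs(wide - truth) + 1e-9


class TestPulseDuration:
    @pytest.mark.parametrize(
        "f,expected_ms",
        [(200.0, 1280.0), (88100.0, 2.91), (25300.0, 10.1)],
    )
    def test_printed_durations(self, f, expected_ms):
        from conftest import sig3

        assert sig3(pulse_duration(f, 256)) == expected_ms

    def test_zero_cycles(self):
        assert pulse_duration(1000.0, 0) == 0.0
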