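"""Waveform-level properties of the sech adiabatic and sinc-Gaussian pulses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slowedit import (
    RFWaveform,
    SincGaussDesign,
    calibrate_sech_amplitude,
    make_sech_pulse,
    make_sinc_gauss_pulse,
    peak_power,
    ppm_to_hz,
    pulse_energy,
    solve_sech_parameters,
)
from slowedit.bloch import inversion_profile, propagate_grid


def asech(x):
    return np.log(1.0 / x + np.sqrt(1.0 / x**2 - 1.0))


class TestSechDesign:
    def test_closed_form_parameters(self):
        # 24 ms / 0.88 kHz / 1% truncation: beta and mu from the closed form
        d = solve_sech_parameters(0.024, 880.0, 0.01)
        assert d.beta == pytest.approx(2.0 * asech(0.01) / 0.024, rel=1e-12)
        assert d.mu == pytest.approx(np.pi * 880.0 / d.beta, rel=1e-12)
        # design identity
        assert d.mu * d.beta / np.pi == pytest.approx(880.0, rel=1e-12)

    def test_degenerate_truncation_rejected(self):
        with pytest.raises(ValueError):
            solve_sech_parameters(0.024, 880.0, truncation=1.0)
        with pytest.raises(ValueError):
            solve_sech_parameters(-0.024, 880.0)

    def test_bandwidth_linearity(self):
        a = solve_sech_parameters(0.024, 440.0)
        b = solve_sech_parameters(0.024, 880.0)
        assert b.beta == pytest.approx(a.beta)
        assert b.mu == pytest.approx(2.0 * a.mu)

    def test_bandwidth_identity_via_inversion_profile(self):
        # sweep width mu*beta/pi matches the simulated Mz=0 crossing width
        d = calibrate_sech_amplitude(solve_sech_parameters(0.024, 880.0, 0.01), 2.0)
        w = make_sech_pulse(d, 2048)
        offs = np.linspace(-900.0, 900.0, 1201)
        prof = inversion_profile(w, offs)
        inverted = offs[prof.mz < 0]
        width = inverted.max() - inverted.min()
        assert width == pytest.approx(880.0, rel=0.10)


@pytest.fixture(scope="module")
def design():
    d = solve_sech_parameters(0.024, 880.0, 0.01, carrier_offset_hz=ppm_to_hz(2.9))
    return calibrate_sech_amplitude(d, 2.0)


class TestSechWaveform:
    def test_peak_at_center_equals_omega0(self, design):
        w = make_sech_pulse(design, 4096)
        assert np.max(w.amplitude) == pytest.approx(design.omega0, rel=1e-5)

    def test_edge_truncation(self, design):
        w = make_sech_pulse(design, 4096)
        edge_ratio = w.amplitude[0] / np.max(w.amplitude)
        assert edge_ratio == pytest.approx(design.truncation, rel=0.01)

    def test_instantaneous_frequency_matches_sweep(self, design):
        w = make_sech_pulse(design, 4096)
        t = w.times
        phase = np.unwrap(np.angle(w.samples))
        inst_f = np.gradient(phase, w.dt) / (2.0 * np.pi)
        expected = -design.mu * design.beta * np.tanh(design.beta * t) / (2.0 * np.pi)
        # interior points (numerical differentiation is poor at the edges)
        sl = slice(10, -10)
        assert np.allclose(inst_f[sl], expected[sl], atol=1.0)
        # odd function of t, asymptote mu*beta/(2*pi)
        assert np.allclose(inst_f[sl], -inst_f[::-1][sl], atol=1.0)
        assert np.abs(expected).max() <= design.mu * design.beta / (2 * np.pi)

    def test_phase_analytic_integral(self, design):
        # unwrapped phase equals mu*ln(sech(beta*t)) up to a constant
        w = make_sech_pulse(design, 4096)
        t = w.times
        phase = np.unwrap(np.angle(w.samples))
        expected = design.mu * np.log(1.0 / np.cosh(design.beta * t))
        diff = phase - expected
        assert np.max(np.abs(diff - diff[0])) < 1e-6

    def test_sampling_rejections(self, design):
        with pytest.raises(ValueError):
            make_sech_pulse(design, 128)  # below minimum
        # too few samples to resolve the sweep
        fast = solve_sech_parameters(0.024, 40000.0, 0.01)
        fast = type(fast)(**{**fast.__dict__, "omega0": 1000.0})
        with pytest.raises(ValueError):
            make_sech_pulse(fast, 256)


class TestSincGauss:
    def test_even_and_removable_singularity(self):
        w = make_sinc_gauss_pulse(SincGaussDesign(), 2048)
        assert np.allclose(w.samples, w.samples[::-1])
        # centre value corresponds to the limit ratio f (scaled): it is the max
        assert np.argmax(w.amplitude) in (1023, 1024)

    def test_flip_angle_scaling(self):
        d = SincGaussDesign(flip_deg=65.0)
        w = make_sinc_gauss_pulse(d, 2048)
        flip = np.sum(w.samples.real) * w.dt
        assert flip == pytest.approx(np.deg2rad(65.0), rel=1e-9)

    def test_excitation_profile_width(self):
        # 6 ms, f=5500, b=400 -> ~5.5 kHz excitation FWHM
        w = make_sinc_gauss_pulse(SincGaussDesign(), 2048)
        offs = np.linspace(-6000.0, 6000.0, 961)
        a, b = propagate_grid(w, offs, 1.0)
        mxy = np.abs(2.0 * np.conj(a) * b)
        half = offs[mxy >= mxy.max() / 2]
        assert (half.max() - half.min()) == pytest.approx(5500.0, rel=0.05)

    def test_invalid_designs_rejected(self):
        with pytest.raises(ValueError):
            SincGaussDesign(t_range=(-1e-3, 2e-3)).validate()
        with pytest.raises(ValueError):
            SincGaussDesign(flip_deg=0.0).validate()
        with pytest.raises(ValueError):
            SincGaussDesign(t_range=(-1.5, 1.5)).validate()


class TestEnergyAndPeak:
    def test_null_waveform(self):
        w = RFWaveform(np.zeros(300, complex), 1e-5)
        assert pulse_energy(w) == 0.0
        assert peak_power(w) == 0.0

    @given(st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_quadratic_scaling(self, factor):
        d = calibrate_sech_amplitude(solve_sech_parameters(0.012, 560.0, 0.01), 2.0)
        w = make_sech_pulse(d, 512)
        assert pulse_energy(w.scaled(factor)) == pytest.approx(
            factor**2 * pulse_energy(w), rel=1e-9
        )

    def test_additive_over_concatenation(self):
        d = calibrate_sech_amplitude(solve_sech_parameters(0.012, 560.0, 0.01), 2.0)
        w = make_sech_pulse(d, 512)
        both = RFWaveform(np.concatenate([w.samples, w.samples]), w.dt)
        assert pulse_energy(both) == pytest.approx(2.0 * pulse_energy(w), rel=1e-12)

    def test_energy_tracks_bandwidth(self):
        # equal duration/truncation, equal threshold multiple: energy ~ BW
        da = calibrate_sech_amplitude(solve_sech_parameters(0.024, 560.0, 0.01), 2.0)
        db = calibrate_sech_amplitude(solve_sech_parameters(0.024, 880.0, 0.01), 2.0)
        ratio = pulse_energy(make_sech_pulse(da, 1024)) / pulse_energy(
            make_sech_pulse(db, 1024)
        )
        assert ratio == pytest.approx(560.0 / 880.0, rel=0.25)

    def test_peak_power_is_omega0_squared_and_tracks_bw_over_tau(self):
        da = calibrate_sech_amplitude(solve_sech_parameters(0.024, 560.0, 0.01), 2.0)
        wa = make_sech_pulse(da, 1024)
        assert peak_power(wa) == pytest.approx(da.omega0**2, rel=1e-4)
        db = calibrate_sech_amplitude(solve_sech_parameters(0.031, 810.0, 0.01), 2.0)
        wb = make_sech_pulse(db, 1024)
        model = (560.0 / 0.024) / (810.0 / 0.031)
        assert peak_power(wa) / peak_power(wb) == pytest.approx(model, rel=0.25)
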