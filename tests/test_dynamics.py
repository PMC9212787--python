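"""Density-matrix engine: Hamiltonian, evolution, sequence and spectra."""

import numpy as np
import pytest

from slowedit import (
    FID,
    IdealBandPulse,
    SequenceTiming,
    SpinSystem,
    evolve,
    fid_to_spectrum,
    hamiltonian,
    run_slow_acquisition,
)
from slowedit.constants import HZ_PER_PPM
from slowedit.dynamics import apply_shaped_pulse, spin_operators
from slowedit.bloch import inversion_profile

from conftest import J_AX


def transverse_and_antiphase(rho, n=2, spin=0, partner=1):
    """Normalized in-phase and antiphase coefficient magnitudes of one spin."""
    ix, iy, iz = spin_operators(n)

    def c(op):
        return np.trace(rho @ op).real / np.trace(op @ op).real

    ip = np.hypot(c(ix[spin]), c(iy[spin]))
    ap = np.hypot(c(2 * ix[spin] @ iz[partner]), c(2 * iy[spin] @ iz[partner]))
    return ip, ap


class TestHamiltonian:
    def test_uncoupled_spin_at_reference_is_zero(self):
        s = SpinSystem("ref", [3.0], [[0.0]])
        assert np.allclose(hamiltonian(s), 0.0)

    def test_hermitian(self, gaba):
        h = hamiltonian(gaba)
        assert np.allclose(h, h.conj().T)

    def test_isotropic_coupling_spectrum(self):
        # two on-resonance spins, J=7: singlet/triplet gap equals 2*pi*J
        s = SpinSystem("pair", [3.0, 3.0], [[0.0, 7.0], [7.0, 0.0]])
        evals = np.sort(np.linalg.eigvalsh(hamiltonian(s)))
        gap = evals[-1] - evals[0]
        assert gap == pytest.approx(2.0 * np.pi * 7.0, rel=1e-12)

    def test_hz_per_ppm_scale(self):
        # one spin 1 ppm downfield precesses at 297 Hz
        s = SpinSystem("one", [4.0], [[0.0]])
        h = hamiltonian(s)
        assert h[0, 0].real == pytest.approx(2 * np.pi * 297.0 / 2, rel=1e-12)


class TestEvolve:
    def test_zero_time_identity(self):
        s = SpinSystem("x", [3.5], [[0.0]])
        h = hamiltonian(s)
        rho = np.array([[0.2, 0.4], [0.4, 0.8]], dtype=complex)
        assert np.allclose(evolve(rho, h, 0.0), rho)

    def test_precession_phase(self):
        s = SpinSystem("x", [4.0], [[0.0]])  # +297 Hz
        h = hamiltonian(s)
        ix, iy, iz = spin_operators(1)
        rho = np.asarray(ix[0])
        t = 1e-3
        out = evolve(rho, h, t)
        phi = 2 * np.pi * 297.0 * t
        # downfield spins precess counterclockwise in this convention (the
        # detected signal gains e^{+i phi}, landing at higher ppm after DFT)
        cx = np.trace(out @ ix[0]).real / 0.5
        cy = np.trace(out @ iy[0]).real / 0.5
        assert np.angle(cx + 1j * cy) == pytest.approx(phi, abs=1e-9)

    def test_unitarity_stress(self, ax_system):
        h = hamiltonian(ax_system)
        rng = np.random.default_rng(0)
        m = rng.normal(size=(4, 4)) + 1j * rng.normal(size=(4, 4))
        rho = m @ m.conj().T
        rho /= np.trace(rho).real
        ev0 = np.sort(np.linalg.eigvalsh(rho))
        out = rho
        for _ in range(10_000):
            out = evolve(out, h, 1e-5)
        assert np.trace(out).real == pytest.approx(1.0, abs=1e-10)
        assert np.allclose(np.sort(np.linalg.eigvalsh(out)), ev0, atol=1e-10)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            evolve(np.eye(2, dtype=complex), np.eye(4, dtype=complex), 1.0)


class TestShapedPulse:
    def test_zero_amplitude_equals_free_evolution(self, ax_system, scheme2_partial_pulse):
        from slowedit.pulses import RFWaveform

        w = scheme2_partial_pulse
        silent = RFWaveform(np.zeros_like(w.samples), w.dt, w.carrier_offset_hz)
        h = hamiltonian(ax_system)
        ix, iy, iz = spin_operators(2)
        rho = np.asarray(ix[0] + iz[1])
        via_pulse = apply_shaped_pulse(rho, ax_system, silent)
        via_free = evolve(rho, h, w.duration)
        assert np.allclose(via_pulse, via_free, atol=1e-8)

    def test_stopband_spin_untouched(self, scheme2_partial_pulse, ax_system):
        # partner at 1.9 ppm is deep in the partial pulse's stop band
        ix, iy, iz = spin_operators(2)
        rho = np.asarray(iz[0] + iz[1])
        out = apply_shaped_pulse(rho, ax_system, scheme2_partial_pulse)
        cz = np.trace(out @ iz[1]).real / np.trace(np.asarray(iz[1]) @ iz[1]).real
        assert cz == pytest.approx(1.0, abs=0.01)
        # and agrees with the single-spin inversion profile within 2%
        prof = inversion_profile(
            scheme2_partial_pulse, np.array([(1.9 - 3.0) * HZ_PER_PPM])
        )
        assert cz == pytest.approx(prof.mz[0], abs=0.02)

    def test_nyquist_rejected(self, ax_system):
        from slowedit.pulses import solve_sech_parameters, make_sech_pulse
        import dataclasses

        d = solve_sech_parameters(0.024, 880.0, 0.01)
        d = dataclasses.replace(d, omega0=1000.0)
        coarse = make_sech_pulse(d, 256)
        # make it coarser than the engine tolerates by faking a huge carrier
        coarse = dataclasses.replace(coarse, carrier_offset_hz=5e4)
        with pytest.raises(ValueError):
            apply_shaped_pulse(np.eye(4, dtype=complex), ax_system, coarse)


class TestSlowAcquisition:
    def test_in_band_singlet_full_amplitude(self, scheme2_full_pulse):
        s = SpinSystem("gly", [3.548], [[0.0]])
        fid = run_slow_acquisition(
            s, scheme2_full_pulse, SequenceTiming(0.068, scheme2_full_pulse.duration),
            n_points=4,
        )
        # fully excited, fully refocused single spin: |s(0)| = 0.5
        assert abs(fid.samples[0]) == pytest.approx(0.5, rel=0.02)

    @pytest.mark.parametrize("te", [0.034, 0.068, 0.090, 0.120])
    def test_weak_coupling_echo_modulation(self, te, ax_far):
        # closed-form oracle: ideal instantaneous refocusing of both spins
        pulse = IdealBandPulse(0.5, 5.0)
        _, rho = run_slow_acquisition(
            ax_far, pulse, SequenceTiming(te, 0.0), n_points=2, return_state=True
        )
        ip, ap = transverse_and_antiphase(rho)
        assert ip == pytest.approx(abs(np.cos(np.pi * J_AX * te)), abs=0.02)
        assert ap == pytest.approx(abs(np.sin(np.pi * J_AX * te)), abs=0.02)

    def test_selective_refocusing_in_phase(self, ax_system, scheme2_partial_pulse):
        # partner in the stop band: J evolution refocused, in-phase doublet at
        # the uncoupled reference amplitude
        timing = SequenceTiming(0.068, scheme2_partial_pulse.duration)
        _, rho = run_slow_acquisition(
            ax_system, scheme2_partial_pulse, timing, n_points=2, return_state=True
        )
        ip, ap = transverse_and_antiphase(rho)
        single = SpinSystem("s", [3.0], [[0.0]])
        _, rho_ref = run_slow_acquisition(
            single, scheme2_partial_pulse, timing, n_points=2, return_state=True
        )
        ix, iy, _ = spin_operators(1)
        ref = np.hypot(
            np.trace(rho_ref @ ix[0]).real / 0.5, np.trace(rho_ref @ iy[0]).real / 0.5
        )
        assert ip == pytest.approx(ref, rel=0.02)
        assert ap <= 0.05

    def test_out_of_band_spin_suppressed(self, scheme2_partial_pulse):
        # water-like singlet outside the band is dephased by pathway selection
        s = SpinSystem("water", [4.7], [[0.0]])
        # 4.7 is outside the partial band (upper edge ~4.39)
        fid = run_slow_acquisition(
            s, scheme2_partial_pulse,
            SequenceTiming(0.068, scheme2_partial_pulse.duration), n_points=4,
        )
        assert abs(fid.samples[0]) <= 5e-3

    def test_timing_budget_enforced(self):
        with pytest.raises(ValueError):
            SequenceTiming(0.030, 0.024)
        with pytest.raises(ValueError):
            SequenceTiming(0.068, 0.010, delays=(0.01, 0.01, 0.01))

    def test_strong_coupling_equivalent_limit(self, scheme2_full_pulse):
        # shift difference -> 0 with J != 0: single line (equivalent spins)
        s = SpinSystem("a2", [3.0, 3.0], [[0.0, 7.0], [7.0, 0.0]])
        fid = run_slow_acquisition(
            s, scheme2_full_pulse, SequenceTiming(0.068, scheme2_full_pulse.duration),
            n_points=512,
        )
        spec = fid_to_spectrum(fid, 2.0, 2)
        absorptive = spec.intensity.real
        peak_ppm = spec.ppm[np.argmax(absorptive)]
        assert peak_ppm == pytest.approx(3.0, abs=0.02)
        # all (absorptive) signal concentrated at the single chemical shift
        outside = np.abs(absorptive[np.abs(spec.ppm - 3.0) > 0.1])
        assert outside.max() <= 0.02 * absorptive.max()


class TestSpectrum:
    def test_zero_fid_zero_spectrum(self):
        fid = FID(np.zeros(64, complex), 1.0 / 1280.0)
        spec = fid_to_spectrum(fid)
        assert np.all(spec.intensity == 0)

    def test_dft_integral_identity(self):
        rng = np.random.default_rng(1)
        fid = FID(rng.normal(size=256) + 1j * rng.normal(size=256), 1.0 / 1280.0)
        spec = fid_to_spectrum(fid, apodization_hz=5.0, zero_fill=2, first_point="full")
        assert np.mean(spec.intensity) == pytest.approx(fid.samples[0], rel=1e-6)

    def test_parseval(self):
        rng = np.random.default_rng(2)
        fid = FID(rng.normal(size=256) + 1j * rng.normal(size=256), 1.0 / 1280.0)
        spec = fid_to_spectrum(fid, apodization_hz=0.0, zero_fill=1, first_point="full")
        lhs = np.sum(np.abs(spec.intensity) ** 2) / fid.samples.size
        rhs = np.sum(np.abs(fid.samples) ** 2)
        assert lhs == pytest.approx(rhs, rel=1e-9)

    def test_lorentzian_position_and_width(self):
        # pure decaying tone at 4.0 ppm: line at 4.0 with FWHM = natural + apod
        dwell = 1.0 / 1280.0
        t = np.arange(2048) * dwell
        natural = 1.0
        f = (4.0 - 3.0) * HZ_PER_PPM
        fid = FID(np.exp((1j * 2 * np.pi * f - np.pi * natural) * t), dwell)
        spec = fid_to_spectrum(fid, apodization_hz=2.0, zero_fill=4)
        absorptive = spec.intensity.real  # line is in phase: FWHM on the real part
        assert spec.ppm[np.argmax(absorptive)] == pytest.approx(4.0, abs=0.005)
        half = spec.ppm[absorptive >= absorptive.max() / 2]
        fwhm_hz = (half.max() - half.min()) * HZ_PER_PPM
        assert fwhm_hz == pytest.approx(3.0, rel=0.15)

    def test_invalid_args(self):
        fid = FID(np.zeros(8, complex), 1e-3)
        with pytest.raises(ValueError):
            fid_to_spectrum(fid, apodization_hz=-1.0)
        with pytest.raises(ValueError):
            fid_to_spectrum(fid, zero_fill=0)

    def test_scheme_invariance_of_singlet_norm(self, scheme2_full_pulse, scheme2_partial_pulse):
        # in-band uncoupled singlet: total integrated magnitude is invariant to
        # the scheme band (full vs partial) within 2%
        s = SpinSystem("gly", [3.548], [[0.0]])
        norms = []
        for pulse in (scheme2_full_pulse, scheme2_partial_pulse):
            fid = run_slow_acquisition(
                s, pulse, SequenceTiming(0.068, pulse.duration), n_points=512
            )
            spec = fid_to_spectrum(fid, 2.0, 2)
            norms.append(np.sum(np.abs(spec.intensity)))
        assert norms[0] == pytest.approx(norms[1], rel=0.02)
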