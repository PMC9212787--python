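"""Density-matrix simulation of coupled spin systems through the SLOW double echo.

The sequence model is: ideal (or shaped) 90deg excitation -> tau/2 -> CSAP ->
tau -> CSAP -> tau/2 -> acquisition, solving the relaxation-free
Liouville-von Neumann equation with the full strong-coupling Hamiltonian

    H = sum_k 2*pi*(delta_k - ref)*hz_per_ppm * Ikz
      + sum_{k<l} 2*pi*J_kl * (Ik . Il)

Chemical-shift and J evolution continue *during* the refocusing pulses (the
pulses are 24-31 ms, a large fraction of TE).  Crusher gradients are modeled
as ideal coherence-pathway selection: around each refocusing pulse only the
density-matrix components whose coherence order is conjugated (p -> -p)
survive, which is exactly what a symmetric spoiler pair enforces.  This is
the mechanism of the implicit water/lipid suppression: spins the pulse does
not invert keep their coherence order and are dephased.

Detection uses s(t) = Tr(rho * F+), i.e. the coherence-order -1 pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .constants import HZ_PER_PPM, REF_PPM
from .pulses import RFWaveform
from .systems import SpinSystem

__all__ = [
    "SequenceTiming",
    "IdealBandPulse",
    "FID",
    "Spectrum",
    "spin_operators",
    "hamiltonian",
    "evolve",
    "apply_shaped_pulse",
    "coherence_filter_through_pulse",
    "run_slow_acquisition",
    "fid_to_spectrum",
]

_SX = np.array([[0, 0.5], [0.5, 0]], dtype=complex)
_SY = np.array([[0, -0.5j], [0.5j, 0]], dtype=complex)
_SZ = np.array([[0.5, 0], [0, -0.5]], dtype=complex)


@lru_cache(maxsize=16)
def spin_operators(n: int):
    """Cartesian single-spin operators (Ix, Iy, Iz per spin) in the n-spin product space."""
    ix, iy, iz = [], [], []
    for k in range(n):
        ops = [np.eye(2, dtype=complex)] * n
        for op, bank in ((_SX, ix), (_SY, iy), (_SZ, iz)):
            ops_k = list(ops)
            ops_k[k] = op
            m = ops_k[0]
            for o in ops_k[1:]:
                m = np.kron(m, o)
            bank.append(m)
    return ix, iy, iz


def _coherence_orders(n: int) -> np.ndarray:
    """Matrix of coherence orders p = M_row - M_col in the Zeeman product basis."""
    m_states = np.zeros(2**n)
    for k in range(n):
        bit = (np.arange(2**n) >> (n - 1 - k)) & 1
        m_states += 0.5 - bit  # bit 0 = |alpha> (m=+1/2)
    return m_states[:, None] - m_states[None, :]


@dataclass
class SequenceTiming:
    """Echo timing: delays around the two refocusing pulses.

    delays = (d1, d2, d3) with the sequence d1 - pulse - d2 - pulse - d3;
    d1 + d2 + d3 + 2*pulse_duration == te_s.
    """

    te_s: float
    pulse_duration_s: float
    delays: tuple = None

    def __post_init__(self) -> None:
        if self.delays is None:
            # symmetric placement tau/2 - pulse - tau - pulse - tau/2
            tau = (self.te_s - 2.0 * self.pulse_duration_s) / 2.0
            if tau < 0:
                raise ValueError("TE too short for two pulses of this duration")
            self.delays = (tau / 2.0, tau, tau / 2.0)
        if any(d < -1e-12 for d in self.delays):
            raise ValueError("delays must be non-negative")
        total = sum(self.delays) + 2.0 * self.pulse_duration_s
        if abs(total - self.te_s) > 1e-9 + 1e-6 * self.te_s:
            raise ValueError(f"timing budget violated: {total} != TE {self.te_s}")


@dataclass
class IdealBandPulse:
    """Instantaneous, perfectly band-selective 180deg refocusing pulse.

    Spins whose (possibly B0-shifted) resonance falls inside [lo_ppm, hi_ppm]
    receive an exact pi rotation about +x; spins outside are untouched.  This
    is the zero-duration / rectangular-profile limit of the swept adiabatic
    pulse: it removes intra-pulse shift and J evolution, so the weak-coupling
    echo-modulation closed forms hold exactly.  Used for oracle tests and for
    idealized editing-yield calculations.
    """

    lo_ppm: float
    hi_ppm: float

    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.hi_ppm <= self.lo_ppm:
            raise ValueError("band must have hi_ppm > lo_ppm")

    def propagator(self, system: SpinSystem, b0_offset_ppm: float = 0.0) -> np.ndarray:
        n = system.n_spins
        ix, _, _ = spin_operators(n)
        u = np.eye(2**n, dtype=complex)
        for k in range(n):
            ppm = system.shifts_ppm[k] + b0_offset_ppm
            if self.lo_ppm <= ppm <= self.hi_ppm:
                u = _propagator(np.asarray(ix[k]), np.pi) @ u
        return u


@dataclass
class FID:
    """Complex time-domain signal with dwell time and ppm reference of 0 Hz."""

    samples: np.ndarray
    dwell: float
    ref_ppm: float = REF_PPM
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=complex)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("FID samples must be finite")
        if self.dwell <= 0:
            raise ValueError("dwell must be positive")


@dataclass
class Spectrum:
    """Complex spectrum on a descending ppm axis."""

    ppm: np.ndarray
    intensity: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=complex)
        if self.ppm.size != self.intensity.size:
            raise ValueError("axis and intensity must have equal length")
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")

    def window(self, lo_ppm: float, hi_ppm: float) -> np.ndarray:
        """Boolean mask of points with lo <= ppm <= hi."""
        if hi_ppm <= lo_ppm:
            raise ValueError("empty window")
        return (self.ppm >= lo_ppm) & (self.ppm <= hi_ppm)

    def integral(self, lo_ppm: float, hi_ppm: float) -> complex:
        """Complex integral over the window (trapezoid on the ppm axis)."""
        m = self.window(lo_ppm, hi_ppm)
        dppm = abs(float(np.mean(np.diff(self.ppm))))
        return complex(np.sum(self.intensity[m]) * dppm)

    def abs_integral(self, lo_ppm: float, hi_ppm: float) -> float:
        m = self.window(lo_ppm, hi_ppm)
        dppm = abs(float(np.mean(np.diff(self.ppm))))
        return float(np.sum(np.abs(self.intensity[m])) * dppm)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"ppm": self.ppm, "re": self.intensity.real, "im": self.intensity.imag}
        )


def hamiltonian(
    system: SpinSystem,
    b0_offset_ppm: float = 0.0,
    ref_ppm: float = REF_PPM,
    hz_per_ppm: float = HZ_PER_PPM,
) -> np.ndarray:
    """Rotating-frame Hamiltonian (rad/s) with strong-coupling (Ik.Il) terms."""
    n = system.n_spins
    ix, iy, iz = spin_operators(n)
    h = np.zeros((2**n, 2**n), dtype=complex)
    for k in range(n):
        offset_hz = (system.shifts_ppm[k] + b0_offset_ppm - ref_ppm) * hz_per_ppm
        h += 2.0 * np.pi * offset_hz * iz[k]
    for k in range(n):
        for l in range(k + 1, n):
            if system.j_hz[k, l] != 0.0:
                h += (2.0 * np.pi * system.j_hz[k, l]) * (
                    ix[k] @ ix[l] + iy[k] @ iy[l] + iz[k] @ iz[l]
                )
    return h


def _propagator(h: np.ndarray, t: float) -> np.ndarray:
    """U = exp(-i H t) via Hermitian eigendecomposition."""
    evals, vecs = np.linalg.eigh(h)
    return (vecs * np.exp(-1j * evals * t)) @ vecs.conj().T


def evolve(rho: np.ndarray, h: np.ndarray, t: float) -> np.ndarray:
    """Unitary evolution rho -> U rho U+ under H for time t."""
    if rho.shape != h.shape:
        raise ValueError("dimension mismatch between state and Hamiltonian")
    if t == 0.0:
        return rho.copy()
    u = _propagator(h, t)
    return u @ rho @ u.conj().T


def shaped_pulse_propagator(
    system: SpinSystem,
    w: RFWaveform,
    b1_scale: float = 1.0,
    b0_offset_ppm: float = 0.0,
) -> np.ndarray:
    """Total propagator of a shaped pulse, including free evolution during it.

    Piecewise-constant: per sample, H_k = H0 + w1x(t_k)*Fx + w1y(t_k)*Fy with
    the carrier ramp applied to the samples.  Raises on Nyquist violation.
    """
    h0 = hamiltonian(system, b0_offset_ppm=b0_offset_ppm)
    n = system.n_spins
    ix, iy, _ = spin_operators(n)
    fx = sum(ix)
    fy = sum(iy)
    # Nyquist check: fastest rotation must be well sampled
    f_sweep = np.max(np.abs(np.diff(np.unwrap(np.angle(w.samples + 1e-300))))) / (
        2 * np.pi * w.dt
    ) if w.n_samples > 1 else 0.0
    f_span = np.max(np.abs((system.shifts_ppm - REF_PPM) * HZ_PER_PPM)) + abs(
        w.carrier_offset_hz
    )
    if w.dt * (f_sweep + f_span) > 0.45:
        raise ValueError("pulse too coarsely sampled for this spin system (Nyquist)")
    t = w.times
    b1 = w.samples * b1_scale * np.exp(1j * 2.0 * np.pi * w.carrier_offset_hz * t)
    u = np.eye(2**n, dtype=complex)
    for k in range(w.n_samples):
        hk = h0 + b1[k].real * fx + b1[k].imag * fy
        u = _propagator(hk, w.dt) @ u
    return u


def apply_shaped_pulse(
    rho: np.ndarray,
    system: SpinSystem,
    w: RFWaveform,
    b1_scale: float = 1.0,
    b0_offset_ppm: float = 0.0,
) -> np.ndarray:
    """Propagate the state through a shaped pulse (no pathway filtering)."""
    u = shaped_pulse_propagator(system, w, b1_scale, b0_offset_ppm)
    return u @ rho @ u.conj().T


def coherence_filter_through_pulse(
    rho: np.ndarray, u: np.ndarray, orders: np.ndarray
) -> np.ndarray:
    """Apply a refocusing-pulse propagator keeping only p -> -p transfers.

    rho_out = sum_p P_{-p}( U P_p(rho) U+ ): the ideal-crusher model of a
    symmetric spoiler pair around a refocusing pulse.
    """
    out = np.zeros_like(rho)
    for p in np.unique(np.round(orders * 2) / 2):
        mask_in = np.isclose(orders, p)
        if not np.any(mask_in & (rho != 0)):
            continue
        rho_p = np.where(mask_in, rho, 0.0)
        transferred = u @ rho_p @ u.conj().T
        out += np.where(np.isclose(orders, -p), transferred, 0.0)
    return out


def run_slow_acquisition(
    system: SpinSystem,
    refocus_pulse: "RFWaveform | IdealBandPulse",
    timing: SequenceTiming,
    excitation: RFWaveform | None = None,
    n_points: int = 1024,
    sweep_hz: float = 1280.0,
    b1_scale: float = 1.0,
    b0_offset_ppm: float = 0.0,
    return_state: bool = False,
):
    """One SLOW acquisition: 90deg -> d1 -> CSAP -> d2 -> CSAP -> d3 -> acquire.

    The excitation is an ideal 90deg rotation about +y unless a shaped
    excitation waveform is supplied.  Acquisition defaults follow the
    sequence (1024 complex points, 1.28 kHz sweep, reference at 3 ppm).
    Returns the FID; with ``return_state=True`` also the density matrix at
    the start of acquisition (useful for product-operator oracles).
    """
    if n_points <= 0 or sweep_hz <= 0:
        raise ValueError("acquisition window must be positive")
    n = system.n_spins
    ix, iy, iz = spin_operators(n)
    h0 = hamiltonian(system, b0_offset_ppm=b0_offset_ppm)
    orders = _coherence_orders(n)

    rho = sum(iz)
    if excitation is None:
        u90 = _propagator(sum(iy), np.pi / 2.0)  # 90deg about +y: Iz -> Ix
        rho = u90 @ rho @ u90.conj().T
    else:
        rho = apply_shaped_pulse(rho, system, excitation, b1_scale, b0_offset_ppm)

    d1, d2, d3 = timing.delays
    if isinstance(refocus_pulse, IdealBandPulse):
        u_pulse = refocus_pulse.propagator(system, b0_offset_ppm)
    else:
        u_pulse = shaped_pulse_propagator(system, refocus_pulse, b1_scale, b0_offset_ppm)
    rho = evolve(rho, h0, d1)
    rho = coherence_filter_through_pulse(rho, u_pulse, orders)
    rho = evolve(rho, h0, d2)
    rho = coherence_filter_through_pulse(rho, u_pulse, orders)
    rho = evolve(rho, h0, d3)

    fplus = sum(ix) + 1j * np.asarray(sum(iy))
    dwell = 1.0 / sweep_hz
    u_dwell = _propagator(h0, dwell)
    sig = np.empty(n_points, dtype=complex)
    r = rho
    for k in range(n_points):
        sig[k] = np.trace(r @ fplus)
        if k + 1 < n_points:
            r = u_dwell @ r @ u_dwell.conj().T
    fid = FID(sig, dwell, meta={"system": system.name, "te_s": timing.te_s,
                                "b0_offset_ppm": b0_offset_ppm})
    if return_state:
        return fid, rho
    return fid


def fid_to_spectrum(
    fid: FID,
    apodization_hz: float = 2.0,
    zero_fill: int = 2,
    first_point: str = "half",
) -> Spectrum:
    """Exponential apodization, zero-fill, DFT, ppm axis (descending).

    Apodization is Lorentzian line broadening of FWHM ``apodization_hz``.
    ``first_point="half"`` (default) scales the first FID point by 0.5 — the
    standard correction that removes the constant baseline offset of the
    one-sided DFT (essential for window integrals).  With
    ``first_point="full"`` the raw DFT identity mean(spectrum) == fid[0]
    holds exactly instead.
    """
    if apodization_hz < 0:
        raise ValueError("apodization must be non-negative")
    if zero_fill < 1:
        raise ValueError("zero_fill must be >= 1")
    if first_point not in ("half", "full"):
        raise ValueError("first_point must be 'half' or 'full'")
    n = fid.samples.size
    t = np.arange(n) * fid.dwell
    data = fid.samples * np.exp(-np.pi * apodization_hz * t)
    if first_point == "half":
        data = data.copy()
        data[0] *= 0.5
    nfft = int(n * zero_fill)
    spec = np.fft.fftshift(np.fft.fft(data, n=nfft))
    freqs = np.fft.fftshift(np.fft.fftfreq(nfft, d=fid.dwell))
    ppm = fid.ref_ppm + freqs / HZ_PER_PPM
    # descending display order
    meta = dict(fid.meta)
    meta["apodization_hz"] = apodization_hz
    return Spectrum(ppm[::-1].copy(), spec[::-1].copy(), meta=meta)
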