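import numpy as np
import pytest

from slowedit import (
    BandSpec,
    EditingScheme,
    SpinSystem,
    design_band_pulse,
    get_scheme,
    get_system,
    ppm_to_hz,
)

J_AX = 7.35  # Hz, GABA-like vicinal coupling used by the toy systems


@pytest.fixture(scope="session")
def scheme2():
    return get_scheme("scheme2")


@pytest.fixture(scope="session")
def scheme2_full_pulse(scheme2):
    """Reconstructed scheme-2 editing-full CSAP at 2x the adiabatic threshold."""
    return design_band_pulse(scheme2.full, threshold_multiple=2.0, n_samples=2048)


@pytest.fixture(scope="session")
def scheme2_partial_pulse(scheme2):
    return design_band_pulse(scheme2.partial, threshold_multiple=2.0, n_samples=512)


@pytest.fixture(scope="session")
def water_band_pulse():
    """Water-suppressing configuration: 31 ms pair refocusing 1.8-4.2 ppm only."""
    band = BandSpec(3.0, 712.8, 0.031, passband_ppm=(1.8, 4.2))
    return design_band_pulse(band, threshold_multiple=2.0, n_samples=2048)


@pytest.fixture(scope="session")
def gaba():
    return get_system("gaba")


@pytest.fixture()
def ax_system():
    """Weakly coupled two-spin system (GABA-like J, partner downfield/upfield)."""
    return SpinSystem("ax", [3.0, 1.9], [[0.0, J_AX], [J_AX, 0.0]])


@pytest.fixture()
def ideal_wide_scheme():
    """Idealized editing scheme for closed-form oracles: instantaneous,
    perfectly selective bands around an AX pair at 4.2 / 1.8 ppm."""
    full = BandSpec(3.0, 1500.0, 0.001, passband_ppm=(1.0, 5.0))
    partial = BandSpec(3.3, 900.0, 0.001, passband_ppm=(2.4, 5.0))

    def make(te_s: float) -> EditingScheme:
        return EditingScheme("toy", full, partial, te_s)

    return make


@pytest.fixture()
def ax_far():
    """AX pair with 2.4 ppm separation (weak-coupling regime, J/dNu < 1%)."""
    return SpinSystem("ax_far", [4.2, 1.8], [[0.0, J_AX], [J_AX, 0.0]])
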