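"""Field and frame constants shared across the package.

The acquisition reference is placed at 3.0 ppm (not at water), matching the
carrier used for excitation, refocusing and acquisition in the sequence this
package models.  Offsets are expressed in Hz relative to that reference with
the convention that positive offset = downfield = higher ppm.
"""

#: Hz per ppm for protons at 7 T (gamma * B0 / 1e6).
HZ_PER_PPM: float = 297.0

#: Acquisition / pulse reference chemical shift (ppm).
REF_PPM: float = 3.0

#: Water resonance (ppm).
WATER_PPM: float = 4.7

#: Main lipid (methylene) resonance (ppm).
LIPID_PPM: float = 1.3


def ppm_to_hz(ppm: float, ref_ppm: float = REF_PPM, hz_per_ppm: float = HZ_PER_PPM) -> float:
    """Chemical shift (ppm) -> offset in Hz relative to the acquisition reference."""
    return (ppm - ref_ppm) * hz_per_ppm


def hz_to_ppm(hz: float, ref_ppm: float = REF_PPM, hz_per_ppm: float = HZ_PER_PPM) -> float:
    """Offset in Hz relative to the acquisition reference -> chemical shift (ppm)."""
    return ref_ppm + hz / hz_per_ppm
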