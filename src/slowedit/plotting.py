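"""Plot helpers writing standard image files (matplotlib, Agg backend)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .bloch import ResponseProfile
from .constants import hz_to_ppm


def plot_profile(profile: ResponseProfile, path, ppm_axis: bool = True) -> None:
    """Inversion/refocusing profile vs offset (first B1 scale if gridded)."""
    fig, ax = plt.subplots(figsize=(7, 4))
    x = (
        np.array([hz_to_ppm(h) for h in profile.offsets_hz])
        if ppm_axis
        else profile.offsets_hz
    )
    mz = np.atleast_2d(profile.mz)[0]
    eff = np.atleast_2d(profile.efficiency)[0]
    ax.plot(x, mz, label="Mz")
    ax.plot(x, eff, label="refocusing efficiency" + (" (pair)" if profile.pair else ""))
    ax.set_xlabel("ppm" if ppm_axis else "offset (Hz)")
    if ppm_axis:
        ax.invert_xaxis()
    ax.legend()
    ax.set_title(profile.label)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_edited(result, path) -> None:
    """Full, partial and difference spectra of one editing run."""
    fig, axes = plt.subplots(3, 1, figsize=(7, 7), sharex=True)
    for ax, name in zip(axes, ("full", "partial", "difference")):
        spec = getattr(result, name)
        ax.plot(spec.ppm, spec.intensity.real)
        ax.set_ylabel(name)
    axes[-1].set_xlabel("ppm")
    axes[-1].invert_xaxis()
    fig.suptitle(f"{result.system_name} / {result.scheme.name}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
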