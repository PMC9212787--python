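"""J-coupled spin systems of the edited brain metabolites.

Chemical shifts (ppm) and scalar couplings (Hz) are standard literature
values for the proton systems of the metabolites targeted by the editing
schemes (GABA, glutamate/glutamine, 2-hydroxyglutarate, phosphoethanolamine,
lactate) plus the common singlet references (creatine, NAA, glycine).
Heteronuclear couplings (e.g. the 31P couplings of PE) are not modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = ["SpinSystem", "METABOLITES", "get_system", "load_system", "save_system"]


@dataclass
class SpinSystem:
    """Chemical shifts (ppm) and symmetric scalar-coupling matrix (Hz)."""

    name: str
    shifts_ppm: np.ndarray
    j_hz: np.ndarray

    def __post_init__(self) -> None:
        self.shifts_ppm = np.atleast_1d(np.asarray(self.shifts_ppm, dtype=float))
        n = self.shifts_ppm.size
        if self.j_hz is None:
            self.j_hz = np.zeros((n, n))
        self.j_hz = np.asarray(self.j_hz, dtype=float)
        if self.j_hz.shape != (n, n):
            raise ValueError("j_hz must be n x n")
        if not np.allclose(self.j_hz, self.j_hz.T):
            raise ValueError("j_hz must be symmetric")
        if np.any(np.diag(self.j_hz) != 0):
            raise ValueError("j_hz must have zero diagonal")
        if np.any(self.shifts_ppm < 0) or np.any(self.shifts_ppm > 10):
            raise ValueError("shifts must lie within [0, 10] ppm")
        if n > 8:
            raise ValueError("at most 8 coupled spins (dense-matrix tractability)")

    @property
    def n_spins(self) -> int:
        return self.shifts_ppm.size

    def shifted(self, delta_ppm: float) -> "SpinSystem":
        """Copy with all resonances globally shifted (models a B0 offset)."""
        return SpinSystem(self.name, self.shifts_ppm + delta_ppm, self.j_hz.copy())


def _sym(n: int, entries: dict[tuple[int, int], float]) -> np.ndarray:
    j = np.zeros((n, n))
    for (a, b), v in entries.items():
        j[a, b] = j[b, a] = v
    return j


def _build_library() -> dict[str, SpinSystem]:
    lib: dict[str, SpinSystem] = {}

    # GABA: C4H2 (3.01, observed/edited), C3H2 (1.89, editing partner), C2H2 (2.28)
    shifts = [3.0128, 3.0128, 1.8890, 1.8890, 2.2840, 2.2840]
    j = _sym(6, {
        (0, 1): -12.02,           # geminal C4
        (2, 3): -13.81,           # geminal C3
        (4, 5): -12.02,           # geminal C2
        (0, 2): 7.35, (0, 3): 7.35, (1, 2): 7.35, (1, 3): 7.35,  # C4-C3 vicinal
        (2, 4): 7.35, (2, 5): 7.35, (3, 4): 7.35, (3, 5): 7.35,  # C3-C2 vicinal
    })
    lib["gaba"] = SpinSystem("gaba", shifts, j)

    # glutamate: H2, H3/H3', H4/H4'
    shifts = [3.7433, 2.0375, 2.1200, 2.3378, 2.3520]
    j = _sym(5, {
        (1, 2): -14.849,
        (0, 1): 7.331, (0, 2): 4.651,
        (1, 3): 6.413, (1, 4): 8.406,
        (2, 3): 8.478, (2, 4): 6.875,
        (3, 4): -15.915,
    })
    lib["glutamate"] = SpinSystem("glutamate", shifts, j)

    # glutamine
    shifts = [3.7530, 2.1290, 2.1090, 2.4320, 2.4540]
    j = _sym(5, {
        (1, 2): -14.504,
        (0, 1): 5.847, (0, 2): 6.500,
        (1, 3): 9.165, (1, 4): 6.347,
        (2, 3): 6.324, (2, 4): 9.209,
        (3, 4): -15.371,
    })
    lib["glutamine"] = SpinSystem("glutamine", shifts, j)

    # 2-hydroxyglutarate: H2 (4.02, edited), H3/H3', H4/H4'
    shifts = [4.0200, 1.8250, 1.9770, 2.2210, 2.2720]
    j = _sym(5, {
        (1, 2): -14.00,
        (0, 1): 7.00, (0, 2): 4.10,
        (1, 3): 10.5, (1, 4): 6.0,
        (2, 3): 4.5, (2, 4): 10.0,
        (3, 4): -15.00,
    })
    lib["2hg"] = SpinSystem("2hg", shifts, j)

    # phosphoethanolamine: N-CH2 (3.22, observed) and O-CH2 (3.98); 31P couplings omitted
    shifts = [3.2213, 3.2213, 3.9765, 3.9765]
    j = _sym(4, {
        (0, 1): -14.60,
        (2, 3): -14.60,
        (0, 2): 5.30, (0, 3): 6.70, (1, 2): 6.70, (1, 3): 5.30,
    })
    lib["pe"] = SpinSystem("pe", shifts, j)

    # lactate: CH quartet at 4.10, CH3 doublet at 1.31
    shifts = [4.0974, 1.3142, 1.3142, 1.3142]
    j = _sym(4, {(0, 1): 6.933, (0, 2): 6.933, (0, 3): 6.933})
    lib["lactate"] = SpinSystem("lactate", shifts, j)

    lib["creatine"] = SpinSystem("creatine", [3.0270, 3.9130], np.zeros((2, 2)))
    lib["naa"] = SpinSystem("naa", [2.0080], np.zeros((1, 1)))
    lib["glycine"] = SpinSystem("glycine", [3.5480], np.zeros((1, 1)))
    return lib


METABOLITES: dict[str, SpinSystem] = _build_library()


def get_system(name: str) -> SpinSystem:
    """Look up a metabolite spin system by name (case-insensitive)."""
    key = name.lower()
    if key not in METABOLITES:
        raise KeyError(f"unknown spin system '{name}'; known: {sorted(METABOLITES)}")
    s = METABOLITES[key]
    return SpinSystem(s.name, s.shifts_ppm.copy(), s.j_hz.copy())


def save_system(system: SpinSystem, path) -> None:
    """Write a spin system as structured text (YAML) config."""
    data = {
        "name": system.name,
        "shifts_ppm": [float(x) for x in system.shifts_ppm],
        "j_hz": [[float(x) for x in row] for row in system.j_hz],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_system(path) -> SpinSystem:
    """Read a spin system from YAML config (inverse of :func:`save_system`)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    unknown = set(data) - {"name", "shifts_ppm", "j_hz"}
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SpinSystem(data["name"], np.asarray(data["shifts_ppm"]), np.asarray(data["j_hz"]))
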