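"""Readers/writers and run manifests shared by the library and the CLI.

Conventions: numeric CSV output at 12 significant digits (byte-identical
reruns for identical config + seed); structured text config is YAML with the
field names of the corresponding dataclasses; bundled results go to an HDF5
container with metadata attributes; every CLI run writes a ``manifest.json``
(config echo, package version, seed) beside its outputs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

FLOAT_FMT = "%.12g"


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_pulse_design(design, path) -> None:
    """Write a pulse design dataclass as YAML (fields as in the dataclass)."""
    def clean(v):
        if isinstance(v, tuple):
            return [clean(x) for x in v]
        if isinstance(v, np.floating):
            return float(v)
        if isinstance(v, np.integer):
            return int(v)
        return v

    data = {k: clean(v) for k, v in dataclasses.asdict(design).items()}
    data["__type__"] = type(design).__name__
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_pulse_design(path):
    from . import pulses

    with open(path) as fh:
        data = yaml.safe_load(fh)
    typename = data.pop("__type__", "SechPulseDesign")
    cls = getattr(pulses, typename)
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys for {typename}: {sorted(unknown)}")
    if "t_range" in data and data["t_range"] is not None:
        data["t_range"] = tuple(data["t_range"])
    return cls(**data)


def write_manifest(out_dir, command: str, config: dict, seed: int | None) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "config": config,
        "package": "slowedit",
        "version": __version__,
        "seed": seed,
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path


def save_edited_result(result, path) -> None:
    """Bundle an EditedResult into an HDF5 container with metadata."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["scheme"] = result.scheme.name
        f.attrs["system"] = result.system_name
        f.attrs["te_s"] = result.scheme.te_s
        f.attrs["convention"] = result.convention
        f.create_dataset("ppm", data=result.full.ppm)
        for name in ("full", "partial", "difference"):
            spec = getattr(result, name)
            f.create_dataset(f"{name}/re", data=spec.intensity.real)
            f.create_dataset(f"{name}/im", data=spec.intensity.imag)


def load_edited_result_arrays(path) -> dict:
    """Read back the arrays of a bundled EditedResult (ppm + three spectra)."""
    import h5py

    out = {}
    with h5py.File(path, "r") as f:
        out["ppm"] = f["ppm"][:]
        for name in ("full", "partial", "difference"):
            out[name] = f[f"{name}/re"][:] + 1j * f[f"{name}/im"][:]
        out["meta"] = dict(f.attrs)
    return out


def spectra_frame(result) -> pd.DataFrame:
    """Long-format DataFrame of an EditedResult's three spectra."""
    frames = []
    for name in ("full", "partial", "difference"):
        spec = getattr(result, name)
        df = spec.to_frame()
        df.insert(0, "band", name)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
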