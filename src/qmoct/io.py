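"""File formats: delimited-text spectra, HDF5 datasets/maps, model checkpoints,
YAML object descriptions."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import yaml

from .forward_model import Layer, LayeredObject, SpectralGrid, Spectrum
from .network.model import ModelConfig, QmRegressor
from .profiles import DispersionMap, DispersionProfile, decode_gvd

__all__ = [
    "write_spectrum",
    "read_spectrum",
    "save_dataset",
    "load_dataset",
    "save_map",
    "load_map",
    "export_profile_csv",
    "save_model",
    "load_model",
    "object_from_yaml",
]


def write_spectrum(path: "str | Path", spectrum: Spectrum) -> None:
    """Two-column delimited text: wavenumber (rad/um) and intensity."""
    header = "wavenumber_rad_per_um\tintensity"
    np.savetxt(path, np.column_stack([spectrum.k, spectrum.intensity]),
               delimiter="\t", header=header)


def read_spectrum(path: "str | Path", grid: SpectralGrid | None = None) -> Spectrum:
    data = np.loadtxt(path)
    if data.ndim != 2 or data.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns (wavenumber, intensity)")
    return Spectrum(k=data[:, 0], intensity=data[:, 1], grid=grid)


def save_dataset(
    path: "str | Path",
    pairs: Iterable,
    meta: dict | None = None,
) -> int:
    """Write (stack, profile) pairs to HDF5 datasets /stacks and /profiles.

    Accepts the lazy stream from ``make_dataset``; returns the number of
    pairs written.  ``meta`` is JSON-encoded into the /meta attribute.
    """
    stacks, profiles = [], []
    pitch = float("nan")
    for x, y in pairs:
        if hasattr(x, "values"):
            pitch = getattr(x, "depth_pitch_um", pitch)
            x = x.values
        stacks.append(np.asarray(x))
        profiles.append(np.asarray(getattr(y, "values", y)))
    with h5py.File(path, "w") as f:
        f.create_dataset("stacks", data=np.stack(stacks))
        f.create_dataset("profiles", data=np.stack(profiles))
        f.attrs["meta"] = json.dumps(meta or {})
        f.attrs["depth_pitch_um"] = pitch
    return len(stacks)


def load_dataset(path: "str | Path") -> tuple[np.ndarray, np.ndarray, dict]:
    with h5py.File(path, "r") as f:
        return (f["stacks"][...], f["profiles"][...],
                json.loads(f.attrs.get("meta", "{}")))


def save_map(path: "str | Path", dmap: DispersionMap, meta: dict | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("maps", data=dmap.values)
        f.attrs["depth_pitch_um"] = dmap.depth_pitch_um
        f.attrs["meta"] = json.dumps(meta or {})


def load_map(path: "str | Path") -> DispersionMap:
    with h5py.File(path, "r") as f:
        return DispersionMap(values=f["maps"][...],
                             depth_pitch_um=float(f.attrs["depth_pitch_um"]))


def export_profile_csv(path: "str | Path", profile: DispersionProfile) -> None:
    """Decoded profile as CSV: depth_um, gvd_fs2_per_mm."""
    depth = np.arange(len(profile)) * profile.depth_pitch_um
    np.savetxt(path, np.column_stack([depth, profile.decoded()]),
               delimiter=",", header="depth_um,gvd_fs2_per_mm", comments="")


def save_model(directory: "str | Path", model: QmRegressor) -> None:
    """Checkpoint: weights as .npz plus a JSON sidecar of the architecture."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz", **model.state_arrays())
    (directory / "config.json").write_text(model.config.to_json())


def load_model(directory: "str | Path") -> QmRegressor:
    directory = Path(directory)
    config = ModelConfig.from_json((directory / "config.json").read_text())
    model = QmRegressor(config)
    with np.load(directory / "weights.npz") as state:
        model.load_state_arrays(dict(state))
    return model


def object_from_yaml(path: "str | Path") -> LayeredObject:
    """Object description:

    .. code-block:: yaml

        front_distance_um: 218.0
        front_gvd: 0.0
        front_reflectivity: 0.5
        layers:
          - {thickness_um: 87.0, gvd: 5000.0, reflectivity: 0.6}
    """
    spec = yaml.safe_load(Path(path).read_text())
    layers = tuple(
        Layer(float(l["thickness_um"]), float(l["gvd"]), float(l["reflectivity"]))
        for l in spec.get("layers", [])
    )
    return LayeredObject(
        front_distance_um=float(spec["front_distance_um"]),
        layers=layers,
        front_gvd=float(spec.get("front_gvd", 0.0)),
        front_reflectivity=float(spec.get("front_reflectivity", 0.5)),
    )
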