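"""Dispersion profiles, maps and the two-interface area algebra.

A dispersion profile encodes depth-resolved group-velocity dispersion as a
vector on [0, 1]: beta2 = -5000 fs^2/mm maps to 0, 0 to 0.5 and
+5000 fs^2/mm to 1, pixel-aligned with the FFT-stack depth axis.  The
profile of a layered object is piecewise constant: the front-medium GVD up
to the first interface, each layer's GVD over its span, and 0 behind the
last interface.

For a two-interface object the parasitic autocorrelation peak splits the
predicted profile into four areas; the apparent GVD between the first
interface and the autocorrelation peak follows the mixing relation

    beta_area2 = (L_front beta_front - L_obj beta_obj) / (L_front - L_obj),

whose inversion recovers the object GVD from a predicted map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward_model import LayeredObject, SpectralGrid
from .processing import depth_axis

__all__ = [
    "GVD_MIN",
    "GVD_MAX",
    "DispersionProfile",
    "DispersionMap",
    "AreaModel",
    "SingularityError",
    "encode_gvd",
    "decode_gvd",
    "profile_from_object",
    "area2_gvd",
    "invert_area2",
    "map_mean_profile",
    "min_std_profile",
]

GVD_MIN = -5000.0
GVD_MAX = 5000.0


class SingularityError(ZeroDivisionError):
    """Degenerate area geometry (zero denominator in the mixing relation)."""


def encode_gvd(beta: "float | np.ndarray") -> "float | np.ndarray":
    """Affine map fs^2/mm -> [0, 1]; out-of-range values are clipped."""
    v = (np.asarray(beta, dtype=float) - GVD_MIN) / (GVD_MAX - GVD_MIN)
    v = np.clip(v, 0.0, 1.0)
    return float(v) if v.ndim == 0 else v


def decode_gvd(v: "float | np.ndarray") -> "float | np.ndarray":
    """Inverse affine map [0, 1] -> fs^2/mm."""
    arr = np.asarray(v, dtype=float)
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError("encoded dispersion values must lie in [0, 1]")
    beta = GVD_MIN + arr * (GVD_MAX - GVD_MIN)
    return float(beta) if beta.ndim == 0 else beta


@dataclass(frozen=True)
class DispersionProfile:
    """Unit-interval encoding of GVD versus depth pixel."""

    values: np.ndarray
    depth_pitch_um: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("profile must be 1-D")
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("profile values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    def decoded(self) -> np.ndarray:
        """Profile in fs^2/mm."""
        return decode_gvd(self.values)


@dataclass(frozen=True)
class DispersionMap:
    """Row-stacked dispersion profiles across adjacent A-scans."""

    values: np.ndarray
    depth_pitch_um: float = float("nan")

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("map must be 2-D (profiles x depth)")
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("map values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def n_profiles(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class AreaModel:
    """Geometry and GVD of the four-area reading of a two-interface object.

    ``l_front`` is the optical distance from zero optical path difference
    to the first interface, ``l_obj`` the object optical thickness;
    ``beta_front`` the front (interferometer imbalance) GVD and
    ``beta_obj`` the object GVD, all in fs^2/mm.
    """

    l_front: float
    l_obj: float
    beta_front: float = 0.0
    beta_obj: float = 0.0

    def __post_init__(self) -> None:
        if self.l_front <= 0 or self.l_obj <= 0:
            raise ValueError("lengths must be positive")


def area2_gvd(model: AreaModel) -> float:
    """Apparent GVD between the first interface and the autocorrelation peak."""
    denom = model.l_front - model.l_obj
    if denom == 0:
        raise SingularityError(
            "front distance equals object thickness: area-II GVD undefined"
        )
    return (model.l_front * model.beta_front
            - model.l_obj * model.beta_obj) / denom


def invert_area2(
    beta_area2: float, l_front: float, l_obj: float, beta_front: float = 0.0
) -> float:
    """Recover the object GVD from the apparent area-II GVD (exact inverse
    of :func:`area2_gvd`)."""
    if l_obj == 0:
        raise SingularityError("object thickness is zero: cannot invert")
    return (l_front * beta_front - beta_area2 * (l_front - l_obj)) / l_obj


def profile_from_object(
    obj: LayeredObject,
    grid: SpectralGrid | None = None,
    pad_length: int = 2048,
) -> DispersionProfile:
    """Ground-truth piecewise-constant dispersion profile of an object.

    Interface pixels are the depth-axis-rounded interface positions; a
    layer's encoded GVD occupies the half-open pixel span
    ``[interface_j, interface_{j+1})``.  Layers thinner than one pixel
    collapse onto a single pixel carrying the deeper layer's value.
    """
    grid = grid or SpectralGrid()
    pitch, axis = depth_axis(grid, pad_length)
    n = pad_length // 2
    pixels = np.rint(obj.interface_depths_um / pitch).astype(int)
    if np.any(pixels >= n):
        from .forward_model import DepthOverflowError

        raise DepthOverflowError(
            f"interface pixel {pixels.max()} beyond the {n}-pixel depth axis"
        )
    values = np.full(n, encode_gvd(0.0))
    values[: pixels[0]] = encode_gvd(obj.front_gvd)
    for j, lay in enumerate(obj.layers):
        values[pixels[j]: pixels[j + 1]] = encode_gvd(lay.gvd)
    return DispersionProfile(values=values, depth_pitch_um=pitch)


def map_mean_profile(
    dmap: DispersionMap, decoded: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel mean and standard deviation over the map's profiles.

    Statistics are computed in the encoded [0, 1] space; with
    ``decoded=True`` the mean is mapped back to fs^2/mm and the standard
    deviation scaled by the encoding span.
    """
    if dmap.n_profiles == 0:
        raise ValueError("empty dispersion map")
    mean = dmap.values.mean(axis=0)
    std = dmap.values.std(axis=0)
    if decoded:
        return decode_gvd(mean), std * (GVD_MAX - GVD_MIN)
    return mean, std


def min_std_profile(
    dmap: DispersionMap, window: tuple[int, int]
) -> tuple[int, np.ndarray]:
    """Profile with the smallest standard deviation inside a pixel window.

    ``window = (start, stop)`` is half-open; ties break to the lowest row
    index.  Returns ``(row_index, profile)``.
    """
    if dmap.n_profiles == 0:
        raise ValueError("empty dispersion map")
    a, b = window
    n = dmap.values.shape[1]
    if not (0 <= a < b <= n):
        raise ValueError(f"empty or out-of-range window {window} for length {n}")
    stds = dmap.values[:, a:b].std(axis=1)
    idx = int(np.argmin(stds))
    return idx, dmap.values[idx]
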