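"""Refractive-index and group-velocity-dispersion calculators for reference materials.

Each bundled material carries a Sellmeier expansion

    n^2(lambda) = 1 + sum_i B_i lambda^2 / (lambda^2 - C_i)

with ``lambda`` in micrometres and ``C_i`` in um^2.  Group velocity
dispersion is the second-order spectral phase per unit length,

    beta2 = lambda^3 / (2 pi c^2) * d^2 n / d lambda^2,

reported in fs^2/mm, the unit used throughout optical coherence
tomography dispersion work.  These values serve as quantitative anchors
when judging dispersion estimates produced from OCT data (e.g. sapphire
and BK7 test plates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "MaterialModel",
    "MATERIALS",
    "get_material",
    "refractive_index",
    "gvd",
    "WavelengthRangeError",
]

#: speed of light in vacuum, m/s
C_M_S = 299_792_458.0


class WavelengthRangeError(ValueError):
    """Wavelength outside a material's Sellmeier validity range."""


@dataclass(frozen=True)
class MaterialModel:
    """An immutable Sellmeier model with a validity interval.

    Parameters
    ----------
    material_id:
        Short name, e.g. ``"BK7"`` or ``"sapphire_ordinary"``.
    sellmeier_coefficients:
        Tuple of ``(B_i, C_i)`` pairs; ``B_i`` dimensionless, ``C_i`` in um^2.
        An empty tuple models vacuum (n = 1 exactly).
    valid_range:
        ``(lambda_min, lambda_max)`` in micrometres.
    """

    material_id: str
    sellmeier_coefficients: tuple[tuple[float, float], ...]
    valid_range: tuple[float, float] = (0.3, 2.0)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sellmeier_coefficients",
            tuple((float(b), float(c)) for b, c in self.sellmeier_coefficients),
        )

    def _check(self, wavelength_um: float, margin: float = 0.0) -> None:
        lo, hi = self.valid_range
        if not (lo + margin <= wavelength_um <= hi - margin):
            raise WavelengthRangeError(
                f"wavelength {wavelength_um} um outside the valid range "
                f"{self.valid_range} um of material {self.material_id!r}"
            )

    def n_squared(self, wavelength_um: float) -> float:
        lam2 = wavelength_um * wavelength_um
        return 1.0 + sum(b * lam2 / (lam2 - c) for b, c in self.sellmeier_coefficients)

    def d2n_dlambda2(self, wavelength_um: float) -> float:
        """Analytic second derivative of n with respect to wavelength (um^-2)."""
        lam = wavelength_um
        lam2 = lam * lam
        f = self.n_squared(lam)
        # f = n^2; term derivatives of B lam^2/(lam^2 - C)
        f1 = sum(-2.0 * b * c * lam / (lam2 - c) ** 2
                 for b, c in self.sellmeier_coefficients)
        f2 = sum(2.0 * b * c * (3.0 * lam2 + c) / (lam2 - c) ** 3
                 for b, c in self.sellmeier_coefficients)
        n = math.sqrt(f)
        # n = sqrt(f): n' = f'/(2n); n'' = f''/(2n) - f'^2/(4 n^3)
        return f2 / (2.0 * n) - f1 * f1 / (4.0 * n ** 3)


# Coefficient provenance (all standard catalogue / literature fits):
#  - BK7: Schott N-BK7 catalogue Sellmeier set.
#  - sapphire_ordinary: Malitson & Dodge ordinary-ray fit.
#  - fused_silica: Malitson (1965) fit.
#  - water: Daimon & Masumura (2007) 20 C four-term fit, visible/NIR.
MATERIALS: dict[str, MaterialModel] = {
    m.material_id: m
    for m in (
        MaterialModel("vacuum", (), valid_range=(0.0, math.inf)),
        MaterialModel(
            "BK7",
            (
                (1.03961212, 0.00600069867),
                (0.231792344, 0.0200179144),
                (1.01046945, 103.560653),
            ),
            valid_range=(0.30, 2.5),
        ),
        MaterialModel(
            "sapphire_ordinary",
            (
                (1.4313493, 0.0726631 ** 2),
                (0.65054713, 0.1193242 ** 2),
                (5.3414021, 18.028251 ** 2),
            ),
            valid_range=(0.20, 5.5),
        ),
        MaterialModel(
            "fused_silica",
            (
                (0.6961663, 0.0684043 ** 2),
                (0.4079426, 0.1162414 ** 2),
                (0.8974794, 9.896161 ** 2),
            ),
            valid_range=(0.21, 6.7),
        ),
        MaterialModel(
            "water",
            (
                (5.684027565e-1, 5.101829712e-3),
                (1.726177391e-1, 1.821153936e-2),
                (2.086189578e-2, 2.620722293e-2),
                (1.130748688e-1, 1.069792721e1),
            ),
            valid_range=(0.18, 1.1),
        ),
    )
}


def get_material(material: "MaterialModel | str") -> MaterialModel:
    if isinstance(material, MaterialModel):
        return material
    try:
        return MATERIALS[material]
    except KeyError:
        raise KeyError(
            f"unknown material {material!r}; available: {sorted(MATERIALS)}"
        ) from None


def refractive_index(material: "MaterialModel | str", wavelength_um: float) -> float:
    """Phase refractive index n(lambda) from the Sellmeier expansion."""
    model = get_material(material)
    model._check(wavelength_um)
    return math.sqrt(model.n_squared(wavelength_um))


def gvd(
    material: "MaterialModel | str",
    wavelength_um: float,
    *,
    method: str = "analytic",
    fd_step_um: float = 1e-4,
) -> float:
    """Group velocity dispersion beta2 in fs^2/mm.

    Parameters
    ----------
    method:
        ``"analytic"`` (closed-form second derivative of the Sellmeier sum)
        or ``"fd"`` (central finite differences with step ``fd_step_um``,
        at most 1 nm).
    """
    model = get_material(material)
    if not model.sellmeier_coefficients:  # vacuum
        model._check(wavelength_um)
        return 0.0
    if method == "analytic":
        model._check(wavelength_um)
        d2n = model.d2n_dlambda2(wavelength_um)
    elif method == "fd":
        if fd_step_um > 1e-3:
            raise ValueError("finite-difference step must be <= 1 nm")
        model._check(wavelength_um, margin=fd_step_um)
        h = fd_step_um
        n0 = refractive_index(model, wavelength_um)
        np_ = refractive_index(model, wavelength_um + h)
        nm_ = refractive_index(model, wavelength_um - h)
        d2n = (np_ - 2.0 * n0 + nm_) / (h * h)
    else:
        raise ValueError(f"unknown method {method!r}")
    # convert: lambda um -> m, d2n um^-2 -> m^-2; beta2 s^2/m -> fs^2/mm
    lam_m = wavelength_um * 1e-6
    d2n_si = d2n * 1e12
    beta2_si = lam_m ** 3 / (2.0 * math.pi * C_M_S ** 2) * d2n_si
    return beta2_si * 1e27
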