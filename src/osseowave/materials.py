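"""Tissue and metal property registry with derived poroelastic constants.

The simulator treats every biological tissue as a fluid-saturated linear
poroelastic solid (Biot) and every metal part (Ti-6Al-4V implant, Cu shock
wave applicator) as a non-porous elastoplastic solid.  The tabulated inputs
are the drained matrix properties (density, Young's modulus, Poisson's
ratio), the bulk modulus of the solid grains ``Ks``, porosity ``theta`` and
intrinsic permeability ``k_perm``; metals additionally carry a von Mises
yield stress ``sigma_y``.

Secondary constants are derived through the standard isotropic identities

    G = E / (2 (1 + nu)),      K = E / (3 (1 - 2 nu)),
    cp = sqrt((K + 4 G / 3) / rho)

and the linear-poroelastic closures

    alpha = 1 - K / Ks,        1 / M = theta / Kf + (alpha - theta) / Ks.

All quantities are SI internally; the registry accepts the conventional
table units (GPa for moduli, MPa for yield stress) when loading a config.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "Material",
    "Fluid",
    "DerivedModuli",
    "MaterialError",
    "load_material_table",
    "default_materials",
    "derived_moduli",
    "biot_constants",
    "phase_material_map",
    "REGION_BASE_MATERIALS",
]


class MaterialError(ValueError):
    """Raised for missing fields or non-physical material parameters."""


@dataclass(frozen=True)
class Material:
    """Drained elastic + poroelastic parameters of one tissue or metal.

    Parameters are SI: ``rho`` kg/m^3, ``E`` and ``Ks`` Pa, ``k_perm`` m^2,
    ``sigma_y`` Pa (metals only, ``None`` for tissues).
    """

    name: str
    rho: float
    E: float
    nu: float
    Ks: float | None = None
    theta: float = 0.0
    k_perm: float = 0.0
    sigma_y: float | None = None

    def __post_init__(self) -> None:
        def bad(msg: str) -> MaterialError:
            return MaterialError(f"material {self.name!r}: {msg}")

        if not self.rho > 0:
            raise bad(f"density must be positive, got {self.rho}")
        if not self.E > 0:
            raise bad(f"Young's modulus must be positive, got {self.E}")
        if not 0 < self.nu < 0.5:
            raise bad(f"Poisson's ratio must lie in (0, 0.5), got {self.nu}")
        if not 0 <= self.theta < 1:
            raise bad(f"porosity must lie in [0, 1), got {self.theta}")
        if self.k_perm < 0:
            raise bad(f"permeability must be non-negative, got {self.k_perm}")
        if self.Ks is not None:
            if not self.Ks > 0:
                raise bad(f"grain bulk modulus must be positive, got {self.Ks}")
            if self.K > self.Ks * (1 + 1e-12):
                raise bad(
                    f"drained bulk modulus K={self.K:.4g} Pa exceeds grain "
                    f"modulus Ks={self.Ks:.4g} Pa"
                )
        if self.sigma_y is not None and not self.sigma_y > 0:
            raise bad(f"yield stress must be positive, got {self.sigma_y}")

    @property
    def G(self) -> float:
        """Shear modulus, Pa."""
        return self.E / (2.0 * (1.0 + self.nu))

    @property
    def K(self) -> float:
        """Drained bulk modulus, Pa."""
        return self.E / (3.0 * (1.0 - 2.0 * self.nu))

    @property
    def porous(self) -> bool:
        """True for fluid-saturated tissues (grain modulus tabulated)."""
        return self.Ks is not None and self.theta > 0


@dataclass(frozen=True)
class Fluid:
    """Interstitial fluid (defaults: salt water)."""

    Kf: float = 2.4e9      # bulk modulus, Pa
    rho_f: float = 1000.0  # density, kg/m^3
    eta_f: float = 1e-3    # dynamic viscosity, Pa s

    def __post_init__(self) -> None:
        if min(self.Kf, self.rho_f, self.eta_f) <= 0:
            raise MaterialError("fluid parameters must be strictly positive")


@dataclass(frozen=True)
class DerivedModuli:
    """Secondary constants used by the engine."""

    G: float       # shear modulus, Pa
    K: float       # drained bulk modulus, Pa
    alpha: float   # Biot coefficient
    M: float       # Biot modulus, Pa (0 for non-porous solids)
    cp: float      # drained P-wave speed, m/s


def derived_moduli(m: Material, fluid: Fluid | None = None) -> DerivedModuli:
    """Compute shear/bulk moduli, wave speed and Biot constants.

    Metals (non-porous) get ``alpha = 0`` and ``M = 0``: their pore pressure
    is identically zero in the engine.
    """
    G, K = m.G, m.K
    cp = math.sqrt((K + 4.0 * G / 3.0) / m.rho)
    if m.porous:
        alpha, M = biot_constants(m, fluid or Fluid())
    else:
        alpha, M = 0.0, 0.0
    return DerivedModuli(G=G, K=K, alpha=alpha, M=M, cp=cp)


def biot_constants(m: Material, f: Fluid) -> tuple[float, float]:
    """Biot coefficient and modulus: alpha = 1 - K/Ks, 1/M = theta/Kf + (alpha-theta)/Ks."""
    if not m.porous:
        raise MaterialError(f"material {m.name!r} is not porous")
    alpha = 1.0 - m.K / m.Ks
    # alpha >= theta holds only under micro-homogeneous grain assumptions;
    # several tabulated soft tissues sit slightly below it.  The hard
    # requirement is a positive storage modulus.
    inv_M = m.theta / f.Kf + (alpha - m.theta) / m.Ks
    if inv_M <= 0:
        raise MaterialError(
            f"material {m.name!r}: non-positive Biot storage modulus "
            f"(porosity {m.theta} inconsistent with grain modulus {m.Ks:g} Pa)"
        )
    return alpha, 1.0 / inv_M


# ---------------------------------------------------------------------------
# Tabulated properties.  Tissues: density kg/m^3, E GPa, nu, Ks GPa, porosity,
# permeability m^2.  Metals: density, E GPa, nu, yield stress MPa.
# ---------------------------------------------------------------------------

_TISSUE_ROWS: dict[str, tuple[float, float, float, float, float, float]] = {
    #                 rho     E     nu    Ks    theta  k
    "Dentin":        (2100, 18.0, 0.27, 50.0, 0.02, 2.0e-16),
    "Cortical":      (1850, 14.7, 0.32, 17.0, 0.04, 1.0e-20),
    "Cancellous":    (700,   3.5, 0.32, 15.0, 0.70, 3.7e-16),
    "PDL":           (800,   1.0, 0.30,  2.3, 0.80, 1.0e-15),
    "Fibrous":       (800,   0.6, 0.29,  2.3, 0.80, 1.0e-17),
    "Primary matrix": (800,  0.6, 0.29,  2.3, 0.80, 1.0e-17),
    "Granulation":   (800,   0.3, 0.29,  2.3, 0.80, 1.0e-17),
    "Woven bone":    (800,   1.2, 0.30,  4.6, 0.80, 1.0e-16),
}

_METAL_ROWS: dict[str, tuple[float, float, float, float]] = {
    #             rho     E      nu    sigma_y (MPa)
    "Ti-6Al-4V": (4500, 107.1, 0.31, 800.0),
    "Cu":        (8950, 111.4, 0.34, 80.0),
}

_GPA = 1e9
_MPA = 1e6

_TISSUE_FIELDS = ("rho", "E", "nu", "Ks", "theta", "k_perm")
_METAL_FIELDS = ("rho", "E", "nu", "sigma_y")


def _material_from_row(name: str, row: Mapping[str, float]) -> Material:
    is_metal = "sigma_y" in row and "Ks" not in row
    required = _METAL_FIELDS if is_metal else _TISSUE_FIELDS
    missing = [f for f in required if f not in row]
    if missing:
        raise MaterialError(f"material {name!r}: missing field(s) {missing}")
    try:
        if is_metal:
            return Material(
                name=name,
                rho=float(row["rho"]),
                E=float(row["E"]) * _GPA,
                nu=float(row["nu"]),
                sigma_y=float(row["sigma_y"]) * _MPA,
            )
        return Material(
            name=name,
            rho=float(row["rho"]),
            E=float(row["E"]) * _GPA,
            nu=float(row["nu"]),
            Ks=float(row["Ks"]) * _GPA,
            theta=float(row["theta"]),
            k_perm=float(row["k_perm"]),
            sigma_y=float(row["sigma_y"]) * _MPA if "sigma_y" in row else None,
        )
    except MaterialError:
        raise
    except (TypeError, ValueError) as exc:
        raise MaterialError(f"material {name!r}: {exc}") from exc


def load_material_table(
    config: Mapping[str, Mapping[str, float]] | str | Path,
) -> dict[str, Material]:
    """Build a Material registry from a mapping or a YAML file.

    Each row maps a material name to its table fields in conventional units
    (``E``/``Ks`` in GPa, ``sigma_y`` in MPa, ``rho`` kg/m^3, ``k_perm`` m^2).
    Rows with ``sigma_y`` and no ``Ks`` are metals.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, Mapping) or not config:
        raise MaterialError("material table must be a non-empty mapping")
    return {name: _material_from_row(name, row) for name, row in config.items()}


def default_materials() -> dict[str, Material]:
    """The built-in tissue + metal property table."""
    table: dict[str, dict[str, float]] = {}
    for name, (rho, E, nu, Ks, theta, k) in _TISSUE_ROWS.items():
        table[name] = dict(rho=rho, E=E, nu=nu, Ks=Ks, theta=theta, k_perm=k)
    for name, (rho, E, nu, sy) in _METAL_ROWS.items():
        table[name] = dict(rho=rho, E=E, nu=nu, sigma_y=sy)
    return load_material_table(table)


# Region -> material assignment that does not depend on the healing phase.
# The gingiva is mapped to the fibrous-tissue row (soft connective tissue);
# the fixed base layer keeps the material of the underlying cancellous bone.
REGION_BASE_MATERIALS: dict[str, str] = {
    "gingiva": "Fibrous",
    "cortical": "Cortical",
    "cancellous": "Cancellous",
    "implant": "Ti-6Al-4V",
    "applicator": "Cu",
    "base": "Cancellous",
    "dentin": "Dentin",
    "pdl": "PDL",
}


def phase_material_map(phase: int, fibrous_interface: bool = True) -> dict[str, str]:
    """Region -> material mapping for an osseointegration phase.

    Phase 1 (osteoconduction): the peri-implant shell is primary matrix
    (blood clot with fibrin fibers).  Phase 2 (osteoinduction): granulation
    tissue with a thin 0.25 mm fibrous interface directly at the implant.
    Phase 3 (remodeling): woven bone, optionally keeping the fibrous
    interface (``fibrous_interface=False`` drops it).
    """
    if phase not in (1, 2, 3):
        raise ValueError(f"unknown osseointegration phase {phase!r}; expected 1, 2 or 3")
    mapping = dict(REGION_BASE_MATERIALS)
    if phase == 1:
        mapping["shell"] = "Primary matrix"
    elif phase == 2:
        mapping["shell"] = "Granulation"
        mapping["fibrous_interface"] = "Fibrous"
    else:
        mapping["shell"] = "Woven bone"
        mapping["fibrous_interface"] = "Fibrous" if fibrous_interface else "Woven bone"
    return mapping
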