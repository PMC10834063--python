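"""Constitutive parameter sets for the magnetostrictive core, the
piezoelectric shell, and the core-shell/coil geometry.

The default parameter sets describe a MetGlas 2628MB sphere (100 um
diameter) coated with a 37.5 um wurtzite AlN shell, driven by a symmetric
pair of current loops.  All quantities are SI.  Losses are stored as real
scalars; complex (lossy) moduli are formed on demand for frequency-domain
work via :func:`complex_stiffness` and :func:`complex_permittivity`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from .constants import EPS0

__all__ = [
    "MagnetostrictiveMaterial",
    "PiezoelectricMaterial",
    "CoreShellGeometry",
    "load_default_metglas",
    "load_default_aln",
    "default_geometry",
    "stiffness_from_compliance",
    "complex_stiffness",
    "complex_permittivity",
]


class MaterialError(ValueError):
    """Raised for invalid or inconsistent material parameter sets."""


def _as_matrix(x: Any, shape: tuple[int, int]) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.shape != shape:
        raise MaterialError(f"expected matrix of shape {shape}, got {a.shape}")
    return a


def _check_spd(m: np.ndarray, name: str, sym_tol: float = 1e-8) -> None:
    if not np.allclose(m, m.T, rtol=sym_tol, atol=0.0):
        raise MaterialError(f"{name} must be symmetric")
    eig = np.linalg.eigvalsh(0.5 * (m + m.T))
    if eig.min() <= 0.0:
        raise MaterialError(f"{name} must be positive definite (min eig {eig.min():g})")


@dataclass(frozen=True)
class MagnetostrictiveMaterial:
    """Anhysteretic magnetostrictive material (isotropic elasticity).

    Parameters
    ----------
    saturation_magnetization : float
        Ms, A/m.
    saturation_magnetostriction : float
        λs, dimensionless strain (e.g. 12e-6 for 12 ppm).
    initial_susceptibility : float
        χ0, dimensionless slope dM/dH at zero field.
    youngs_modulus, poisson_ratio, density :
        Isotropic elastic constants (Pa, -, kg/m³).
    electrical_conductivity : float
        S/m.
    relative_permittivity, relative_permeability : float
        Dimensionless.
    mechanical_loss : float
        Structural loss factor η (isotropic loss factor damping).
    remanent_magnetization : float
        Mr, A/m.  The anhysteretic model carries no remanence; fixed at 0.
    """

    saturation_magnetization: float
    saturation_magnetostriction: float
    initial_susceptibility: float
    youngs_modulus: float
    poisson_ratio: float
    density: float
    electrical_conductivity: float
    relative_permittivity: float = 1.0
    relative_permeability: float = 1.0
    mechanical_loss: float = 0.0
    remanent_magnetization: float = 0.0

    def __post_init__(self) -> None:
        if self.saturation_magnetization <= 0:
            raise MaterialError("Ms must be > 0")
        if self.saturation_magnetostriction <= 0:
            raise MaterialError("λs must be > 0")
        if self.initial_susceptibility <= 0:
            raise MaterialError("χ0 must be > 0")
        if not 0.0 < self.poisson_ratio < 0.5:
            raise MaterialError("Poisson ratio must lie in (0, 0.5)")
        if self.youngs_modulus <= 0 or self.density <= 0:
            raise MaterialError("Young's modulus and density must be > 0")
        if self.mechanical_loss < 0:
            raise MaterialError("mechanical loss factor must be >= 0")
        if self.remanent_magnetization != 0.0:
            raise MaterialError("the anhysteretic model requires Mr = 0")

    @property
    def shear_modulus(self) -> float:
        """G = E / (2(1+ν)), Pa."""
        return self.youngs_modulus / (2.0 * (1.0 + self.poisson_ratio))

    @property
    def shear_wave_speed(self) -> float:
        """c_s = sqrt(G/ρ), m/s."""
        return float(np.sqrt(self.shear_modulus / self.density))

    @property
    def pressure_wave_speed(self) -> float:
        """c_p = sqrt((λ+2G)/ρ), m/s."""
        e, nu = self.youngs_modulus, self.poisson_ratio
        m = e * (1.0 - nu) / ((1.0 + nu) * (1.0 - 2.0 * nu))
        return float(np.sqrt(m / self.density))

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "MagnetostrictiveMaterial":
        return cls(**d)


@dataclass(frozen=True)
class PiezoelectricMaterial:
    """Linear piezoelectric material in strain-charge (d) form.

    ``compliance_sE`` is the 6x6 elastic compliance at constant electric
    field (1/Pa), ``coupling_d`` the 3x6 piezoelectric charge matrix (C/N),
    ``permittivity_relative`` the 3x3 relative permittivity at constant
    stress.  ``dielectric_loss`` (tanδ) and ``mechanical_loss`` (η_s) are
    scalar loss factors applied as (1 - j·tanδ)·εT and (1 + j·η_s)·cE in
    frequency-domain work.
    """

    compliance_sE: np.ndarray
    coupling_d: np.ndarray
    permittivity_relative: np.ndarray
    dielectric_loss: float
    mechanical_loss: float
    density: float
    electrical_conductivity: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "compliance_sE", _as_matrix(self.compliance_sE, (6, 6)))
        object.__setattr__(self, "coupling_d", _as_matrix(self.coupling_d, (3, 6)))
        object.__setattr__(
            self, "permittivity_relative", _as_matrix(self.permittivity_relative, (3, 3))
        )
        _check_spd(self.compliance_sE, "compliance sE")
        _check_spd(self.permittivity_relative, "relative permittivity εT")
        if self.dielectric_loss < 0 or self.mechanical_loss < 0:
            raise MaterialError("loss factors must be >= 0")
        if self.density <= 0:
            raise MaterialError("density must be > 0")

    def to_dict(self) -> dict[str, Any]:
        return {
            "compliance_sE": self.compliance_sE.tolist(),
            "coupling_d": self.coupling_d.tolist(),
            "permittivity_relative": self.permittivity_relative.tolist(),
            "dielectric_loss": self.dielectric_loss,
            "mechanical_loss": self.mechanical_loss,
            "density": self.density,
            "electrical_conductivity": self.electrical_conductivity,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PiezoelectricMaterial":
        return cls(**d)


@dataclass(frozen=True)
class CoreShellGeometry:
    """Spherical core-shell device between a symmetric coil pair."""

    core_radius: float = 50e-6
    shell_thickness: float = 37.5e-6
    coil_separation: float = 800e-6
    coil_radius: float = 400e-6
    coil_current_amplitude: float = 0.1

    def __post_init__(self) -> None:
        for name in (
            "core_radius",
            "shell_thickness",
            "coil_separation",
            "coil_radius",
            "coil_current_amplitude",
        ):
            if getattr(self, name) <= 0:
                raise MaterialError(f"{name} must be strictly positive")
        if self.shell_thickness >= self.core_radius:
            raise MaterialError("shell_thickness must be smaller than core_radius")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "CoreShellGeometry":
        return cls(**d)


def load_default_metglas() -> MagnetostrictiveMaterial:
    """MetGlas 2628MB parameter set (core)."""
    return MagnetostrictiveMaterial(
        saturation_magnetization=700282.0,
        saturation_magnetostriction=12e-6,
        initial_susceptibility=200.0,
        youngs_modulus=152e9,
        poisson_ratio=0.22,
        density=7900.0,
        electrical_conductivity=7.25e5,
        relative_permittivity=1.0,
        relative_permeability=201.0,  # 1 + χ0
        mechanical_loss=1e-4,
        remanent_magnetization=0.0,
    )


def load_default_aln(s44: float = 8e-12, s66: float = 7.7e-12) -> PiezoelectricMaterial:
    """Wurtzite (6mm) AlN parameter set (shell).

    The two unlabeled shear compliances are assigned s44 = s55 = 8e-12 and
    s66 = 7.7e-12 1/Pa by default; the assignment is configurable because
    the source tabulation does not label them.
    """
    s11, s12, s13, s33 = 2.9e-12, -0.93e-12, -0.5e-12, 2.9e-12
    sE = np.array(
        [
            [s11, s12, s13, 0, 0, 0],
            [s12, s11, s13, 0, 0, 0],
            [s13, s13, s33, 0, 0, 0],
            [0, 0, 0, s44, 0, 0],
            [0, 0, 0, 0, s44, 0],
            [0, 0, 0, 0, 0, s66],
        ]
    )
    d15, d31, d33 = -3.8e-12, -1.9e-12, 5e-12
    d = np.array(
        [
            [0, 0, 0, 0, d15, 0],
            [0, 0, 0, d15, 0, 0],
            [d31, d31, d33, 0, 0, 0],
        ]
    )
    return PiezoelectricMaterial(
        compliance_sE=sE,
        coupling_d=d,
        permittivity_relative=9.0 * np.eye(3),
        dielectric_loss=1e-4,
        mechanical_loss=1e-4,
        density=3300.0,
        electrical_conductivity=1e-6,
    )


def default_geometry() -> CoreShellGeometry:
    """Reference device geometry: 100 um core, 37.5 um shell, 800 um coil gap."""
    return CoreShellGeometry()


def stiffness_from_compliance(mat: PiezoelectricMaterial) -> np.ndarray:
    """Elastic stiffness cE = inv(sE), Pa.

    Raises :class:`MaterialError` if the compliance is numerically singular.
    """
    sE = mat.compliance_sE
    if np.linalg.cond(sE) > 1e14:
        raise MaterialError("compliance matrix is singular or near-singular")
    return np.linalg.inv(sE)


def complex_stiffness(mat: PiezoelectricMaterial) -> np.ndarray:
    """Lossy stiffness (1 + j·η_s)·cE for frequency-domain use."""
    return (1.0 + 1j * mat.mechanical_loss) * stiffness_from_compliance(mat)


def complex_permittivity(mat: PiezoelectricMaterial) -> np.ndarray:
    """Lossy absolute permittivity (1 - j·tanδ)·ε0·εT, F/m."""
    return (1.0 - 1j * mat.dielectric_loss) * EPS0 * mat.permittivity_relative


def save_materials_json(
    path: str | Path,
    core: MagnetostrictiveMaterial,
    shell: PiezoelectricMaterial,
    geometry: CoreShellGeometry,
) -> None:
    payload = {
        "core": core.to_dict(),
        "shell": shell.to_dict(),
        "geometry": geometry.to_dict(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_materials_json(
    path: str | Path,
) -> tuple[MagnetostrictiveMaterial, PiezoelectricMaterial, CoreShellGeometry]:
    payload = json.loads(Path(path).read_text())
    return (
        MagnetostrictiveMaterial.from_dict(payload["core"]),
        PiezoelectricMaterial.from_dict(payload["shell"]),
        CoreShellGeometry.from_dict(payload["geometry"]),
    )
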