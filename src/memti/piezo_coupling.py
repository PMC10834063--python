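"""Strain transfer to the piezoelectric shell and the ME coupling coefficient.

The thin AlN shell is perfectly bonded to the core: the interface strain
equals the core surface strain reduced by the geometric transfer factor
R/(R + t).  At open circuit (D = 0, insulating shell, zero volume charge)
the strain-charge constitutive law gives the shell field

    E = −(ε0 εT)⁻¹ · d · σ,        σ = cE · ε_transferred,

and the magnetoelectric coupling coefficient is the small-signal slope of
the whole chain, α_ME = dE/dH, conventionally quoted in V/(m·Oe).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import A_PER_M_PER_OE, EPS0, MU0
from .magnetostriction import me_strain, solve_axial_magnetization
from .materials import (
    CoreShellGeometry,
    MagnetostrictiveMaterial,
    PiezoelectricMaterial,
    stiffness_from_compliance,
)

__all__ = [
    "CouplingResult",
    "CouplingSweep",
    "shell_stress_from_strain",
    "open_circuit_field",
    "me_coefficient",
    "me_coefficient_at_bias",
    "chain_electric_field",
    "strain_to_field_gain",
    "coupling_sweep",
]


def transfer_factor(geom: CoreShellGeometry) -> float:
    """Thin-shell geometric strain transfer factor R/(R + t)."""
    return geom.core_radius / (geom.core_radius + geom.shell_thickness)


def shell_stress_from_strain(
    core_strain: np.ndarray,
    geom: CoreShellGeometry,
    core_mat: MagnetostrictiveMaterial,
    shell_mat: PiezoelectricMaterial,
) -> np.ndarray:
    """Shell stress (Voigt, Pa) from the core magnetostrictive strain.

    Perfect bonding: the transferred strain is the core strain scaled by
    R/(R + t); the shell responds with its own stiffness.  Linear in the
    input strain.
    """
    eps = np.asarray(core_strain, dtype=float)
    c_e = stiffness_from_compliance(shell_mat)
    return c_e @ (transfer_factor(geom) * eps)


def open_circuit_field(sigma: np.ndarray, shell_mat: PiezoelectricMaterial) -> np.ndarray:
    """Open-circuit electric field in the shell, E = −(ε0 εT)⁻¹·d·σ (V/m)."""
    sigma = np.asarray(sigma, dtype=float)
    eps_abs = EPS0 * shell_mat.permittivity_relative
    return -np.linalg.solve(eps_abs, shell_mat.coupling_d @ sigma)


def strain_to_field_gain(
    geom: CoreShellGeometry,
    core_mat: MagnetostrictiveMaterial,
    shell_mat: PiezoelectricMaterial,
) -> float:
    """Scalar gain E_z / λ∥ of the linear shell chain (V/m per unit strain).

    The core strain for axial magnetization is λ∥·(−1/2, −1/2, 1, 0, 0, 0);
    the shell stress and open-circuit field are linear in it, so the axial
    field is a fixed multiple of λ∥.
    """
    basis = np.array([-0.5, -0.5, 1.0, 0.0, 0.0, 0.0])
    sigma = shell_stress_from_strain(basis, geom, core_mat, shell_mat)
    return float(open_circuit_field(sigma, shell_mat)[2])


def chain_electric_field(
    h_applied_z: float,
    core_mat: MagnetostrictiveMaterial,
    shell_mat: PiezoelectricMaterial,
    geom: CoreShellGeometry,
) -> np.ndarray:
    """Full static chain: applied axial H (A/m) → shell E field (V/m)."""
    m = solve_axial_magnetization(np.asarray([h_applied_z]), core_mat)[0]
    eps = me_strain(np.array([0.0, 0.0, m]), core_mat)
    sigma = shell_stress_from_strain(eps, geom, core_mat, shell_mat)
    return open_circuit_field(sigma, shell_mat)


def me_coefficient(de_dh: float) -> float:
    """Convert a field slope dE/dH from (V/m)/(A/m) to V/(m·Oe)."""
    return float(abs(de_dh)) * A_PER_M_PER_OE


def me_coefficient_at_bias(
    bias_B: float,
    core_mat: MagnetostrictiveMaterial,
    shell_mat: PiezoelectricMaterial,
    geom: CoreShellGeometry,
    dh: float = 10.0,
) -> float:
    """α_ME = |dE_z/dH| at an operating bias (applied flux density, T).

    Two-point central difference of the full chain around H = bias_B/μ0;
    ``dh`` is the probe half-step in A/m.

    Raises ``ValueError`` for a non-positive probe step.
    """
    if dh <= 0:
        raise ValueError("finite-difference step dh must be > 0")
    h0 = bias_B / MU0
    e_hi = chain_electric_field(h0 + dh, core_mat, shell_mat, geom)[2]
    e_lo = chain_electric_field(h0 - dh, core_mat, shell_mat, geom)[2]
    return me_coefficient((e_hi - e_lo) / (2.0 * dh))


@dataclass(frozen=True)
class CouplingResult:
    """ME coupling evaluated at one (bias, shell thickness) operating point."""

    alpha_me: float  # V/(m·Oe), magnitude
    e_surface_peak: float  # V/m
    e_surface_mean: float  # V/m
    shell_thickness: float  # m
    bias_B: float  # T
    drive_summary: str = ""

    def to_dict(self) -> dict:
        return {
            "alpha_me_V_per_m_Oe": self.alpha_me,
            "E_surface_peak_V_per_m": self.e_surface_peak,
            "E_surface_mean_V_per_m": self.e_surface_mean,
            "shell_thickness_m": self.shell_thickness,
            "bias_B_T": self.bias_B,
            "drive_summary": self.drive_summary,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


@dataclass(frozen=True)
class CouplingSweep:
    """Grid of coupling results over bias and shell thickness."""

    results: list  # of CouplingResult
    best: CouplingResult

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bias_T": [r.bias_B for r in self.results],
                "thickness_m": [r.shell_thickness for r in self.results],
                "alpha_me_V_per_m_Oe": [r.alpha_me for r in self.results],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def coupling_sweep(
    bias_range: np.ndarray,
    thickness_range: np.ndarray,
    core_mat: MagnetostrictiveMaterial,
    shell_mat: PiezoelectricMaterial,
    geom: CoreShellGeometry,
    drive_summary: str = "",
    probe_amplitude_T: float | None = None,
) -> CouplingSweep:
    """Evaluate α_ME on a (bias, thickness) grid; deterministic.

    ``probe_amplitude_T`` sets the AC probe amplitude used to report the
    surface-field excursion at each bias (defaults to the small-signal
    probe only).
    """
    results: list[CouplingResult] = []
    for thick in np.asarray(thickness_range, dtype=float):
        g = CoreShellGeometry(
            core_radius=geom.core_radius,
            shell_thickness=float(thick),
            coil_separation=geom.coil_separation,
            coil_radius=geom.coil_radius,
            coil_current_amplitude=geom.coil_current_amplitude,
        )
        for bias in np.asarray(bias_range, dtype=float):
            alpha = me_coefficient_at_bias(float(bias), core_mat, shell_mat, g)
            e_z = chain_electric_field(bias / MU0, core_mat, shell_mat, g)[2]
            if probe_amplitude_T:
                e_hi = chain_electric_field(
                    (bias + probe_amplitude_T) / MU0, core_mat, shell_mat, g
                )[2]
                peak = abs(e_hi - e_z)
            else:
                peak = abs(e_z)
            results.append(
                CouplingResult(
                    alpha_me=alpha,
                    e_surface_peak=float(peak),
                    e_surface_mean=float(abs(e_z)),
                    shell_thickness=float(thick),
                    bias_B=float(bias),
                    drive_summary=drive_summary,
                )
            )
    best = max(results, key=lambda r: r.alpha_me)
    return CouplingSweep(results=results, best=best)
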