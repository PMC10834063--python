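"""Free-vibration eigenfrequencies of the homogeneous isotropic elastic sphere.

Classical Lamb problem: traction-free boundary at r = R.  Torsional modes
satisfy the transcendental equation

    η j_l'(η) − j_l(η) = (l−1) j_l(η) − η j_{l+1}(η) = 0,   η = ωR/c_s,

and spheroidal modes the 2x2 determinant obtained from σ_rr = σ_rθ = 0
applied to the compressional (ξ = ωR/c_p) and shear (η) partial waves;
l = 0 (breathing) reduces to a single condition on ξ.  Roots are located by
dense linear scanning and polished with Brent's method; frequencies scale
exactly as 1/R.

Material loss enters as a uniform structural loss factor: the complex
stiffness c(1 + jη_mech) perturbs each real eigenfrequency to
f·(1 + j·η_mech/2), giving a damping-ratio floor ζ ≈ η_mech/2.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import spherical_jn

from .materials import MagnetostrictiveMaterial

__all__ = [
    "Mode",
    "ModeList",
    "sphere_mode_frequencies",
    "damping_ratio",
    "select_mti_pair",
    "torsional_characteristic",
    "spheroidal_characteristic",
    "ModeSelectionError",
]

Branch = Literal["torsional", "spheroidal"]


class ModeSelectionError(RuntimeError):
    """No mode pair satisfies the selection constraints."""


def _jl(l: int, x: np.ndarray) -> np.ndarray:
    return spherical_jn(l, x)


def _djl(l: int, x: np.ndarray) -> np.ndarray:
    return spherical_jn(l, x, derivative=True)


def _d2jl(l: int, x: np.ndarray) -> np.ndarray:
    # from the spherical Bessel ODE: x²y'' + 2xy' + (x² − l(l+1))y = 0
    return -2.0 / x * _djl(l, x) - (1.0 - l * (l + 1) / x**2) * _jl(l, x)


def torsional_characteristic(l: int, eta: np.ndarray) -> np.ndarray:
    """σ_rφ = 0 condition for torsional modes: η j_l'(η) − j_l(η)."""
    eta = np.asarray(eta, dtype=float)
    return eta * _djl(l, eta) - _jl(l, eta)


def spheroidal_characteristic(
    l: int, eta: np.ndarray, speed_ratio: float
) -> np.ndarray:
    """Traction determinant for spheroidal modes.

    ``eta`` is ωR/c_s and ``speed_ratio`` = c_s/c_p, so the compressional
    argument is ξ = η·c_s/c_p.  For l = 0 only the compressional wave
    exists and the single σ_rr condition is returned.
    """
    eta = np.asarray(eta, dtype=float)
    xi = eta * speed_ratio
    lam_over_mu = 1.0 / speed_ratio**2 - 2.0  # λ/μ = cp²/cs² − 2
    if l == 0:
        return -lam_over_mu * _jl(0, xi) + 2.0 * _d2jl(0, xi)
    a11 = xi**2 * (-lam_over_mu * _jl(l, xi) + 2.0 * _d2jl(l, xi))
    a12 = 2.0 * l * (l + 1) * (eta * _djl(l, eta) - _jl(l, eta))
    a21 = 2.0 * (xi * _djl(l, xi) - _jl(l, xi))
    a22 = (l * (l + 1) - 2.0) * _jl(l, eta) + eta**2 * _d2jl(l, eta)
    return a11 * a22 - a12 * a21


@dataclass(frozen=True)
class Mode:
    """One elastic eigenmode of the free sphere."""

    frequency: complex  # Hz; imag part from the structural loss factor
    branch: Branch
    angular_order: int  # l
    overtone: int  # 1-based radial overtone index within (branch, l)
    zeta: float  # damping ratio imag(f)/|f|

    @property
    def f_real(self) -> float:
        return float(self.frequency.real)


class ModeList:
    """Eigenmode collection, sorted by real frequency."""

    def __init__(self, modes: Sequence[Mode]):
        self.modes: list[Mode] = sorted(modes, key=lambda m: m.f_real)

    def __iter__(self) -> Iterator[Mode]:
        return iter(self.modes)

    def __len__(self) -> int:
        return len(self.modes)

    def __getitem__(self, i) -> Mode:
        return self.modes[i]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "f_real_Hz": [m.frequency.real for m in self.modes],
                "f_imag_Hz": [m.frequency.imag for m in self.modes],
                "branch": [m.branch for m in self.modes],
                "l": [m.angular_order for m in self.modes],
                "overtone": [m.overtone for m in self.modes],
                "zeta": [m.zeta for m in self.modes],
            }
        ).to_csv(path, index=False)


def _scan_roots(fun, eta_min: float, eta_max: float, n_grid: int) -> list[float]:
    """Dense sign-change scan followed by Brent polishing; deduplicated."""
    grid = np.linspace(eta_min, eta_max, n_grid)
    vals = fun(grid)
    sign = np.sign(vals)
    idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    roots = []
    for i in idx:
        r = brentq(lambda x: float(fun(np.asarray([x]))[0]), grid[i], grid[i + 1],
                   xtol=1e-14, rtol=4 * np.finfo(float).eps)
        if not roots or abs(r - roots[-1]) > 1e-8 * max(abs(r), 1.0):
            roots.append(r)
    return roots


def sphere_mode_frequencies(
    mat: MagnetostrictiveMaterial,
    radius: float,
    f_range: tuple[float, float],
    l_max: int = 6,
    points_per_decade: int = 20000,
) -> ModeList:
    """All torsional and spheroidal eigenfrequencies of the core in ``f_range``.

    Roots are counted from the lowest mode of each (branch, l) family so the
    overtone index is absolute, then filtered to the requested range.
    Torsional families start at l = 1 (the l = 1 fundamental is the trivial
    rigid rotation and is excluded by the η > 0 scan window); spheroidal
    families at l = 0, with near-zero rigid-body roots discarded.
    """
    f_lo, f_hi = f_range
    if f_lo <= 0 or f_hi <= f_lo:
        raise ValueError("f_range must be positive with f_hi > f_lo")
    c_s = mat.shear_wave_speed
    c_p = mat.pressure_wave_speed
    ratio = c_s / c_p
    if not np.isfinite(c_s) or c_s <= 0:
        raise ValueError("degenerate material: non-positive shear wave speed")

    eta_of_f = 2.0 * np.pi * radius / c_s
    eta_hi = f_hi * eta_of_f
    eta_start = 0.05  # excludes rigid-body zeros while catching all fundamentals
    decades = max(1.0, np.log10(eta_hi / eta_start))
    n_grid = int(points_per_decade * decades)

    loss = mat.mechanical_loss
    zeta = (loss / 2.0) / np.sqrt(1.0 + (loss / 2.0) ** 2)

    modes: list[Mode] = []
    for l in range(1, l_max + 1):
        for n, eta in enumerate(
            _scan_roots(lambda x: torsional_characteristic(l, x), eta_start, eta_hi, n_grid),
            start=1,
        ):
            f = eta / eta_of_f
            if f_lo <= f <= f_hi:
                modes.append(
                    Mode(
                        frequency=f * (1.0 + 0.5j * loss),
                        branch="torsional",
                        angular_order=l,
                        overtone=n,
                        zeta=zeta,
                    )
                )
    for l in range(0, l_max + 1):
        for n, eta in enumerate(
            _scan_roots(
                lambda x: spheroidal_characteristic(l, x, ratio), eta_start, eta_hi, n_grid
            ),
            start=1,
        ):
            f = eta / eta_of_f
            if f_lo <= f <= f_hi:
                modes.append(
                    Mode(
                        frequency=f * (1.0 + 0.5j * loss),
                        branch="spheroidal",
                        angular_order=l,
                        overtone=n,
                        zeta=zeta,
                    )
                )
    return ModeList(modes)


def damping_ratio(f_complex: complex) -> float:
    """ζ = imag(f)/|f|."""
    if f_complex == 0:
        raise ValueError("damping ratio undefined at zero frequency")
    return float(np.imag(f_complex) / np.abs(f_complex))


def select_mti_pair(
    modes: ModeList, min_separation: float, zeta_max: float
) -> tuple[float, float]:
    """Pick the two excitation frequencies for the MTI drive.

    Among modes with ζ ≤ ζ_max, returns the pair with separation at least
    ``min_separation`` and the lowest summed damping; ties break to the
    lower first frequency, then the lower second.
    """
    cands = [m for m in modes if m.zeta <= zeta_max]
    pairs = [
        (a.zeta + b.zeta, a.f_real, b.f_real)
        for i, a in enumerate(cands)
        for b in cands[i + 1 :]
        if abs(b.f_real - a.f_real) >= min_separation
    ]
    if not pairs:
        listing = ", ".join(f"{m.f_real/1e6:.2f} MHz (ζ={m.zeta:.2e})" for m in cands)
        raise ModeSelectionError(
            f"no mode pair with separation ≥ {min_separation:g} Hz and ζ ≤ {zeta_max:g}; "
            f"candidates: [{listing}]"
        )
    pairs.sort()
    _, f1, f2 = pairs[0]
    return f1, f2
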