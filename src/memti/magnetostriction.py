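"""Nonlinear static magnetization and magnetostrictive strain of the core.

The core sphere is treated as a single uniformly magnetized macro-spin with
the exact sphere demagnetizing factor N = 1/3.  The anhysteretic
magnetization follows a Langevin law whose argument is scaled so that the
initial susceptibility equals the material's χ0,

    M = Ms · L(3 χ0 |H_eff| / Ms) · Ĥ_eff,      L(x) = coth x − 1/x,

and the magnetostrictive strain is the deviatoric quadratic form

    ε_me = (3/2) (λs / Ms²) · dev(M ⊗ M),

which saturates at λs along the magnetization axis.  External stress feeds
back on the effective field as H_eff = H + 3 λs/(μ0 Ms²) · S·M.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import MU0
from .materials import MagnetostrictiveMaterial

__all__ = [
    "langevin",
    "dlangevin",
    "magnetization_of_field",
    "me_strain",
    "effective_field",
    "self_consistent_state",
    "solve_axial_magnetization",
    "bias_sweep",
    "MagnetizationState",
    "BiasCurve",
    "ConvergenceError",
]

#: Sphere demagnetizing factor.
DEMAG_SPHERE = 1.0 / 3.0


class ConvergenceError(RuntimeError):
    """Self-consistent magnetization iteration failed to converge."""

    def __init__(self, message: str, residual: float):
        super().__init__(f"{message} (last residual {residual:.3e})")
        self.residual = residual


def langevin(x):
    """Langevin function L(x) = coth(x) − 1/x.

    Odd, monotone increasing, |L| < 1.  Evaluated by series x/3 − x³/45 for
    |x| < 1e-4 for numerical stability (L(0) = 0 exactly).
    """
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-4
    xs = x[small]
    out[small] = xs / 3.0 - xs**3 / 45.0
    xl = x[~small]
    out[~small] = 1.0 / np.tanh(xl) - 1.0 / xl
    return out if out.ndim else float(out)


def dlangevin(x):
    """Derivative L'(x) = 1/x² − csch²(x); L'(0) = 1/3."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-4
    xs = x[small]
    out[small] = 1.0 / 3.0 - xs**2 / 15.0
    xl = x[~small]
    # 1/sinh² overflows for |x| > ~355; there L' ~ 1/x² exactly to double precision
    big = np.abs(xl) > 350.0
    sinh_sq = np.empty_like(xl)
    sinh_sq[~big] = np.sinh(xl[~big]) ** 2
    r = np.empty_like(xl)
    r[~big] = 1.0 / xl[~big] ** 2 - 1.0 / sinh_sq[~big]
    r[big] = 1.0 / xl[big] ** 2
    out[~small] = r
    return out if out.ndim else float(out)


def magnetization_of_field(h_eff: np.ndarray, mat: MagnetostrictiveMaterial) -> np.ndarray:
    """Anhysteretic magnetization vector for a given effective field (A/m).

    The Langevin argument 3 χ0 |H_eff| / Ms makes the small-field slope equal
    the initial susceptibility χ0; |M| < Ms always.
    """
    h_eff = np.asarray(h_eff, dtype=float)
    ms, chi0 = mat.saturation_magnetization, mat.initial_susceptibility
    h_mag = np.linalg.norm(h_eff)
    if h_mag == 0.0:
        return np.zeros(3)
    return ms * langevin(3.0 * chi0 * h_mag / ms) * (h_eff / h_mag)


def me_strain(m: np.ndarray, mat: MagnetostrictiveMaterial) -> np.ndarray:
    """Magnetostrictive strain, Voigt 6-vector (ε11, ε22, ε33, 2ε23, 2ε13, 2ε12).

    ε_me = (3/2)(λs/Ms²)·dev(M⊗M): traceless, quadratic (even) in M, and equal
    to λs along M at saturation.
    """
    m = np.asarray(m, dtype=float)
    ms, lam_s = mat.saturation_magnetization, mat.saturation_magnetostriction
    outer = np.outer(m, m)
    dev = outer - np.trace(outer) / 3.0 * np.eye(3)
    eps = 1.5 * lam_s / ms**2 * dev
    # engineering shear strains (factor 2) in Voigt positions 4..6
    return np.array(
        [eps[0, 0], eps[1, 1], eps[2, 2], 2 * eps[1, 2], 2 * eps[0, 2], 2 * eps[0, 1]]
    )


def _voigt_to_tensor(s: np.ndarray) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    return np.array(
        [
            [s[0], s[5], s[4]],
            [s[5], s[1], s[3]],
            [s[4], s[3], s[2]],
        ]
    )


def effective_field(
    h: np.ndarray, stress: np.ndarray, m: np.ndarray, mat: MagnetostrictiveMaterial
) -> np.ndarray:
    """Effective field H_eff = H + 3λs/(μ0 Ms²)·S·M (stress in Voigt order, Pa)."""
    h = np.asarray(h, dtype=float)
    m = np.asarray(m, dtype=float)
    s_tensor = _voigt_to_tensor(stress)
    ms, lam_s = mat.saturation_magnetization, mat.saturation_magnetostriction
    return h + 3.0 * lam_s / (MU0 * ms**2) * s_tensor @ m


@dataclass(frozen=True)
class MagnetizationState:
    """Converged self-consistent magnetization state of the macro-spin sphere."""

    applied_field: np.ndarray  # H applied, A/m
    internal_field: np.ndarray  # H_applied − N·M, A/m
    effective_field: np.ndarray  # internal field plus stress feedback, A/m
    magnetization: np.ndarray  # A/m
    strain_me: np.ndarray  # Voigt 6-vector, dimensionless
    residual: float  # |ΔM|/Ms of the last iterate

    @property
    def lambda_parallel(self) -> float:
        """Strain component along the magnetization axis (= ε_zz for M ∥ z)."""
        m = self.magnetization
        n = np.linalg.norm(m)
        if n == 0.0:
            return 0.0
        mh = m / n
        eps = _voigt_to_tensor(self.strain_me * np.array([1, 1, 1, 0.5, 0.5, 0.5]))
        return float(mh @ eps @ mh)


def self_consistent_state(
    h_applied: np.ndarray,
    s_ext: np.ndarray | None,
    mat: MagnetostrictiveMaterial,
    demag_factor: float = DEMAG_SPHERE,
    tol: float = 1e-10,
    max_iter: int = 20000,
) -> MagnetizationState:
    """Fixed point of the magnetization/strain/effective-field chain.

    Solves M = Ms·L(3χ0|H_eff|/Ms)·Ĥ_eff with H_eff = (H_applied − N·M) +
    stress feedback, by damped fixed-point iteration with damping
    γ = 2/(2 + χ0) (the map's local slope is ≈ −χ0·N, so heavy damping is
    required for convergence at χ0 = 200).

    Raises
    ------
    ConvergenceError
        If |ΔM|/Ms has not fallen below ``tol`` after ``max_iter`` steps.
    """
    h_applied = np.asarray(h_applied, dtype=float)
    s_ext = np.zeros(6) if s_ext is None else np.asarray(s_ext, dtype=float)
    ms, chi0 = mat.saturation_magnetization, mat.initial_susceptibility
    gamma = 2.0 / (2.0 + chi0)

    m = np.zeros(3)
    residual = np.inf
    for _ in range(max_iter):
        h_int = h_applied - demag_factor * m
        h_eff = effective_field(h_int, s_ext, m, mat)
        m_new = magnetization_of_field(h_eff, mat)
        residual = float(np.linalg.norm(m_new - m) / ms)
        m = (1.0 - gamma) * m + gamma * m_new
        if residual < tol:
            break
    else:
        raise ConvergenceError("self-consistent magnetization did not converge", residual)

    h_int = h_applied - demag_factor * m
    h_eff = effective_field(h_int, s_ext, m, mat)
    return MagnetizationState(
        applied_field=h_applied,
        internal_field=h_int,
        effective_field=h_eff,
        magnetization=m,
        strain_me=me_strain(m, mat),
        residual=residual,
    )


def solve_axial_magnetization(
    h_applied_z: np.ndarray,
    mat: MagnetostrictiveMaterial,
    demag_factor: float = DEMAG_SPHERE,
    tol: float = 1e-12,
    max_iter: int = 100,
) -> np.ndarray:
    """Vectorized axial (z-only, zero external stress) self-consistent solve.

    Newton iteration on the monotone residual g(M) = M − Ms·L(3χ0(H−N·M)/Ms)
    with g' ≥ 1, safeguarded by clipping to [−Ms, Ms].  Used by the
    time-domain transduction path where one state per sample is needed.
    """
    h = np.asarray(h_applied_z, dtype=float)
    ms, chi0 = mat.saturation_magnetization, mat.initial_susceptibility
    k = 3.0 * chi0 / ms

    # sheared-susceptibility initial guess, clipped into the open interval
    chi_eff = chi0 / (1.0 + chi0 * demag_factor)
    m = np.clip(chi_eff * h, -0.999999 * ms, 0.999999 * ms)
    for _ in range(max_iter):
        x = k * (h - demag_factor * m)
        g = m - ms * langevin(x)
        gp = 1.0 + chi0 * demag_factor * 3.0 * dlangevin(x)
        step = g / gp
        m = np.clip(m - step, -ms, ms)
        if np.max(np.abs(step)) < tol * ms:
            break
    else:
        raise ConvergenceError(
            "axial magnetization Newton iteration did not converge",
            float(np.max(np.abs(step)) / ms),
        )
    return m


@dataclass(frozen=True)
class BiasCurve:
    """λ∥ versus applied flux density, with slope and optimum-bias data.

    The bias axis is the *applied* flux density B = μ0·H_applied (the field
    the coils impose far from the particle), not the internal field.
    """

    bias_axis: np.ndarray  # T
    lambda_parallel: np.ndarray  # strain
    dlambda_dB: np.ndarray  # strain / T
    optimum_bias: float  # T, argmax of dλ/dB on B > 0
    optimum_window: tuple[float, float]  # T, contiguous band ≥ 50% of max slope

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "B_T": self.bias_axis,
                "lambda": self.lambda_parallel,
                "dlambda_dB": self.dlambda_dB,
            }
        ).to_csv(path, index=False)

    def to_dict(self) -> dict:
        return {
            "optimum_bias_T": self.optimum_bias,
            "optimum_window_T": list(self.optimum_window),
            "lambda_max": float(np.max(self.lambda_parallel)),
            "n_points": int(len(self.bias_axis)),
        }


def bias_sweep(b_range: np.ndarray, mat: MagnetostrictiveMaterial) -> BiasCurve:
    """Sweep the DC bias (applied flux density, T) and evaluate λ∥(B).

    The optimum bias is the argmax of dλ/dB restricted to B > 0 (central
    differences); ties break to the smallest B.  The optimum window is the
    contiguous positive-bias band where the slope exceeds half its maximum.
    """
    b = np.asarray(b_range, dtype=float)
    if b.ndim != 1 or len(b) < 5:
        raise ValueError("bias range must be a 1-D array with at least 5 points")
    m = solve_axial_magnetization(b / MU0, mat)
    lam = mat.saturation_magnetostriction * (m / mat.saturation_magnetization) ** 2
    dlam = np.gradient(lam, b)

    pos = b > 0
    slopes = np.where(pos, dlam, -np.inf)
    best = int(np.argmax(slopes))  # np.argmax returns the first (smallest B) maximum
    half = 0.5 * slopes[best]
    above = pos & (dlam >= half)
    # contiguous band containing the optimum
    lo = best
    while lo - 1 >= 0 and above[lo - 1]:
        lo -= 1
    hi = best
    while hi + 1 < len(b) and above[hi + 1]:
        hi += 1
    return BiasCurve(
        bias_axis=b,
        lambda_parallel=lam,
        dlambda_dB=dlam,
        optimum_bias=float(b[best]),
        optimum_window=(float(b[lo]), float(b[hi])),
    )
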