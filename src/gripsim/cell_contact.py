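"""Hertzian large-deformation contact of the gripped cell.

A sphere of radius R squeezed between the gripper tips resists with a force
that grows superlinearly in the radial compression δ_r, accounting for the
lateral extension of the cell through the kernel

    f(a) = 2(1+v) R² / (a²+4R²)^{3/2} + (1-v²) / (a²+4R²)^{1/2},

which couples the two contact patches across the cell diameter.  The
implemented force law is

    F_xc(δ_r) = [δ_r E_c / (3(1-v²))] · [4 a − f(a) a² / π],

with the f-term normalised by a² to be commensurate with the 4a term (f has
dimension 1/length), and ``a`` one of two contact radii selected by the
``law`` argument:

* ``"geometric"`` (default) — a = √(2R δ_r − δ_r²), the truncation radius of
  the flattened cap.  This is the published form of the model; its
  small-compression limit is √2 × the classical Hertz sphere-plate force.
* ``"hertz"`` — a = √(R δ_r), the Hertzian contact radius, whose
  small-compression limit is exactly the classical Hertz relation
  F = (4/3) E √R δ^{3/2} / (1−v²).

:func:`contact_radius` always reports the geometric radius — the flattened
cap a microscope would see.

The torque about the pivot is T_c = F_xc(δ_r) · r_c with the compression
split equally between the two tips, δ_r = r_c θ_z / 2.  For the Duffing
dynamics, T_c(θ) is reduced to an odd cubic α_a θ + α_b θ³ by least squares;
both coefficients are homogeneous of degree one in E_c.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import CellModel, KinematicsModel

__all__ = [
    "ContactState",
    "CubicTorqueFit",
    "contact_radius",
    "force_bracket",
    "resistive_force",
    "resistive_torque",
    "contact_state",
    "fit_cubic_torque",
    "linearized_cell_stiffness",
    "default_theta_max",
    "MAX_RELATIVE_COMPRESSION",
    "DEFAULT_LAW",
]

#: validity cap of the large-deformation law, as a fraction of the radius
MAX_RELATIVE_COMPRESSION = 0.6

#: contact radius entering the force bracket
DEFAULT_LAW = "geometric"


@dataclass(frozen=True)
class ContactState:
    """State of one squeezed cell at radial compression ``delta_r``."""

    delta_r: float
    a: float
    F_xc: float
    T_c: float


@dataclass(frozen=True)
class CubicTorqueFit:
    """Least-squares reduction T_c(θ) ≈ α_a θ + α_b θ³ on [0, theta_max]."""

    alpha_a: float
    alpha_b: float
    theta_max: float
    residual: float


def contact_radius(cell: CellModel, delta_r: float) -> float:
    """Geometric radius a = sqrt(2 R δ_r − δ_r²) of the flattened cap (m)."""
    if delta_r < 0:
        raise ValueError(f"delta_r must be >= 0, got {delta_r}")
    if delta_r > cell.R:
        raise ValueError(f"delta_r = {delta_r} exceeds the cell radius {cell.R}")
    return math.sqrt(delta_r * (2.0 * cell.R - delta_r))


def _lateral_kernel(a, R: float, v: float):
    """f(a): lateral-extension kernel (units 1/m)."""
    s = np.asarray(a) ** 2 + 4.0 * R * R
    return 2.0 * (1.0 + v) * R * R / s**1.5 + (1.0 - v * v) / np.sqrt(s)


def _bracket_radius(cell: CellModel, delta, law: str):
    if law == "geometric":
        return np.sqrt(delta * (2.0 * cell.R - delta))
    if law == "hertz":
        return np.sqrt(cell.R * delta)
    raise ValueError(f"unknown contact law {law!r}; use 'geometric' or 'hertz'")


def force_bracket(cell: CellModel, delta_r, law: str = DEFAULT_LAW):
    """The geometric bracket 4a − f(a) a²/π (m); multiply by
    δ_r E_c / (3(1−v²)) to get the resistive force."""
    delta = np.asarray(delta_r, dtype=float)
    a = _bracket_radius(cell, delta, law)
    return 4.0 * a - _lateral_kernel(a, cell.R, cell.v) * a**2 / math.pi


def resistive_force(cell: CellModel, delta_r, law: str = DEFAULT_LAW):
    """Resistive (compression) force F_xc (N) at radial compression δ_r (m).

    Valid for 0 <= δ_r <= 0.6 R; scalar or array input.
    """
    delta = np.asarray(delta_r, dtype=float)
    if np.any(delta < 0):
        raise ValueError("delta_r must be >= 0")
    if np.any(delta > MAX_RELATIVE_COMPRESSION * cell.R):
        raise ValueError(
            f"delta_r exceeds the validity cap {MAX_RELATIVE_COMPRESSION} R "
            f"= {MAX_RELATIVE_COMPRESSION * cell.R:.3e} m"
        )
    if cell.v >= 1.0:
        raise ValueError("Poisson ratio v must be < 1")
    out = delta * cell.E_c / (3.0 * (1.0 - cell.v**2)) * force_bracket(cell, delta, law)
    return out if out.ndim else float(out)


def resistive_torque(cell: CellModel, theta_z, kin: KinematicsModel,
                     law: str = DEFAULT_LAW):
    """Resistive torque T_c = F_xc(δ_r) r_c (N m) at rotation θ_z >= 0, with
    the compression δ_r = r_c θ_z / 2 shared equally by the two tips."""
    theta = np.asarray(theta_z, dtype=float)
    if np.any(theta < 0):
        raise ValueError("theta_z must be >= 0")
    delta = kin.r_c * theta / 2.0
    cap = MAX_RELATIVE_COMPRESSION * cell.R
    if np.any(delta > cap):
        bad = float(np.max(theta))
        raise ValueError(
            f"theta_z = {bad:.4g} rad implies compression beyond {cap:.3e} m"
        )
    out = resistive_force(cell, delta, law) * kin.r_c
    return out if np.ndim(out) else float(out)


def contact_state(cell: CellModel, theta_z: float, kin: KinematicsModel,
                  law: str = DEFAULT_LAW) -> ContactState:
    """Full contact state at one rotation angle."""
    delta = kin.r_c * theta_z / 2.0
    return ContactState(
        delta_r=delta,
        a=contact_radius(cell, delta),
        F_xc=float(resistive_force(cell, delta, law)),
        T_c=float(resistive_torque(cell, theta_z, kin, law)),
    )


def fit_odd_cubic(theta, torque) -> tuple[float, float, float]:
    """Least squares of sampled torque data onto α_a θ + α_b θ³.

    Returns (alpha_a, alpha_b, rms residual).  Raises on a degenerate grid.
    """
    theta = np.asarray(theta, dtype=float)
    torque = np.asarray(torque, dtype=float)
    X = np.column_stack([theta, theta**3])
    if len(theta) < 2 or np.allclose(theta, theta[0]):
        raise ValueError("degenerate fit grid")
    coef, *_ = np.linalg.lstsq(X, torque, rcond=None)
    resid = torque - X @ coef
    return float(coef[0]), float(coef[1]), float(np.sqrt(np.mean(resid**2)))


def fit_cubic_torque(cell: CellModel, kin: KinematicsModel, theta_max: float,
                     n_grid: int = 200, law: str = DEFAULT_LAW) -> CubicTorqueFit:
    """Least-squares fit of T_c(θ) to α_a θ + α_b θ³ on [0, theta_max].

    The basis is odd and passes through the origin, as a physical contact
    torque must (T_c(0) = 0).  Returns coefficients and the rms residual.
    """
    if theta_max <= 0:
        raise ValueError(f"theta_max must be > 0, got {theta_max}")
    if n_grid < 10:
        raise ValueError(f"n_grid must be >= 10, got {n_grid}")
    theta = np.linspace(0.0, theta_max, n_grid)
    torque = np.asarray(resistive_torque(cell, theta, kin, law))
    alpha_a, alpha_b, resid = fit_odd_cubic(theta, torque)
    return CubicTorqueFit(alpha_a=alpha_a, alpha_b=alpha_b,
                          theta_max=theta_max, residual=resid)


def linearized_cell_stiffness(fit: CubicTorqueFit) -> float:
    """Rotational stiffness the cell adds to the suspension: k_zc = α_a."""
    return fit.alpha_a


def default_theta_max(cell: CellModel, kin: KinematicsModel,
                      relative_compression: float = 0.2) -> float:
    """Rotation at which the cell is compressed by the given fraction of its
    radius (default 20%, the squeezing operating point)."""
    return 2.0 * relative_compression * cell.R / kin.r_c
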