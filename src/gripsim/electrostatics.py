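"""Electrostatics of the rotary comb-drive actuators.

The overlap capacitance of a rotary comb bank is linear in the overlap angle
θ, so the torque ½ V² dC/dθ is independent of θ within the overlap range —
the rotary analogue of the constant-force property of linear comb drives.

All quantities SI.  ``EPS0`` is the permittivity of free space; air is
treated as vacuum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .config import CombDriveGeometry, DriveSignal, StiffnessSet

__all__ = [
    "EPS0",
    "TorqueModel",
    "geometry_sum",
    "capacitance",
    "torque_coefficient",
    "pushpull_voltages",
    "actuation_torque_amplitude",
    "optimal_pushpull_split",
    "critical_voltage",
    "static_rotation",
    "max_opening",
]

EPS0 = 8.854e-12  # F/m


@dataclass(frozen=True)
class TorqueModel:
    """Torque coefficient τ0 (N m V^-2) and alternating torque amplitude
    B (N m) of an actuator bank."""

    tau0: float
    B: float = 0.0


def geometry_sum(geom: CombDriveGeometry) -> float:
    """The dimensionless bracketed sum over finger-pair gaps.

    Radial finger i occupies [R0 + 2i(Wf+g) - Wf, R0 + 2i(Wf+g)]; the two
    sums run over the inner- and outer-facing gaps of pairs i = 1 … n-1.
    """
    R0, Wf, g, n = geom.R0, geom.Wf, geom.g, geom.n
    pitch = Wf + g
    total = 0.0
    for i in range(1, n):
        r_out = R0 + 2 * i * pitch
        total += 1.0 / math.log(r_out / (r_out - g))
        total += 1.0 / math.log((R0 + (2 * i + 1) * pitch) / (r_out + Wf))
    return total


def capacitance(geom: CombDriveGeometry, theta: float) -> float:
    """Total overlap capacitance (F) of the bank at overlap angle ``theta``
    (rad), summed over the mobile structural layers."""
    if theta < 0:
        raise ValueError(f"theta must be >= 0, got {theta}")
    if theta >= math.pi / 2:
        raise ValueError(f"theta must be < pi/2 rad, got {theta}")
    return EPS0 * theta * geom.h * geometry_sum(geom) * geom.layers


def torque_coefficient(geom: CombDriveGeometry) -> float:
    """Torque coefficient τ0 = ½ dC/dθ (N m V^-2); the actuation torque is
    τ = τ0 V², independent of θ while the fingers overlap."""
    return 0.5 * EPS0 * geom.h * geometry_sum(geom) * geom.layers


def pushpull_voltages(sig: DriveSignal, t) -> tuple[np.ndarray, np.ndarray]:
    """Push-pull drive voltages V_L = V0 + V1 sin(ωt), V_R = V0 − V1 sin(ωt)."""
    s = sig.V1 * np.sin(sig.omega * np.asarray(t, dtype=float))
    return sig.V0 + s, sig.V0 - s


def actuation_torque_amplitude(tau0: float, sig: DriveSignal) -> float:
    """Amplitude B (N m) of the net push-pull torque B sin(ωt).

    The two banks pull in opposite senses, so the net torque is
    τ0 (V_L² − V_R²) = 4 τ0 V0 V1 sin(ωt).
    """
    if tau0 <= 0:
        raise ValueError(f"tau0 must be > 0, got {tau0}")
    return 4.0 * tau0 * (sig.V0 * sig.V1)


def optimal_pushpull_split(tau0: float, v_peak: float) -> tuple[float, float, float]:
    """Maximise B = 4 τ0 V0 V1 subject to the peak-voltage cap
    V0 + V1 <= v_peak (the instantaneous maximum of V_L).

    Returns (V0, V1, B).  The optimum is the symmetric split; located
    numerically rather than assumed.
    """
    if v_peak <= 0:
        raise ValueError(f"v_peak must be > 0, got {v_peak}")
    res = optimize.minimize_scalar(
        lambda v0: -4.0 * tau0 * v0 * (v_peak - v0),
        bounds=(0.0, v_peak),
        method="bounded",
        options={"xatol": 1e-12 * v_peak},
    )
    v0 = float(res.x)
    v1 = v_peak - v0
    return v0, v1, 4.0 * tau0 * v0 * v1


def critical_voltage(k: float, g: float, C: float) -> float:
    """Side-instability voltage limit V_c = g sqrt(k / (2C)).

    ``k`` is the suspension stiffness along the direction normal to the
    finger sidewalls, ``g`` the finger gap, ``C`` the total capacitance.
    Above V_c the lateral electrostatic negative stiffness overcomes the
    suspension and the fingers snap sideways.
    """
    if k <= 0 or g <= 0:
        raise ValueError("k and g must be > 0")
    if C <= 0:
        raise ValueError(f"capacitance must be > 0, got {C}")
    return g * math.sqrt(k / (2.0 * C))


def static_rotation(tau0: float, Vdc: float, k_tz: float,
                    r_tip: float | None = None) -> tuple[float, float]:
    """Static rotation θ_z = τ0 V² / k_tz under a dc voltage, from the torque
    balance with no cell; returns (θ_z, tip displacement θ_z · r_tip)."""
    if tau0 <= 0 or k_tz <= 0:
        raise ValueError("tau0 and k_tz must be > 0")
    theta = tau0 * Vdc * Vdc / k_tz
    tip = theta * r_tip if r_tip is not None else float("nan")
    return theta, tip


def gripping_force(tau0: float, Vdc: float, k_tz: float, theta_z,
                   r_tip: float):
    """Force available at the tip while closing: the electrostatic torque
    minus the spring reaction, divided by the tip lever.

    Decreases with the closing rotation θ_z — the deeper the arm rotates,
    the more of the drive torque the suspension absorbs.
    """
    theta = np.asarray(theta_z, dtype=float)
    out = (tau0 * Vdc * Vdc - k_tz * theta) / r_tip
    return out if out.ndim else float(out)


def max_opening(gap0: float) -> float:
    """Maximum tip opening (m): the arm travel is symmetric, so the tips can
    open by the same stroke that fully closes the initial gap, doubling it."""
    if gap0 <= 0:
        raise ValueError(f"gap0 must be > 0, got {gap0}")
    return 2.0 * gap0
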