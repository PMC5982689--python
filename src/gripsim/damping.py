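"""Slide-film (Couette) air damping of the rotating mobile arm.

Each surface moving laterally over a nearby parallel wall at gap d drags air
with shear stress µ v / d; for a body at lever r from the pivot the local
velocity is r θ̇, so every contribution is a rotational damping coefficient —
torque per unit angular velocity, N m s rad⁻¹:

* ``c_am1``: lowest structural layer over the substrate, µ A_p r² / d_p,
  summed over the bodies that sit above the substrate;
* ``c_am2``: inter-layer drag of a body of half-length l at lever r,
  (32/3) µ l r², summed over the three bodies (the third mobile layer
  contributes the same amount again, hence the factor 2 in the total);
* ``c_am4``: comb-finger sidewalls, µ A_sn r² / g per finger.

Total: c_amT = c_am1 + 2 c_am2 + c_am4.
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import DampingGeometry

__all__ = ["DampingCoefficients", "slide_film_coefficients", "damping_torque"]


@dataclass(frozen=True)
class DampingCoefficients:
    """Rotational damping coefficients (N m s rad^-1)."""

    c_am1: float
    c_am2: float
    c_am4: float

    @property
    def c_amT(self) -> float:
        return self.c_am1 + 2.0 * self.c_am2 + self.c_am4


def slide_film_coefficients(geom: DampingGeometry) -> DampingCoefficients:
    """Partial and total slide-film damping coefficients for the arm."""
    if geom.d_p <= 0:
        raise ValueError(f"substrate gap d_p must be > 0, got {geom.d_p}")
    if geom.g <= 0:
        raise ValueError(f"sidewall gap g must be > 0, got {geom.g}")
    mu = geom.mu
    c1 = sum(mu * b.A_p * b.r_am**2 / geom.d_p for b in geom.bodies)
    c2 = sum((32.0 / 3.0) * mu * b.l_am * b.r_am**2 for b in geom.bodies)
    c4 = sum(s.count * mu * s.A_sn * s.r_am4**2 / geom.g for s in geom.sidewalls)
    return DampingCoefficients(c_am1=c1, c_am2=c2, c_am4=c4)


def damping_torque(c: DampingCoefficients, theta_dot: float) -> float:
    """Damping torque T_d = c_amT θ̇_z (N m), opposing the motion."""
    return c.c_amT * theta_dot
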