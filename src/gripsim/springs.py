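"""Serpentine-spring suspension stiffness.

Two routes to the same numbers:

* :func:`castigliano_stiffness` — closed-form energy method.  Internal loads
  along the (statically determinate) cantilever chain follow from rigid
  statics; the strain energy is an exact quadratic form in the tip load, so
  the tip compliance matrix is assembled analytically, with no numerical
  differentiation.  Energy terms: tension/compression, Saint-Venant torsion
  and Euler-Bernoulli bending in both planes (shear deformation neglected).
* :func:`beam_matrix_oracle` — a 12-dof space-frame finite-element solve of
  the same chain, used as an independent cross-check in the test suite.

Stiffness definitions follow the energy method with a single load applied at
the connection point: k_q = 1 / (∂²U/∂Q²) per spring, and springs of the
assembly act in parallel (their stiffnesses add).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import BeamSegment, StiffnessSet, SuspensionModel

__all__ = [
    "LoadCase",
    "SectionProperties",
    "section_properties",
    "strain_energy",
    "tip_compliance",
    "castigliano_stiffness",
    "beam_matrix_oracle",
    "reaction_torque",
    "suspension_stiffness",
]

# Load-component order used throughout: [Fx, Fy, Fz, Mx, My, Mz]
_COMPONENTS = ("Fx", "Fy", "Fz", "Mx", "My", "Mz")


@dataclass(frozen=True)
class LoadCase:
    """Force/moment applied at the connection point (SI)."""

    Fx: float = 0.0
    Fy: float = 0.0
    Fz: float = 0.0
    Mx: float = 0.0
    My: float = 0.0
    Mz: float = 0.0

    def as_vector(self) -> np.ndarray:
        return np.array([self.Fx, self.Fy, self.Fz, self.Mx, self.My, self.Mz])


@dataclass(frozen=True)
class SectionProperties:
    """Rectangular-section properties: area, bending inertias about the two
    principal axes, and the Saint-Venant torsion constant."""

    A: float
    I_inplane: float   # bending about the out-of-plane axis (width direction)
    I_outplane: float  # bending about the in-plane transverse axis
    J: float


def torsion_constant(b: float, h: float, series_terms: int = 12) -> float:
    """Saint-Venant torsion constant of a b × h rectangle via the classical
    tanh series; exact in the infinite-series limit for any aspect ratio."""
    s = 0.0
    for m in range(series_terms):
        q = 2 * m + 1
        s += math.tanh(q * math.pi * b / (2.0 * h)) / q**5
    return (b * h**3 / 3.0) * (1.0 - (192.0 * h / (math.pi**5 * b)) * s)


def section_properties(b: float, h: float, series_terms: int = 12) -> SectionProperties:
    """Properties of a rectangular section of in-plane width ``b`` and
    out-of-plane height ``h`` (SI)."""
    if b <= 0 or h <= 0:
        raise ValueError("section dimensions must be > 0")
    if series_terms < 1:
        raise ValueError("series_terms must be >= 1")
    return SectionProperties(
        A=b * h,
        I_inplane=h * b**3 / 12.0,
        I_outplane=b * h**3 / 12.0,
        J=torsion_constant(b, h, series_terms),
    )


def _local_frame(axis: Sequence[float]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    e1 = np.asarray(axis, dtype=float)
    e1 = e1 / np.linalg.norm(e1)
    e3 = np.array([0.0, 0.0, 1.0])
    e2 = np.cross(e3, e1)
    n2 = np.linalg.norm(e2)
    if n2 < 1e-12:
        raise ValueError("beam axis must lie in the device plane")
    return e1, e2 / n2, e3


def _chain_starts(beams: Sequence[BeamSegment]) -> list[np.ndarray]:
    """Start position of each segment, chaining from the connection point."""
    starts = []
    cursor = np.zeros(3)
    for i, seg in enumerate(beams):
        off = np.asarray(seg.offset, dtype=float)
        if i == 0:
            cursor = off.copy()
        elif np.any(off != 0.0):
            raise ValueError(
                "only the first segment may carry an offset; the chain is contiguous"
            )
        starts.append(cursor.copy())
        cursor = cursor + seg.L * np.asarray(seg.axis, dtype=float)
    return starts


def _segment_energy(seg: BeamSegment, start: np.ndarray, F: np.ndarray,
                    M: np.ndarray, E: float, G: float,
                    series_terms: int) -> float:
    """Exact strain energy of one segment under tip load (F, M) applied at
    the connection point (the coordinate origin)."""
    e1, e2, e3 = _local_frame(seg.axis)
    sec = section_properties(seg.b, seg.h, series_terms)

    # Internal loads at arc position s: force F, moment m(s) = M - r(s) x F,
    # with r(s) = start + s*e1  =>  m(s) = m0 + s * dm,  dm = -e1 x F.
    m0 = M - np.cross(start, F)
    dm = -np.cross(e1, F)
    L = seg.L

    def quad_int(a0: float, a1: float) -> float:
        # integral of (a0 + a1 s)^2 over [0, L]
        return L * (a0 * a0 + a0 * a1 * L + a1 * a1 * L * L / 3.0)

    N = float(F @ e1)                       # axial, constant
    U = N * N * L / (2.0 * E * sec.A)
    U += quad_int(float(m0 @ e1), float(dm @ e1)) / (2.0 * G * sec.J)
    U += quad_int(float(m0 @ e2), float(dm @ e2)) / (2.0 * E * sec.I_outplane)
    U += quad_int(float(m0 @ e3), float(dm @ e3)) / (2.0 * E * sec.I_inplane)
    return U


def strain_energy(beams: Sequence[BeamSegment], load: LoadCase, E: float,
                  nu: float, series_terms: int = 12) -> float:
    """Total strain energy (J) of one spring chain under a connection-point
    load, by rigid statics and exact integration along each segment."""
    if len(beams) == 0:
        raise ValueError("beam chain is empty")
    G = E / (2.0 * (1.0 + nu))
    F = load.as_vector()[:3]
    M = load.as_vector()[3:]
    starts = _chain_starts(beams)
    return sum(
        _segment_energy(seg, start, F, M, E, G, series_terms)
        for seg, start in zip(beams, starts)
    )


def tip_compliance(beams: Sequence[BeamSegment], E: float, nu: float,
                   series_terms: int = 12) -> np.ndarray:
    """6x6 compliance matrix of one spring at the connection point,
    C_ij = ∂²U/∂Q_i∂Q_j, assembled exactly from the quadratic energy form."""
    def U(q: np.ndarray) -> float:
        return strain_energy(beams, LoadCase(*q), E, nu, series_terms)

    C = np.zeros((6, 6))
    unit = np.eye(6)
    U_single = [U(unit[i]) for i in range(6)]
    for i in range(6):
        C[i, i] = 2.0 * U_single[i]
        for j in range(i + 1, 6):
            C[i, j] = C[j, i] = U(unit[i] + unit[j]) - U_single[i] - U_single[j]
    return C


def castigliano_stiffness(suspension: SuspensionModel) -> StiffnessSet:
    """Stiffness set of the spring assembly from the energy method.

    Each entry is the single-load stiffness 1/C_qq of one spring, times the
    number of parallel springs.
    """
    if suspension.mode != "castigliano":
        raise ValueError("castigliano_stiffness requires suspension.mode='castigliano'")
    C = tip_compliance(list(suspension.beams), suspension.E, suspension.nu_poly)
    n = suspension.n_springs
    return StiffnessSet(
        k_Fx=n / C[0, 0],
        k_Fy=n / C[1, 1],
        k_Fz=n / C[2, 2],
        k_tx=n / C[3, 3],
        k_tz=n / C[5, 5],
    )


def suspension_stiffness(suspension: SuspensionModel) -> StiffnessSet:
    """The stiffness set in effect: as given (direct mode) or derived from
    beam geometry (castigliano mode)."""
    if suspension.mode == "direct":
        return suspension.stiffness
    return castigliano_stiffness(suspension)


def reaction_torque(k_tz: float, theta_z: float) -> float:
    """Restoring torque of the suspension, T_s = k_tz θ_z (N m)."""
    return k_tz * theta_z


# ---------------------------------------------------------------------------
# Space-frame finite-element oracle


def _element_stiffness(E: float, G: float, sec: SectionProperties,
                       L: float) -> np.ndarray:
    """12x12 local stiffness of a 3D Euler-Bernoulli frame element.

    Local axes: x along the beam, y in-plane transverse (bending stiffness
    uses I_inplane), z out of plane (uses I_outplane).
    """
    k = np.zeros((12, 12))
    EA_L = E * sec.A / L
    GJ_L = G * sec.J / L

    def add_axial(i, j, val):
        k[i, i] += val
        k[j, j] += val
        k[i, j] -= val
        k[j, i] -= val

    add_axial(0, 6, EA_L)      # axial u_x
    add_axial(3, 9, GJ_L)      # torsion θ_x

    def add_bending(I, it, ir, jt, jr, sign):
        # translation dofs it/jt couple to rotation dofs ir/jr
        a = 12.0 * E * I / L**3
        b = sign * 6.0 * E * I / L**2
        c4 = 4.0 * E * I / L
        c2 = 2.0 * E * I / L
        k[it, it] += a; k[jt, jt] += a
        k[it, jt] -= a; k[jt, it] -= a
        for t, r, s in ((it, ir, 1.0), (it, jr, 1.0), (jt, ir, -1.0), (jt, jr, -1.0)):
            k[t, r] += s * b
            k[r, t] += s * b
        k[ir, ir] += c4; k[jr, jr] += c4
        k[ir, jr] += c2; k[jr, ir] += c2

    # bending in local x-y plane (deflection u_y, rotation θ_z): I_inplane
    add_bending(sec.I_inplane, 1, 5, 7, 11, +1.0)
    # bending in local x-z plane (deflection u_z, rotation θ_y): I_outplane
    add_bending(sec.I_outplane, 2, 4, 8, 10, -1.0)
    return k


def beam_matrix_oracle(beams: Sequence[BeamSegment], load: LoadCase, E: float,
                       nu: float, n_elem: int = 16,
                       series_terms: int = 12) -> np.ndarray:
    """Displacements/rotations [ux, uy, uz, θx, θy, θz] at the connection
    point of ONE spring chain under ``load``, by assembling space-frame
    elements along the chain with the anchor end clamped.

    Independent numerical route used to validate the closed-form energy
    method; exact for this loading up to round-off because cubic Hermite
    shape functions reproduce linear internal moment fields.
    """
    if len(beams) == 0:
        raise ValueError("beam chain is empty")
    G = E / (2.0 * (1.0 + nu))
    starts = _chain_starts(beams)

    nodes: list[np.ndarray] = [starts[0]]
    elements: list[tuple[int, int, BeamSegment, np.ndarray]] = []
    for seg, start in zip(beams, starts):
        e1, e2, e3 = _local_frame(seg.axis)
        R = np.vstack([e1, e2, e3])  # global -> local
        if not np.allclose(nodes[-1], start, atol=1e-15):
            raise ValueError("beam chain is not contiguous")
        for j in range(n_elem):
            p_end = start + seg.L * (j + 1) / n_elem * e1
            nodes.append(p_end)
            elements.append((len(nodes) - 2, len(nodes) - 1, seg, R))

    n_dof = 6 * len(nodes)
    K = np.zeros((n_dof, n_dof))
    for i, j, seg, R in elements:
        sec = section_properties(seg.b, seg.h, series_terms)
        k_loc = _element_stiffness(E, G, sec, seg.L / n_elem)
        T = np.zeros((12, 12))
        for blk in range(4):
            T[3 * blk:3 * blk + 3, 3 * blk:3 * blk + 3] = R
        k_glob = T.T @ k_loc @ T
        dofs = np.r_[6 * i:6 * i + 6, 6 * j:6 * j + 6]
        K[np.ix_(dofs, dofs)] += k_glob

    # Load acts at the connection point (origin); transfer to the first node
    # if the chain starts with a rigid offset.
    F = load.as_vector()[:3]
    M = load.as_vector()[3:] - np.cross(nodes[0], F)
    rhs = np.zeros(n_dof)
    rhs[0:3] = F
    rhs[3:6] = M

    free = np.arange(0, n_dof - 6)  # clamp the anchor node
    K_ff = K[np.ix_(free, free)]
    try:
        u = np.linalg.solve(K_ff, rhs[free])
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular frame system (disconnected chain?)") from exc

    u_tip = u[0:6].copy()
    # displacement at the origin = node displacement + rotation x lever
    lever = -nodes[0]
    u_tip[0:3] += np.cross(u_tip[3:6], lever)
    return u_tip
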