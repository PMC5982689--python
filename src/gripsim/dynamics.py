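"""Rotational dynamics of the mobile arm: Duffing equation and its
steady-state frequency response.

With a gripped cell the equation of motion about the pivot is

    J_b θ̈ + c_amT θ̇ + (k_tz + α_a) θ + α_b θ³ = B sin(ωt),

a forced Duffing oscillator (hardening for α_b > 0).  The steady state is
approximated by the single-harmonic ansatz θ = c1 cos(ωt − Ψ); balancing the
fundamental harmonic (Ritz averaging / harmonic balance) gives the implicit
amplitude equation

    [(k_lin − J_b ω²) c1 + (3/4) α_b c1³]² + (c_amT ω c1)² = B²,

a cubic in c1², with phase Ψ = atan2(c_amT ω, k_lin + (3/4) α_b c1² − J_b ω²).
Up to three real branches coexist in the hardening region; the intermediate
amplitude branch is the unstable one.

A direct time-domain integration (:func:`time_integrate`) serves as an
independent oracle for the averaged solution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .cell_contact import default_theta_max, fit_cubic_torque
from .config import Scenario
from .damping import slide_film_coefficients
from .electrostatics import actuation_torque_amplitude, torque_coefficient
from .springs import suspension_stiffness

__all__ = [
    "DuffingParams",
    "FrequencyResponse",
    "resonant_frequency",
    "assemble_motion_equation",
    "ritz_response",
    "sweep_amplitudes",
    "time_integrate",
    "steady_state_amplitude",
    "quality_factor",
    "peak_location",
]


@dataclass(frozen=True)
class DuffingParams:
    """Lumped parameters of the arm's rotational equation of motion (SI)."""

    J_b: float
    c_amT: float
    k_lin: float
    alpha_b: float
    B: float

    def __post_init__(self) -> None:
        if self.J_b <= 0 or self.k_lin <= 0:
            raise ValueError("J_b and k_lin must be > 0")
        if self.c_amT < 0 or self.alpha_b < 0 or self.B < 0:
            raise ValueError("c_amT, alpha_b and B must be >= 0")

    @property
    def omega_n(self) -> float:
        return math.sqrt(self.k_lin / self.J_b)


@dataclass(frozen=True)
class FrequencyResponse:
    """Steady-state response on a frequency grid.

    ``branches[i]`` is a list of (c1, psi, stable) tuples for grid point i,
    ordered by increasing amplitude.
    """

    omega: np.ndarray
    branches: list[list[tuple[float, float, bool]]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for w, brs in zip(self.omega, self.branches):
            for j, (c1, psi, stable) in enumerate(brs):
                rows.append((w / (2.0 * math.pi), c1, psi, j, stable))
        return pd.DataFrame(
            rows, columns=["frequency_hz", "c1_rad", "psi_rad", "branch", "stable"]
        )

    def sweep_up(self) -> np.ndarray:
        """Amplitude selected by a low→high sweep: stay on the upper stable
        branch until it folds, then drop to the remaining stable branch."""
        return _sweep(self, ascending=True)

    def sweep_down(self) -> np.ndarray:
        return _sweep(self, ascending=False)


def _sweep(resp: FrequencyResponse, ascending: bool) -> np.ndarray:
    idx = range(len(resp.omega)) if ascending else range(len(resp.omega) - 1, -1, -1)
    out = np.empty(len(resp.omega))
    prev = None
    for i in idx:
        stable = [c for c, _, s in resp.branches[i] if s]
        if not stable:  # numerically degenerate point: take any root
            stable = [resp.branches[i][0][0]]
        if prev is None:
            pick = max(stable) if ascending else min(stable)
        else:
            # hysteresis: continue on the branch closest to the previous
            # amplitude; on a fold the closest surviving branch is the jump
            pick = min(stable, key=lambda c: abs(c - prev))
            # a sweep can also climb onto a newly appeared branch only if it
            # connects continuously; prefer continuity
        out[i] = pick
        prev = pick
    return out


def resonant_frequency(k_Tz_total: float, J_b: float) -> float:
    """Undamped rotational resonant frequency f = (1/2π) sqrt(k/J) (Hz)."""
    if k_Tz_total <= 0 or J_b <= 0:
        raise ValueError("stiffness and inertia must be > 0")
    return math.sqrt(k_Tz_total / J_b) / (2.0 * math.pi)


def assemble_motion_equation(scn: Scenario) -> DuffingParams:
    """Lump a scenario into Duffing parameters.

    J_b from the inertia model; c_amT from the slide-film damping geometry;
    B = 4 τ0 V0 V1 from the electrodynamic comb bank; k_lin = k_tz plus the
    cell's linearised stiffness α_a when a cell is gripped, with α_b the
    cubic coefficient of its torque reduction (zero without a cell).
    """
    k_tz = suspension_stiffness(scn.suspension).k_tz
    c_amT = slide_film_coefficients(scn.damping).c_amT
    tau0 = torque_coefficient(scn.comb_electrodynamic)
    B = actuation_torque_amplitude(tau0, scn.drive) if scn.drive.V0 * scn.drive.V1 > 0 else 0.0
    alpha_a = 0.0
    alpha_b = 0.0
    if scn.cell is not None:
        fit = fit_cubic_torque(
            scn.cell, scn.kinematics,
            theta_max=default_theta_max(scn.cell, scn.kinematics),
        )
        alpha_a = fit.alpha_a
        alpha_b = max(fit.alpha_b, 0.0)
    return DuffingParams(
        J_b=scn.inertia.J_b,
        c_amT=c_amT,
        k_lin=k_tz + alpha_a,
        alpha_b=alpha_b,
        B=B,
    )


def _amplitude_roots(p: DuffingParams, w: float) -> list[float]:
    """Real positive amplitude roots c1 of the harmonic-balance equation."""
    d = p.k_lin - p.J_b * w * w
    g = 0.75 * p.alpha_b
    if p.alpha_b == 0.0:
        return [p.B / math.hypot(d, p.c_amT * w)] if p.B > 0 else [0.0]
    # cubic in u = c1^2: g^2 u^3 + 2 g d u^2 + (d^2 + (cw)^2) u - B^2 = 0
    coeffs = [g * g, 2.0 * g * d, d * d + (p.c_amT * w) ** 2, -p.B * p.B]
    roots = np.roots(coeffs)
    out = sorted(
        float(math.sqrt(r.real))
        for r in roots
        if abs(r.imag) < 1e-9 * max(1.0, abs(r.real)) and r.real > 0.0
    )
    if not out and p.B > 0:
        raise RuntimeError("harmonic balance produced no positive root")
    return out or [0.0]


def ritz_response(p: DuffingParams, omega_grid) -> FrequencyResponse:
    """Steady-state frequency response by Ritz averaging on a grid of
    angular frequencies (rad/s).  Flags the intermediate branch unstable
    wherever three branches coexist."""
    omega_grid = np.asarray(omega_grid, dtype=float)
    if np.any(omega_grid <= 0) or np.any(omega_grid > 10.0 * p.omega_n):
        raise ValueError("omega grid must lie in (0, 10 omega_n]")
    branches = []
    for w in omega_grid:
        roots = _amplitude_roots(p, w)
        brs = []
        for j, c1 in enumerate(roots):
            psi = math.atan2(
                p.c_amT * w,
                p.k_lin + 0.75 * p.alpha_b * c1 * c1 - p.J_b * w * w,
            )
            stable = not (len(roots) == 3 and j == 1)
            brs.append((c1, psi, stable))
        branches.append(brs)
    return FrequencyResponse(omega=omega_grid, branches=branches)


def sweep_amplitudes(p: DuffingParams, omega_grid, policy: str = "stable") -> np.ndarray:
    """Single amplitude per grid point under a branch policy: ``stable``
    (low→high sweep with hysteresis), ``lowest``, or ``all`` is not reducible
    to one value and raises."""
    resp = ritz_response(p, omega_grid)
    if policy == "stable":
        return resp.sweep_up()
    if policy == "lowest":
        return np.array([brs[0][0] for brs in resp.branches])
    raise ValueError(f"policy {policy!r} does not define a single amplitude")


def time_integrate(p: DuffingParams, omega: float, n_periods: int = 200,
                   rtol: float = 1e-9, atol: float = 1e-12,
                   theta0: float = 0.0, theta_dot0: float = 0.0):
    """Integrate the Duffing equation from given initial conditions.

    Returns (t, θ, θ̇) sampled densely over ``n_periods`` forcing periods
    (or free-oscillation periods if B = 0).
    """
    w_ref = omega if omega > 0 else p.omega_n
    T = 2.0 * math.pi / w_ref
    t_end = n_periods * T

    def rhs(t, y):
        th, thd = y
        return [
            thd,
            (p.B * math.sin(omega * t) - p.c_amT * thd - p.k_lin * th
             - p.alpha_b * th**3) / p.J_b,
        ]

    t_eval = np.linspace(0.0, t_end, n_periods * 64 + 1)
    sol = solve_ivp(rhs, (0.0, t_end), [theta0, theta_dot0], t_eval=t_eval,
                    rtol=rtol, atol=atol, method="DOP853")
    if not sol.success:
        raise RuntimeError(f"time integration failed: {sol.message}")
    return sol.t, sol.y[0], sol.y[1]


def steady_state_amplitude(p: DuffingParams, omega: float, n_periods: int = 200,
                           rtol: float = 1e-9, atol: float = 1e-12) -> float:
    """Steady-state amplitude from the time-domain oracle: half the
    peak-to-peak excursion over the last 10 forcing periods."""
    if n_periods < 50:
        raise ValueError("need at least 50 periods to reach steady state")
    t, th, _ = time_integrate(p, omega, n_periods, rtol, atol)
    tail = th[t >= t[-1] - 10 * 2.0 * math.pi / omega]
    return 0.5 * (tail.max() - tail.min())


def peak_location(omega: np.ndarray, amplitude: np.ndarray) -> tuple[float, float]:
    """(ω_peak, c_peak) by quadratic interpolation around the grid maximum."""
    i = int(np.argmax(amplitude))
    if i == 0 or i == len(omega) - 1:
        raise ValueError("response peak lies at the grid edge; widen the grid")
    w0, w1, w2 = omega[i - 1:i + 2]
    y0, y1, y2 = amplitude[i - 1:i + 2]
    denom = (y0 - 2.0 * y1 + y2)
    if denom == 0:
        return float(omega[i]), float(amplitude[i])
    dw = 0.5 * (y0 - y2) / denom * (w1 - w0)
    w_pk = w1 + dw
    c_pk = y1 - 0.25 * (y0 - y2) * dw / (w1 - w0)
    return float(w_pk), float(c_pk)


def quality_factor(resp: FrequencyResponse) -> float:
    """Quality factor Q = f_peak / Δf from the half-power bandwidth of the
    sweep-up amplitude curve.

    For hardening (bent) peaks the upper half-power crossing can be
    multivalued; the crossing on the swept curve — which jumps down at the
    fold — is used, so the fold frequency bounds the bandwidth there.
    """
    amp = resp.sweep_up()
    w = resp.omega
    w_pk, c_pk = peak_location(w, amp)
    c_hp = c_pk / math.sqrt(2.0)

    i_pk = int(np.argmax(amp))
    lo = None
    for i in range(i_pk, 0, -1):
        if amp[i - 1] < c_hp <= amp[i]:
            lo = w[i - 1] + (w[i] - w[i - 1]) * (c_hp - amp[i - 1]) / (amp[i] - amp[i - 1])
            break
    hi = None
    for i in range(i_pk, len(w) - 1):
        if amp[i + 1] < c_hp <= amp[i]:
            if amp[i] - amp[i + 1] > 0:
                hi = w[i] + (w[i + 1] - w[i]) * (amp[i] - c_hp) / (amp[i] - amp[i + 1])
            else:
                hi = w[i]
            break
    if lo is None or hi is None:
        raise ValueError("half-power crossings not resolved; widen the grid")
    return float(w_pk / (hi - lo))
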