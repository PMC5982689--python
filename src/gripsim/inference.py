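"""Inverting resonance measurements to cell stiffness and elastic modulus.

Gripping a cell stiffens the arm's rotational mode: the resonant frequency
rises from f_free = (1/2π)√(k_tz/J_b) to f_loaded = (1/2π)√((k_tz+k_zc)/J_b).
Because the cell's contact torque is linear in its elastic modulus E_c, both
the linearised stiffness α_a and the cubic (hardening) coefficient α_b scale
as E_c times geometry-only coefficients, so inverting a measured spectrum for
E_c is a one-parameter problem.

Two estimators are provided:

* ``frequency_shift`` — locate the response peak; at the peak of a hardening
  Duffing resonance J ω_p² ≈ k_tz + α_a + (3/4) α_b c_p² (the backbone
  relation), which is linear in E_c given the measured peak amplitude c_p.
* ``torque_balance`` — reconstruct the cell's effective elastic torque from
  the amplitude equation at every usable grid point (the drive, inertia,
  damping and suspension terms are known), convert each to a modulus, and
  take the median.

A residual-resampling bootstrap supplies confidence intervals, and measured
moduli are classified against reference cell lines by nearest z-score.

The statsmodels-style front door is :class:`CellModulusModel` /
:class:`CellModulusResults`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cell_contact import default_theta_max, fit_cubic_torque
from .config import CellModel, Scenario
from .damping import slide_film_coefficients
from .dynamics import (DuffingParams, assemble_motion_equation, peak_location,
                       resonant_frequency, ritz_response)
from .electrostatics import actuation_torque_amplitude, torque_coefficient
from .fixtures import CELL_REFERENCES
from .springs import suspension_stiffness

__all__ = [
    "ModulusEstimate",
    "estimate_stiffness_from_shift",
    "unit_modulus_coefficients",
    "estimate_modulus",
    "classify_cell",
    "CellModulusModel",
    "CellModulusResults",
]

#: plausibility window for an estimated modulus (Pa); outside -> flagged
MODULUS_WINDOW = (1.0, 1e5)


@dataclass(frozen=True)
class ModulusEstimate:
    """Point estimate of a gripped cell's mechanics."""

    E_hat: float
    k_zc_hat: float
    method: str
    flagged: bool = False
    ci: Optional[tuple[float, float]] = None


def estimate_stiffness_from_shift(f_loaded: float, f_free: float, J_b: float) -> float:
    """Cell rotational stiffness from the resonance shift:
    k_zc = J_b [(2π f_loaded)² − (2π f_free)²]."""
    if f_free <= 0 or f_loaded <= 0:
        raise ValueError("frequencies must be > 0")
    if f_loaded < f_free:
        raise ValueError(
            f"loaded frequency {f_loaded} Hz below free frequency {f_free} Hz: "
            "a gripped cell cannot soften the suspension in this model"
        )
    tau = 2.0 * math.pi
    return J_b * ((tau * f_loaded) ** 2 - (tau * f_free) ** 2)


def unit_modulus_coefficients(cell_geometry: CellModel, scn: Scenario) -> tuple[float, float]:
    """(A1, A3): linear and cubic torque coefficients per unit modulus.

    The contact torque is homogeneous of degree 1 in E_c, so α_a = A1 E_c and
    α_b = A3 E_c with A1, A3 depending only on the cell and tip geometry.
    """
    probe = CellModel(E_c=1.0, v=cell_geometry.v, R=cell_geometry.R,
                      label=cell_geometry.label)
    fit = fit_cubic_torque(probe, scn.kinematics,
                           theta_max=default_theta_max(probe, scn.kinematics))
    return fit.alpha_a, fit.alpha_b


def _known_params(scn: Scenario) -> tuple[float, float, float, float]:
    """(J_b, c_amT, k_tz, B) — everything known without the cell."""
    k_tz = suspension_stiffness(scn.suspension).k_tz
    c_amT = slide_film_coefficients(scn.damping).c_amT
    tau0 = torque_coefficient(scn.comb_electrodynamic)
    B = actuation_torque_amplitude(tau0, scn.drive)
    return scn.inertia.J_b, c_amT, k_tz, B


def _estimate_from_arrays(omega: np.ndarray, amp: np.ndarray, scn: Scenario,
                          A1: float, A3: float, method: str) -> tuple[float, float, bool]:
    """Core estimator; returns (E_hat, k_zc_hat, flagged)."""
    J_b, c_amT, k_tz, B = _known_params(scn)
    w_pk, c_pk = peak_location(omega, amp)

    if method == "frequency_shift":
        k_shift = J_b * w_pk**2 - k_tz
        denom = A1 + 0.75 * A3 * c_pk**2
        E_hat = k_shift / denom
    elif method == "torque_balance":
        usable = amp >= 0.2 * c_pk
        w = omega[usable]
        c1 = amp[usable]
        rad = (B / c1) ** 2 - (c_amT * w) ** 2
        ok = rad > 0
        sign = np.where(w < w_pk, 1.0, -1.0)
        k_eff = J_b * w**2 - k_tz + sign * np.sqrt(np.clip(rad, 0.0, None))
        E_points = k_eff[ok] / (A1 + 0.75 * A3 * c1[ok] ** 2)
        if len(E_points) == 0:
            raise ValueError("no usable measurement points for torque balance")
        E_hat = float(np.median(E_points))
    else:
        raise ValueError(f"unknown method {method!r}")

    k_zc_hat = E_hat * A1
    flagged = not (MODULUS_WINDOW[0] < E_hat < MODULUS_WINDOW[1])
    return float(E_hat), float(k_zc_hat), flagged


def estimate_modulus(measurement: pd.DataFrame, scn: Scenario,
                     method: str = "frequency_shift") -> ModulusEstimate:
    """Estimate the gripped cell's elastic modulus from an amplitude spectrum.

    ``measurement`` needs columns ``frequency_hz`` and ``amplitude_rad`` and
    must cover the resonance peak.  The scenario supplies everything known
    a priori (inertia, damping, suspension, drive, tip kinematics) plus the
    cell's geometry (radius and Poisson ratio); only the modulus is inferred.
    """
    if scn.cell is None:
        raise ValueError("scenario must carry the gripped cell's geometry")
    omega = 2.0 * np.pi * measurement["frequency_hz"].to_numpy(dtype=float)
    amp = measurement["amplitude_rad"].to_numpy(dtype=float)
    A1, A3 = unit_modulus_coefficients(scn.cell, scn)
    E_hat, k_zc_hat, flagged = _estimate_from_arrays(omega, amp, scn, A1, A3, method)
    if flagged:
        warnings.warn(
            f"estimated modulus {E_hat:.3g} Pa outside the plausible window "
            f"{MODULUS_WINDOW}; flagged (below/above instrument resolution)",
            stacklevel=2,
        )
    return ModulusEstimate(E_hat=E_hat, k_zc_hat=k_zc_hat, method=method,
                           flagged=flagged)


def classify_cell(E_hat: float, references: Optional[dict] = None,
                  ) -> tuple[str, dict[str, float]]:
    """Nearest-reference classification by z-score.

    ``references`` maps label -> (mean, sd[, ...]); defaults to the packaged
    prostate-line table.  Ties break toward the stiffer class with a warning.
    """
    refs = references if references is not None else CELL_REFERENCES
    if not refs:
        raise ValueError("references must be non-empty")
    z = {label: (E_hat - v[0]) / v[1] for label, v in refs.items()}
    best = min(abs(x) for x in z.values())
    candidates = [lab for lab, x in z.items() if abs(abs(x) - best) < 1e-12]
    if len(candidates) > 1:
        candidates.sort(key=lambda lab: -refs[lab][0])
        warnings.warn(
            f"modulus {E_hat:.3g} Pa equidistant between {candidates}; "
            f"tie broken toward the stiffer class {candidates[0]!r}",
            stacklevel=2,
        )
    return candidates[0], z


# ---------------------------------------------------------------------------
# Model / Results front end


class CellModulusModel:
    """Measurement-inversion model for a single gripped cell.

    Parameters
    ----------
    measurement : pandas.DataFrame
        Amplitude spectrum with columns ``frequency_hz``, ``amplitude_rad``.
    scenario : Scenario
        Device description including the gripped cell's geometry (the cell's
        modulus field is ignored — it is what gets estimated).
    """

    def __init__(self, measurement: pd.DataFrame, scenario: Scenario):
        for col in ("frequency_hz", "amplitude_rad"):
            if col not in measurement.columns:
                raise ValueError(f"measurement lacks column {col!r}")
        if scenario.cell is None:
            raise ValueError("scenario must carry the gripped cell's geometry")
        self.measurement = measurement.reset_index(drop=True)
        self.scenario = scenario

    @classmethod
    def from_csv(cls, path, scenario: Scenario) -> "CellModulusModel":
        return cls(pd.read_csv(path), scenario)

    def fit(self, method: str = "frequency_shift", n_boot: int = 50,
            seed: int = 0, alpha: float = 0.05) -> "CellModulusResults":
        """Estimate the modulus; bootstrap CIs by residual resampling
        (``n_boot = 0`` skips the bootstrap)."""
        est = {
            m: estimate_modulus(self.measurement, self.scenario, m)
            for m in ("frequency_shift", "torque_balance")
        }
        primary = est[method]

        ci = None
        se = float("nan")
        boot: np.ndarray | None = None
        if n_boot > 0 and not primary.flagged:
            boot = self._bootstrap(primary.E_hat, method, n_boot, seed)
            lo, hi = np.percentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
            ci = (float(lo), float(hi))
            se = float(np.std(boot, ddof=1))

        label, z = classify_cell(primary.E_hat)
        return CellModulusResults(
            model=self, method=method, estimates=est,
            E_hat=primary.E_hat, k_zc_hat=primary.k_zc_hat,
            se=se, ci=ci, alpha=alpha, classification=label, z_scores=z,
            flagged=primary.flagged, bootstrap_samples=boot,
        )

    # -- internals ---------------------------------------------------------

    def _model_curve(self, E_hat: float) -> np.ndarray:
        """Noiseless model amplitudes at the measurement frequencies, for the
        fitted modulus."""
        cell = self.scenario.cell
        scn = self.scenario.with_cell(
            CellModel(E_c=E_hat, v=cell.v, R=cell.R, label=cell.label)
        )
        omega = 2.0 * np.pi * self.measurement["frequency_hz"].to_numpy(dtype=float)
        params = assemble_motion_equation(scn)
        return ritz_response(params, omega).sweep_up()

    def _bootstrap(self, E_hat: float, method: str, n_boot: int,
                   seed: int) -> np.ndarray:
        omega = 2.0 * np.pi * self.measurement["frequency_hz"].to_numpy(dtype=float)
        amp = self.measurement["amplitude_rad"].to_numpy(dtype=float)
        model = self._model_curve(E_hat)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(model > 0, amp / model, 1.0)
        rng = np.random.default_rng(seed)
        A1, A3 = unit_modulus_coefficients(self.scenario.cell, self.scenario)
        out = np.empty(n_boot)
        for b in range(n_boot):
            resampled = model * rng.choice(ratio, size=len(ratio), replace=True)
            out[b], _, _ = _estimate_from_arrays(
                omega, resampled, self.scenario, A1, A3, method
            )
        return out


@dataclass
class CellModulusResults:
    """Results of :meth:`CellModulusModel.fit`."""

    model: CellModulusModel
    method: str
    estimates: dict[str, ModulusEstimate]
    E_hat: float
    k_zc_hat: float
    se: float
    ci: Optional[tuple[float, float]]
    alpha: float
    classification: str
    z_scores: dict[str, float]
    flagged: bool
    bootstrap_samples: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def f_free_hz(self) -> float:
        scn = self.model.scenario
        return resonant_frequency(
            suspension_stiffness(scn.suspension).k_tz, scn.inertia.J_b
        )

    def conf_int(self) -> Optional[tuple[float, float]]:
        return self.ci

    def summary(self) -> str:
        lines = [
            "Cell modulus estimation",
            "=" * 56,
            f"method:            {self.method}",
            f"E_hat:             {self.E_hat:.4g} Pa",
            f"k_zc_hat:          {self.k_zc_hat:.4g} N m/rad",
            f"bootstrap se:      {self.se:.3g} Pa",
        ]
        if self.ci is not None:
            lines.append(
                f"{100*(1-self.alpha):.0f}% CI:            "
                f"({self.ci[0]:.4g}, {self.ci[1]:.4g}) Pa"
            )
        lines.append(f"free resonance:    {self.f_free_hz:.1f} Hz")
        lines.append("-" * 56)
        for m, e in self.estimates.items():
            tag = " (flagged)" if e.flagged else ""
            lines.append(f"  {m:<17s} E = {e.E_hat:.4g} Pa{tag}")
        lines.append("-" * 56)
        lines.append(f"classification:    {self.classification}")
        for lab, z in sorted(self.z_scores.items(), key=lambda kv: abs(kv[1])):
            lines.append(f"  z({lab:<6s})        {z:+.2f}")
        return "\n".join(lines)
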