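"""Synthetic data: cell populations and noisy frequency-response
"measurements" standing in for the capacitive read-out of a real device.

Reference values for the three prostate-cell lines (elastic modulus mean ±
sd in Pa, radius in m) come from published AFM indentation measurements:
BHP (benign hyperplasia), PC-3 and LNCaP (carcinoma lines, progressively
softer).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CellModel, Scenario
from .dynamics import assemble_motion_equation, ritz_response

__all__ = [
    "CELL_REFERENCES",
    "reference_cell",
    "make_cell_population",
    "frequency_grid",
    "make_synthetic_measurement",
]

#: label -> (mean modulus Pa, sd Pa, radius m)
CELL_REFERENCES: dict[str, tuple[float, float, float]] = {
    "BHP": (2797.0, 491.0, 10e-6),
    "PC-3": (1401.0, 162.0, 10e-6),
    "LNCaP": (287.0, 52.0, 10e-6),
}

_ALIASES = {"PC3": "PC-3", "LNCAP": "LNCaP", "BHP": "BHP", "PC-3": "PC-3",
            "LNCaP": "LNCaP"}


def _canonical(label: str) -> str:
    key = _ALIASES.get(label) or _ALIASES.get(label.upper())
    if key is None:
        raise ValueError(
            f"unknown cell type {label!r}; known: {', '.join(CELL_REFERENCES)}"
        )
    return key


def reference_cell(label: str, modulus: float | None = None) -> CellModel:
    """A CellModel preset for one of the reference lines, with the mean
    modulus unless overridden."""
    key = _canonical(label)
    mean, _sd, radius = CELL_REFERENCES[key]
    return CellModel(E_c=modulus if modulus is not None else mean, v=0.5,
                     R=radius, label=key)


def make_cell_population(n_cells: int, cell_type: str, seed: int) -> list[CellModel]:
    """Draw a population of cells of one type.

    Moduli are drawn from a normal distribution with the reference mean and
    sd, truncated at E_c > 0 (by redraw); the radius is the fixed reference
    radius.  Deterministic under ``seed``.
    """
    if n_cells < 1:
        raise ValueError(f"n_cells must be >= 1, got {n_cells}")
    key = _canonical(cell_type)
    mean, sd, radius = CELL_REFERENCES[key]
    rng = np.random.default_rng(seed)
    draws = rng.normal(mean, sd, size=n_cells)
    while np.any(draws <= 0):  # truncation; essentially never at these CVs
        bad = draws <= 0
        draws[bad] = rng.normal(mean, sd, size=int(bad.sum()))
    return [CellModel(E_c=float(e), v=0.5, R=radius, label=key) for e in draws]


def frequency_grid(scn: Scenario) -> np.ndarray:
    """Angular-frequency grid (rad/s) from the scenario's solver settings."""
    s = scn.solver
    return 2.0 * np.pi * np.linspace(s.freq_min, s.freq_max, s.points)


def make_synthetic_measurement(scn: Scenario, noise_sd: float, seed: int) -> pd.DataFrame:
    """Simulate a measured amplitude spectrum.

    Runs the Ritz steady-state response on the scenario's frequency grid,
    selects the swept (stable) branch, and applies multiplicative Gaussian
    amplitude noise of relative sd ``noise_sd``.  Columns:
    ``frequency_hz``, ``amplitude_rad``.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    omega = frequency_grid(scn)
    params = assemble_motion_equation(scn)
    amp = ritz_response(params, omega).sweep_up()
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        amp = amp * (1.0 + noise_sd * rng.standard_normal(amp.shape))
    return pd.DataFrame({
        "frequency_hz": omega / (2.0 * np.pi),
        "amplitude_rad": amp,
    })
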