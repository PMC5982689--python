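"""Typed device and scenario configuration.

A :class:`Scenario` bundles everything needed to simulate the microgripper:
the two rotary comb actuators (a dc "electrostatic" bank used to open/close
the tips and an ac "electrodynamic" bank used to squeeze the gripped cell),
the serpentine-spring suspension, the rotational inertia of the mobile arm,
the slide-film damping geometry, tip kinematics, an optional cell, the drive
signal, and solver settings.

All fields of the in-memory dataclasses are SI.  Configuration files use the
micro-units natural for MEMS artwork; :func:`load_scenario` converts at the
boundary (see :mod:`gripsim.units`).
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .units import ConfigurationError, format_quantity, parse_quantity

__all__ = [
    "CombDriveGeometry",
    "StiffnessSet",
    "BeamSegment",
    "SuspensionModel",
    "InertiaModel",
    "PlateBody",
    "SidewallGroup",
    "DampingGeometry",
    "CellModel",
    "KinematicsModel",
    "DriveSignal",
    "SolverSettings",
    "Scenario",
    "load_scenario",
    "save_scenario",
    "scenario_from_dict",
    "scenario_to_dict",
    "preset_path",
    "available_presets",
    "ConfigurationError",
]


def _require_positive(name: str, value: float) -> None:
    if not (value > 0):
        raise ConfigurationError(f"{name}: must be > 0, got {value}")


def _require_nonnegative(name: str, value: float) -> None:
    if not (value >= 0):
        raise ConfigurationError(f"{name}: must be >= 0, got {value}")


@dataclass(frozen=True)
class CombDriveGeometry:
    """Rotary comb-drive electrode bank.

    Parameters (SI): ``R0`` inner radius of the first finger, ``Wf`` finger
    width, ``g`` finger gap, ``h`` finger thickness, ``n`` finger pairs per
    structural layer, ``layers`` mobile layers carrying fingers, ``theta0``
    initial overlap angle.
    """

    R0: float
    Wf: float
    g: float
    h: float
    n: int
    layers: int = 1
    theta0: float = math.radians(6.0)

    def __post_init__(self) -> None:
        for name in ("R0", "Wf", "g", "h"):
            _require_positive(f"comb.{name}", getattr(self, name))
        if self.n < 2:
            raise ConfigurationError(f"comb.n: need at least 2 finger pairs, got {self.n}")
        if self.layers < 1:
            raise ConfigurationError(f"comb.layers: must be >= 1, got {self.layers}")
        if not (0 < self.theta0 < math.pi / 2):
            raise ConfigurationError(
                f"comb.theta0: must lie in (0, pi/2) rad, got {self.theta0}"
            )


@dataclass(frozen=True)
class StiffnessSet:
    """Suspension stiffness of the two-spring assembly (SI: N m rad^-1, N m^-1)."""

    k_tz: float
    k_tx: float
    k_Fx: float
    k_Fy: float
    k_Fz: float

    def __post_init__(self) -> None:
        for name in ("k_tz", "k_tx", "k_Fx", "k_Fy", "k_Fz"):
            _require_positive(f"stiffness.{name}", getattr(self, name))


@dataclass(frozen=True)
class BeamSegment:
    """One straight beam of a serpentine spring.

    ``axis`` is a unit vector in the device plane pointing from the segment's
    start toward its end; segments are listed from the connection point
    (where loads act) to the anchor and are contiguous unless ``offset``
    places the first segment away from the connection point.
    ``b`` is the in-plane width, ``h`` the out-of-plane height.
    """

    L: float
    b: float
    h: float
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("L", "b", "h"):
            _require_positive(f"beam.{name}", getattr(self, name))
        norm = math.sqrt(sum(a * a for a in self.axis))
        if abs(norm - 1.0) > 1e-9:
            raise ConfigurationError(f"beam.axis: must be unit-norm, |axis| = {norm}")
        if abs(self.axis[2]) > 1e-12:
            raise ConfigurationError("beam.axis: must lie in the device (xy) plane")


@dataclass(frozen=True)
class SuspensionModel:
    """Suspension: either a directly specified stiffness set or serpentine
    beam geometry from which stiffness is derived by Castigliano's theorem.

    ``E``, ``nu_poly``, ``rho`` are polysilicon properties (SI).
    """

    mode: str
    E: float = 160e9
    nu_poly: float = 0.23
    rho: float = 2330.0
    stiffness: Optional[StiffnessSet] = None
    beams: Optional[tuple[BeamSegment, ...]] = None
    n_springs: int = 2

    def __post_init__(self) -> None:
        if self.mode not in ("direct", "castigliano"):
            raise ConfigurationError(
                f"suspension.mode: expected 'direct' or 'castigliano', got {self.mode!r}"
            )
        _require_positive("suspension.E", self.E)
        _require_positive("suspension.rho", self.rho)
        if not (0 < self.nu_poly < 0.5):
            raise ConfigurationError(
                f"suspension.nu_poly: must lie in (0, 0.5), got {self.nu_poly}"
            )
        if self.mode == "direct":
            if self.stiffness is None or self.beams is not None:
                raise ConfigurationError(
                    "suspension: mode 'direct' requires 'stiffness' and no 'beams'"
                )
        else:
            if self.beams is None or self.stiffness is not None:
                raise ConfigurationError(
                    "suspension: mode 'castigliano' requires 'beams' and no 'stiffness'"
                )
            if len(self.beams) < 1:
                raise ConfigurationError("suspension.beams: need at least one segment")
        if self.n_springs < 1:
            raise ConfigurationError("suspension.n_springs: must be >= 1")

    @property
    def shear_modulus(self) -> float:
        return self.E / (2.0 * (1.0 + self.nu_poly))


@dataclass(frozen=True)
class InertiaModel:
    """Polar mass moment of inertia of the mobile arm about the pivot (kg m^2)."""

    J_b: float

    def __post_init__(self) -> None:
        _require_positive("inertia.J_b", self.J_b)


@dataclass(frozen=True)
class PlateBody:
    """One body of the mobile arm for slide-film damping.

    ``A_p``: surface area facing the substrate (zero if the body is not above
    the substrate); ``r_am``: lever from the pivot to the body's drag
    centroid; ``l_am``: body half-length.  SI units.
    """

    A_p: float
    r_am: float
    l_am: float

    def __post_init__(self) -> None:
        _require_nonnegative("damping.body.A_p", self.A_p)
        _require_nonnegative("damping.body.r_am", self.r_am)
        _require_nonnegative("damping.body.l_am", self.l_am)


@dataclass(frozen=True)
class SidewallGroup:
    """A group of identical comb-finger sidewalls: area per finger, lever
    from the pivot, and finger count."""

    A_sn: float
    r_am4: float
    count: int = 1

    def __post_init__(self) -> None:
        _require_nonnegative("damping.sidewall.A_sn", self.A_sn)
        _require_nonnegative("damping.sidewall.r_am4", self.r_am4)
        if self.count < 1:
            raise ConfigurationError("damping.sidewall.count: must be >= 1")


@dataclass(frozen=True)
class DampingGeometry:
    """Geometry entering the slide-film air-damping model (SI)."""

    bodies: tuple[PlateBody, ...]
    d_p: float
    sidewalls: tuple[SidewallGroup, ...]
    g: float
    mu: float = 1.81e-5

    def __post_init__(self) -> None:
        _require_positive("damping.d_p", self.d_p)
        _require_positive("damping.g", self.g)
        _require_positive("damping.mu", self.mu)


@dataclass(frozen=True)
class CellModel:
    """Gripped cell: elastic modulus ``E_c`` (Pa), Poisson ratio ``v``,
    radius ``R`` (m).  ``v = 0.5`` is the incompressible limit commonly
    assumed for cells."""

    E_c: float
    v: float = 0.5
    R: float = 10e-6
    label: str = "cell"

    def __post_init__(self) -> None:
        _require_positive("cell.E_c", self.E_c)
        if not (0 <= self.v <= 0.5):
            raise ConfigurationError(f"cell.v: must lie in [0, 0.5], got {self.v}")
        _require_positive("cell.R", self.R)


@dataclass(frozen=True)
class KinematicsModel:
    """Tip kinematics: ``r_tip`` lever from pivot to gripper tip, ``gap0``
    initial tip separation, ``r_c`` lever of the cell-contact force (SI)."""

    r_tip: float = 250e-6
    gap0: float = 40e-6
    r_c: float = 2500e-6

    def __post_init__(self) -> None:
        for name in ("r_tip", "gap0", "r_c"):
            _require_positive(f"kinematics.{name}", getattr(self, name))


@dataclass(frozen=True)
class DriveSignal:
    """Drive voltages: push-pull dc offset ``V0`` and ac amplitude ``V1`` at
    angular frequency ``omega`` for the electrodynamic bank; ``Vdc`` for the
    dc-only electrostatic bank."""

    V0: float = 0.0
    V1: float = 0.0
    omega: float = 0.0
    Vdc: float = 0.0

    def __post_init__(self) -> None:
        for name in ("V0", "V1", "omega", "Vdc"):
            _require_nonnegative(f"drive.{name}", getattr(self, name))


@dataclass(frozen=True)
class SolverSettings:
    """Numerical settings: frequency grid (Hz), branch policy for the Duffing
    sweep, ODE tolerances for the time-domain oracle, RNG seed for fixtures,
    and truncation of the torsion-constant series."""

    freq_min: float = 350.0
    freq_max: float = 900.0
    points: int = 1201
    branch_policy: str = "stable"
    ode_rtol: float = 1e-9
    ode_atol: float = 1e-12
    seed: int = 0
    series_terms: int = 12

    def __post_init__(self) -> None:
        if not (self.freq_min < self.freq_max):
            raise ConfigurationError("solver: freq_min must be < freq_max")
        if self.points < 2:
            raise ConfigurationError("solver.points: must be >= 2")
        if self.branch_policy not in ("lowest", "all", "stable"):
            raise ConfigurationError(
                f"solver.branch_policy: unknown policy {self.branch_policy!r}"
            )
        for name in ("ode_rtol", "ode_atol"):
            _require_positive(f"solver.{name}", getattr(self, name))
        if self.series_terms < 1:
            raise ConfigurationError("solver.series_terms: must be >= 1")


@dataclass(frozen=True)
class Scenario:
    """A complete, validated simulation scenario (all SI)."""

    comb_electrostatic: CombDriveGeometry
    comb_electrodynamic: CombDriveGeometry
    suspension: SuspensionModel
    inertia: InertiaModel
    damping: DampingGeometry
    kinematics: KinematicsModel
    drive: DriveSignal = field(default_factory=DriveSignal)
    solver: SolverSettings = field(default_factory=SolverSettings)
    cell: Optional[CellModel] = None

    def with_cell(self, cell: Optional[CellModel]) -> "Scenario":
        return dataclasses.replace(self, cell=cell)

    def with_drive(self, drive: DriveSignal) -> "Scenario":
        return dataclasses.replace(self, drive=drive)


# ---------------------------------------------------------------------------
# YAML (de)serialisation


def _get(d: dict, key: str, section: str):
    if key not in d:
        raise ConfigurationError(f"{section}.{key}: missing required field")
    return d[key]


def _comb_from_dict(d: dict, section: str) -> CombDriveGeometry:
    return CombDriveGeometry(
        R0=parse_quantity(_get(d, "R0", section), "length", "um", f"{section}.R0"),
        Wf=parse_quantity(_get(d, "Wf", section), "length", "um", f"{section}.Wf"),
        g=parse_quantity(_get(d, "g", section), "length", "um", f"{section}.g"),
        h=parse_quantity(_get(d, "h", section), "length", "um", f"{section}.h"),
        n=int(_get(d, "n", section)),
        layers=int(d.get("layers", 1)),
        theta0=parse_quantity(
            d.get("theta0", "6 deg"), "angle", "rad", f"{section}.theta0"
        ),
    )


def _comb_to_dict(c: CombDriveGeometry) -> dict:
    return {
        "R0": format_quantity(c.R0, "length"),
        "Wf": format_quantity(c.Wf, "length"),
        "g": format_quantity(c.g, "length"),
        "h": format_quantity(c.h, "length"),
        "n": c.n,
        "layers": c.layers,
        "theta0": format_quantity(c.theta0, "angle"),
    }


def _suspension_from_dict(d: dict) -> SuspensionModel:
    mode = _get(d, "mode", "suspension")
    kwargs: dict = {
        "mode": mode,
        "E": parse_quantity(d.get("E", "160 GPa"), "pressure", "Pa", "suspension.E"),
        "nu_poly": float(d.get("nu_poly", 0.23)),
        "rho": parse_quantity(
            d.get("rho", 2330.0), "density", "kg/m^3", "suspension.rho"
        ),
        "n_springs": int(d.get("n_springs", 2)),
    }
    if mode == "direct":
        s = _get(d, "stiffness", "suspension")
        kwargs["stiffness"] = StiffnessSet(
            k_tz=parse_quantity(_get(s, "k_tz", "stiffness"), "rot_stiffness",
                                "uN*um/rad", "stiffness.k_tz"),
            k_tx=parse_quantity(_get(s, "k_tx", "stiffness"), "rot_stiffness",
                                "uN*um/rad", "stiffness.k_tx"),
            k_Fx=parse_quantity(_get(s, "k_Fx", "stiffness"), "lin_stiffness",
                                "uN/um", "stiffness.k_Fx"),
            k_Fy=parse_quantity(_get(s, "k_Fy", "stiffness"), "lin_stiffness",
                                "uN/um", "stiffness.k_Fy"),
            k_Fz=parse_quantity(_get(s, "k_Fz", "stiffness"), "lin_stiffness",
                                "uN/um", "stiffness.k_Fz"),
        )
    elif mode == "castigliano":
        beams = []
        for i, b in enumerate(_get(d, "beams", "suspension")):
            sec = f"suspension.beams[{i}]"
            beams.append(
                BeamSegment(
                    L=parse_quantity(_get(b, "L", sec), "length", "um", f"{sec}.L"),
                    b=parse_quantity(_get(b, "b", sec), "length", "um", f"{sec}.b"),
                    h=parse_quantity(_get(b, "h", sec), "length", "um", f"{sec}.h"),
                    axis=tuple(float(x) for x in b.get("axis", (1.0, 0.0, 0.0))),
                    offset=tuple(
                        parse_quantity(x, "length", "um", f"{sec}.offset")
                        for x in b.get("offset", (0.0, 0.0, 0.0))
                    ),
                )
            )
        kwargs["beams"] = tuple(beams)
    return SuspensionModel(**kwargs)


def _suspension_to_dict(s: SuspensionModel) -> dict:
    d: dict = {
        "mode": s.mode,
        "E": format_quantity(s.E, "pressure"),
        "nu_poly": s.nu_poly,
        "rho": format_quantity(s.rho, "density"),
        "n_springs": s.n_springs,
    }
    if s.stiffness is not None:
        d["stiffness"] = {
            "k_tz": format_quantity(s.stiffness.k_tz, "rot_stiffness"),
            "k_tx": format_quantity(s.stiffness.k_tx, "rot_stiffness"),
            "k_Fx": format_quantity(s.stiffness.k_Fx, "lin_stiffness"),
            "k_Fy": format_quantity(s.stiffness.k_Fy, "lin_stiffness"),
            "k_Fz": format_quantity(s.stiffness.k_Fz, "lin_stiffness"),
        }
    if s.beams is not None:
        d["beams"] = [
            {
                "L": format_quantity(b.L, "length"),
                "b": format_quantity(b.b, "length"),
                "h": format_quantity(b.h, "length"),
                "axis": list(b.axis),
                "offset": [format_quantity(x, "length") for x in b.offset],
            }
            for b in s.beams
        ]
    return d


def _damping_from_dict(d: dict) -> DampingGeometry:
    bodies = tuple(
        PlateBody(
            A_p=parse_quantity(b.get("A_p", 0.0), "area", "um^2",
                               f"damping.bodies[{i}].A_p"),
            r_am=parse_quantity(_get(b, "r_am", f"damping.bodies[{i}]"), "length",
                                "um", f"damping.bodies[{i}].r_am"),
            l_am=parse_quantity(_get(b, "l_am", f"damping.bodies[{i}]"), "length",
                                "um", f"damping.bodies[{i}].l_am"),
        )
        for i, b in enumerate(_get(d, "bodies", "damping"))
    )
    sidewalls = tuple(
        SidewallGroup(
            A_sn=parse_quantity(_get(s, "A_sn", f"damping.sidewalls[{i}]"), "area",
                                "um^2", f"damping.sidewalls[{i}].A_sn"),
            r_am4=parse_quantity(_get(s, "r_am4", f"damping.sidewalls[{i}]"),
                                 "length", "um", f"damping.sidewalls[{i}].r_am4"),
            count=int(s.get("count", 1)),
        )
        for i, s in enumerate(d.get("sidewalls", []))
    )
    return DampingGeometry(
        bodies=bodies,
        d_p=parse_quantity(d.get("d_p", "2 um"), "length", "um", "damping.d_p"),
        sidewalls=sidewalls,
        g=parse_quantity(d.get("g", "2 um"), "length", "um", "damping.g"),
        mu=parse_quantity(d.get("mu", 1.81e-5), "viscosity", "Pa*s", "damping.mu"),
    )


def _damping_to_dict(g: DampingGeometry) -> dict:
    return {
        "bodies": [
            {
                "A_p": format_quantity(b.A_p, "area"),
                "r_am": format_quantity(b.r_am, "length"),
                "l_am": format_quantity(b.l_am, "length"),
            }
            for b in g.bodies
        ],
        "d_p": format_quantity(g.d_p, "length"),
        "sidewalls": [
            {
                "A_sn": format_quantity(s.A_sn, "area"),
                "r_am4": format_quantity(s.r_am4, "length"),
                "count": s.count,
            }
            for s in g.sidewalls
        ],
        "g": format_quantity(g.g, "length"),
        "mu": format_quantity(g.mu, "viscosity"),
    }


def scenario_from_dict(raw: dict) -> Scenario:
    """Build a validated :class:`Scenario` from a parsed configuration dict."""
    if not isinstance(raw, dict):
        raise ConfigurationError("scenario: top level must be a mapping")
    kin = raw.get("kinematics", {})
    drive = raw.get("drive", {})
    solver = raw.get("solver", {})
    cell = raw.get("cell")
    return Scenario(
        comb_electrostatic=_comb_from_dict(
            _get(raw, "comb_electrostatic", "scenario"), "comb_electrostatic"
        ),
        comb_electrodynamic=_comb_from_dict(
            _get(raw, "comb_electrodynamic", "scenario"), "comb_electrodynamic"
        ),
        suspension=_suspension_from_dict(_get(raw, "suspension", "scenario")),
        inertia=InertiaModel(
            J_b=parse_quantity(
                _get(_get(raw, "inertia", "scenario"), "J_b", "inertia"),
                "inertia", "kg*um^2", "inertia.J_b",
            )
        ),
        damping=_damping_from_dict(_get(raw, "damping", "scenario")),
        kinematics=KinematicsModel(
            r_tip=parse_quantity(kin.get("r_tip", "250 um"), "length", "um",
                                 "kinematics.r_tip"),
            gap0=parse_quantity(kin.get("gap0", "40 um"), "length", "um",
                                "kinematics.gap0"),
            r_c=parse_quantity(kin.get("r_c", "2500 um"), "length", "um",
                               "kinematics.r_c"),
        ),
        drive=DriveSignal(
            V0=parse_quantity(drive.get("V0", 0.0), "voltage", "V", "drive.V0"),
            V1=parse_quantity(drive.get("V1", 0.0), "voltage", "V", "drive.V1"),
            omega=2.0 * math.pi * parse_quantity(
                drive.get("f_hz", 0.0), "frequency", "Hz", "drive.f_hz"
            ),
            Vdc=parse_quantity(drive.get("Vdc", 0.0), "voltage", "V", "drive.Vdc"),
        ),
        solver=SolverSettings(
            freq_min=parse_quantity(solver.get("freq_min", 350.0), "frequency",
                                    "Hz", "solver.freq_min"),
            freq_max=parse_quantity(solver.get("freq_max", 900.0), "frequency",
                                    "Hz", "solver.freq_max"),
            points=int(solver.get("points", 1201)),
            branch_policy=str(solver.get("branch_policy", "stable")),
            ode_rtol=float(solver.get("ode_rtol", 1e-9)),
            ode_atol=float(solver.get("ode_atol", 1e-12)),
            seed=int(solver.get("seed", 0)),
            series_terms=int(solver.get("series_terms", 12)),
        ),
        cell=None if cell is None else CellModel(
            E_c=parse_quantity(_get(cell, "E_c", "cell"), "pressure", "Pa",
                               "cell.E_c"),
            v=float(cell.get("v", 0.5)),
            R=parse_quantity(cell.get("R", "10 um"), "length", "um", "cell.R"),
            label=str(cell.get("label", "cell")),
        ),
    )


def scenario_to_dict(scn: Scenario) -> dict:
    """Inverse of :func:`scenario_from_dict` (canonical micro-units)."""
    d: dict = {
        "comb_electrostatic": _comb_to_dict(scn.comb_electrostatic),
        "comb_electrodynamic": _comb_to_dict(scn.comb_electrodynamic),
        "suspension": _suspension_to_dict(scn.suspension),
        "inertia": {"J_b": format_quantity(scn.inertia.J_b, "inertia")},
        "damping": _damping_to_dict(scn.damping),
        "kinematics": {
            "r_tip": format_quantity(scn.kinematics.r_tip, "length"),
            "gap0": format_quantity(scn.kinematics.gap0, "length"),
            "r_c": format_quantity(scn.kinematics.r_c, "length"),
        },
        "drive": {
            "V0": format_quantity(scn.drive.V0, "voltage"),
            "V1": format_quantity(scn.drive.V1, "voltage"),
            "f_hz": format_quantity(scn.drive.omega / (2.0 * math.pi), "frequency"),
            "Vdc": format_quantity(scn.drive.Vdc, "voltage"),
        },
        "solver": {
            "freq_min": format_quantity(scn.solver.freq_min, "frequency"),
            "freq_max": format_quantity(scn.solver.freq_max, "frequency"),
            "points": scn.solver.points,
            "branch_policy": scn.solver.branch_policy,
            "ode_rtol": scn.solver.ode_rtol,
            "ode_atol": scn.solver.ode_atol,
            "seed": scn.solver.seed,
            "series_terms": scn.solver.series_terms,
        },
    }
    if scn.cell is not None:
        d["cell"] = {
            "E_c": format_quantity(scn.cell.E_c, "pressure"),
            "v": scn.cell.v,
            "R": format_quantity(scn.cell.R, "length"),
            "label": scn.cell.label,
        }
    return d


def available_presets() -> list[str]:
    root = importlib.resources.files("gripsim") / "presets"
    return sorted(p.name[: -len(".yaml")] for p in root.iterdir()
                  if p.name.endswith(".yaml"))


def preset_path(name: str) -> Path:
    """Filesystem path of a packaged preset (``paper_default``, ``cell_BHP``,
    ``cell_PC3``, ``cell_LNCaP``)."""
    root = importlib.resources.files("gripsim") / "presets"
    p = root / f"{name}.yaml"
    if not p.is_file():
        raise ConfigurationError(
            f"unknown preset {name!r}; available: {', '.join(available_presets())}"
        )
    return Path(str(p))


def load_scenario(path) -> Scenario:
    """Load and validate a scenario from a YAML file or packaged preset name.

    Supports a top-level ``extends: <preset name>`` key whose sections are
    used as defaults for any section absent from the file.
    """
    p = Path(path)
    if not p.is_file() and not p.suffix:
        p = preset_path(str(path))
    if not p.is_file():
        raise ConfigurationError(f"configuration file not found: {path}")
    with open(p, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raise ConfigurationError(f"{path}: empty configuration file")
    base_name = raw.pop("extends", None)
    if base_name is not None:
        with open(preset_path(base_name), "r", encoding="utf-8") as fh:
            base = yaml.safe_load(fh)
        base.pop("extends", None)
        for key, value in raw.items():
            base[key] = value
        raw = base
    return scenario_from_dict(raw)


def save_scenario(scn: Scenario, path) -> None:
    """Write a scenario to YAML in canonical micro-units (round-trips through
    :func:`load_scenario` to better than 12 significant digits)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(scenario_to_dict(scn), fh, sort_keys=False)
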