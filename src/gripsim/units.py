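"""Unit handling at the configuration boundary.

Device artwork and cell parameters are naturally written in micro-units
(µm, µN·µm/rad, kg·µm²) while all physics inside the package is SI
(m, kg, s, N, F, Pa).  Conversion happens exactly once, when a scenario
is loaded, and once more on save; nothing else in the package ever sees
a non-SI number.

A quantity in a configuration file is either a bare number (interpreted
in the field's documented default unit) or a string ``"<number> <unit>"``
such as ``"400 um"`` or ``"49557 uN*um/rad"``.
"""

from __future__ import annotations

import math

__all__ = ["ConfigurationError", "to_si", "from_si", "parse_quantity", "format_quantity"]


class ConfigurationError(ValueError):
    """A configuration file is missing a field, carries an unknown unit,
    or violates an invariant.  The message always names the field."""


#: unit symbol -> (dimension kind, multiplicative factor to SI)
_UNITS: dict[str, tuple[str, float]] = {
    # length
    "m": ("length", 1.0),
    "mm": ("length", 1e-3),
    "um": ("length", 1e-6),
    "nm": ("length", 1e-9),
    # angle
    "rad": ("angle", 1.0),
    "deg": ("angle", math.pi / 180.0),
    # electric potential
    "V": ("voltage", 1.0),
    # pressure / elastic modulus
    "Pa": ("pressure", 1.0),
    "kPa": ("pressure", 1e3),
    "MPa": ("pressure", 1e6),
    "GPa": ("pressure", 1e9),
    # dynamic viscosity
    "Pa*s": ("viscosity", 1.0),
    # area
    "m^2": ("area", 1.0),
    "um^2": ("area", 1e-12),
    # rotational inertia
    "kg*m^2": ("inertia", 1.0),
    "kg*um^2": ("inertia", 1e-12),
    # rotational stiffness (torque per radian)
    "N*m/rad": ("rot_stiffness", 1.0),
    "uN*um/rad": ("rot_stiffness", 1e-12),
    # translational stiffness
    "N/m": ("lin_stiffness", 1.0),
    "uN/um": ("lin_stiffness", 1.0),
    # frequency
    "Hz": ("frequency", 1.0),
    # density
    "kg/m^3": ("density", 1.0),
    # dimensionless
    "": ("dimensionless", 1.0),
    "1": ("dimensionless", 1.0),
}

#: dimension kind -> unit used when writing configuration files
_CANONICAL_OUT: dict[str, str] = {
    "length": "um",
    "angle": "rad",
    "voltage": "V",
    "pressure": "Pa",
    "viscosity": "Pa*s",
    "area": "um^2",
    "inertia": "kg*um^2",
    "rot_stiffness": "uN*um/rad",
    "lin_stiffness": "uN/um",
    "frequency": "Hz",
    "density": "kg/m^3",
    "dimensionless": "",
}


def to_si(value: float, unit: str, kind: str, field: str = "?") -> float:
    """Convert ``value`` expressed in ``unit`` to SI, checking the dimension."""
    try:
        got_kind, factor = _UNITS[unit]
    except KeyError:
        raise ConfigurationError(f"{field}: unknown unit {unit!r}") from None
    if got_kind != kind:
        raise ConfigurationError(
            f"{field}: unit {unit!r} has dimension {got_kind}, expected {kind}"
        )
    return value * factor


def from_si(value: float, kind: str) -> tuple[float, str]:
    """Convert an SI value to the canonical configuration-file unit."""
    unit = _CANONICAL_OUT[kind]
    return value / _UNITS[unit][1], unit


def parse_quantity(raw, kind: str, default_unit: str, field: str = "?") -> float:
    """Parse a YAML scalar into an SI float.

    Accepts a bare number (``default_unit`` assumed), a ``"value unit"``
    string, or a ``{value:, unit:}`` mapping.
    """
    if isinstance(raw, bool):
        raise ConfigurationError(f"{field}: expected a quantity, got a boolean")
    if isinstance(raw, (int, float)):
        return to_si(float(raw), default_unit, kind, field)
    if isinstance(raw, str):
        parts = raw.split(None, 1)
        try:
            value = float(parts[0])
        except (ValueError, IndexError):
            raise ConfigurationError(f"{field}: cannot parse quantity {raw!r}") from None
        unit = parts[1].strip() if len(parts) > 1 else default_unit
        return to_si(value, unit, kind, field)
    if isinstance(raw, dict):
        try:
            value = float(raw["value"])
        except (KeyError, TypeError, ValueError):
            raise ConfigurationError(f"{field}: malformed quantity mapping {raw!r}") from None
        unit = raw.get("unit", default_unit)
        return to_si(value, unit, kind, field)
    raise ConfigurationError(f"{field}: cannot parse quantity {raw!r}")


def format_quantity(value_si: float, kind: str) -> str:
    """Render an SI value as a ``"value unit"`` string in canonical units,
    with enough digits for a 12-significant-digit round trip."""
    value, unit = from_si(value_si, kind)
    text = repr(float(value))
    return f"{text} {unit}".strip()
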