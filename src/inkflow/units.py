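"""Unit conversions at the package boundary.

Internally every quantity is strict SI (m, Pa, s, Pa·s). Print-run tables and
vendor documentation mix micrometres for widths/diameters, multiples of
10⁵ Pa for gauge pressures, and centipoise for viscosities; these helpers
convert at the I/O boundary only, so the physics modules never see a
non-SI number.
"""

from __future__ import annotations

import re

from .exceptions import DomainError

UM_PER_M = 1e6
PA_S_PER_CP = 1e-3
PA_PER_BAR = 1e5

#: multiplicative factors mapping a pressure-unit suffix to pascals
_PRESSURE_SUFFIXES = {
    "pa": 1.0,
    "kpa": 1e3,
    "mpa": 1e6,
    "bar": PA_PER_BAR,
}

_PRESSURE_RE = re.compile(
    r"^\s*([-+]?\d+\.?\d*(?:[eE][-+]?\d+)?)\s*([a-zA-Z]*)\s*$"
)


def um_to_m(value_um: float) -> float:
    """Convert micrometres to metres."""
    return float(value_um) / UM_PER_M


def m_to_um(value_m: float) -> float:
    """Convert metres to micrometres."""
    return float(value_m) * UM_PER_M


def pa_s_to_cp(viscosity_pa_s: float) -> float:
    """Convert a viscosity from Pa·s to centipoise (1 Pa·s = 1000 cP)."""
    return float(viscosity_pa_s) / PA_S_PER_CP


def cp_to_pa_s(viscosity_cp: float) -> float:
    """Convert a viscosity from centipoise to Pa·s."""
    return float(viscosity_cp) * PA_S_PER_CP


def parse_pressure(value: float | str) -> float:
    """Parse a gauge pressure into pascals.

    Accepts plain numbers (taken as Pa), scientific notation strings such as
    ``"1e5"``, and suffixed forms such as ``"1bar"``, ``"250kPa"`` or
    ``"0.1 MPa"`` (case-insensitive, optional whitespace).

    Raises
    ------
    DomainError
        If the string is unparseable or the resulting pressure is not
        strictly positive.
    """
    if isinstance(value, (int, float)):
        pressure = float(value)
    else:
        match = _PRESSURE_RE.match(value)
        if match is None:
            raise DomainError(f"unparseable pressure: {value!r}")
        magnitude, suffix = match.groups()
        factor = _PRESSURE_SUFFIXES.get(suffix.lower(), None) if suffix else 1.0
        if factor is None:
            raise DomainError(
                f"unknown pressure unit {suffix!r} in {value!r}; "
                f"known units: {sorted(_PRESSURE_SUFFIXES)}"
            )
        pressure = float(magnitude) * factor
    if not pressure > 0:
        raise DomainError(f"gauge pressure must be positive, got {pressure} Pa")
    return pressure
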