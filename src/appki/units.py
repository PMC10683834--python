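"""Concentration unit handling.

Everything internal is mol/L and seconds. Interfaces accept tagged
quantities like ``"10 uM"`` or ``(10, "uM")`` and convert on entry.
"""
from __future__ import annotations

import re

#: multiplicative factors to mol/L
CONC_UNITS = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
}

_QTY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([mµunp]?M)\s*$")


def to_molar(value, unit: str | None = None) -> float:
    """Convert a concentration to mol/L.

    ``value`` may be a plain number (assumed mol/L when ``unit`` is None),
    a ``(number, unit)`` pair, or a string such as ``"5 nM"``.
    """
    if isinstance(value, str):
        m = _QTY_RE.match(value)
        if not m:
            raise ValueError(f"cannot parse concentration {value!r}")
        value, unit = float(m.group(1)), m.group(2)
    elif isinstance(value, (tuple, list)) and len(value) == 2:
        value, unit = float(value[0]), value[1]
    if unit is None:
        return float(value)
    try:
        return float(value) * CONC_UNITS[unit]
    except KeyError:
        raise ValueError(f"unknown concentration unit {unit!r}") from None


def from_molar(value_m: float, unit: str) -> float:
    """Express a mol/L concentration in the given unit."""
    try:
        return value_m / CONC_UNITS[unit]
    except KeyError:
        raise ValueError(f"unknown concentration unit {unit!r}") from None
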