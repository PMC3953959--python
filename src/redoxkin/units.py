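"""Unit conversion helpers.

All internal computation in :mod:`redoxkin` is strictly SI (concentrations in
mol/L, times in seconds).  User-facing layers (CLI, report tables) convert
from/to the units biologists actually quote (µM doses, response times in
minutes or hours) through this module, so unit handling lives in exactly one
place.
"""

from __future__ import annotations

__all__ = [
    "CONCENTRATION_UNITS",
    "TIME_UNITS",
    "to_molar",
    "from_molar",
    "to_seconds",
    "from_seconds",
    "round_sig",
]

#: multiplicative factors to mol/L
CONCENTRATION_UNITS: dict[str, float] = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "nM": 1e-9,
}

#: multiplicative factors to seconds
TIME_UNITS: dict[str, float] = {
    "s": 1.0,
    "min": 60.0,
    "h": 3600.0,
}


def _factor(unit: str, table: dict[str, float], kind: str) -> float:
    try:
        return table[unit]
    except KeyError:
        valid = ", ".join(sorted(table))
        raise ValueError(f"unknown {kind} unit {unit!r}; expected one of: {valid}") from None


def to_molar(value: float, unit: str) -> float:
    """Convert a concentration expressed in ``unit`` to mol/L."""
    return value * _factor(unit, CONCENTRATION_UNITS, "concentration")


def from_molar(value: float, unit: str) -> float:
    """Convert a concentration in mol/L to ``unit``."""
    return value / _factor(unit, CONCENTRATION_UNITS, "concentration")


def to_seconds(value: float, unit: str) -> float:
    """Convert a duration expressed in ``unit`` to seconds."""
    return value * _factor(unit, TIME_UNITS, "time")


def from_seconds(value: float, unit: str) -> float:
    """Convert a duration in seconds to ``unit``."""
    return value / _factor(unit, TIME_UNITS, "time")


def round_sig(value: float, sig_figs: int = 2) -> float:
    """Round ``value`` to ``sig_figs`` significant figures.

    Zero and non-finite values pass through unchanged.  Used for report
    output only; internal computation keeps full double precision.
    """
    if sig_figs < 1:
        raise ValueError("sig_figs must be >= 1")
    if value == 0 or value != value or value in (float("inf"), float("-inf")):
        return value
    return float(f"{value:.{sig_figs - 1}e}")
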