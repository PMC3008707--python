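"""Unit handling.

Package-wide defaults are millimolar (mmol/L) for concentrations and
seconds for time.  Stores declare units per entry and values are converted
to the defaults at load time, never at match or simulation time.
"""

from __future__ import annotations

CONCENTRATION_UNIT = "mM"
TIME_UNIT = "s"

# multiplicative factor to millimolar
_CONC_FACTORS = {
    "mM": 1.0,
    "mmol/l": 1.0,
    "mmol/L": 1.0,
    "M": 1e3,
    "mol/l": 1e3,
    "mol/L": 1e3,
    "uM": 1e-3,
    "umol/l": 1e-3,
    "umol/L": 1e-3,
    "µM": 1e-3,
    "nM": 1e-6,
}

# multiplicative factor to seconds
_TIME_FACTORS = {"s": 1.0, "sec": 1.0, "min": 60.0, "h": 3600.0, "hr": 3600.0}


class UnitError(ValueError):
    """Unknown or unconvertible unit tag."""


def to_millimolar(value: float, unit: str) -> float:
    try:
        return value * _CONC_FACTORS[unit]
    except KeyError:
        raise UnitError(f"unknown concentration unit {unit!r}") from None


def to_seconds(value: float, unit: str) -> float:
    try:
        return value * _TIME_FACTORS[unit]
    except KeyError:
        raise UnitError(f"unknown time unit {unit!r}") from None


def convert_rate_parameter(value: float, unit: str) -> float:
    """Convert a kinetic parameter value to the package unit system.

    Understood tags: concentration units (Km-like), ``<conc>/<time>``
    (Vmax-like), ``1/<time>`` or ``<time>^-1`` (first-order constants), and
    ``dimensionless``/"" (pass-through).
    """
    unit = unit.strip()
    if unit in ("", "dimensionless", "1"):
        return value
    if unit in _CONC_FACTORS:
        return to_millimolar(value, unit)
    if unit in _TIME_FACTORS:
        return value * _TIME_FACTORS[unit]
    if "/" in unit:
        num, _, den = unit.partition("/")
        num, den = num.strip(), den.strip()
        if num == "1" and den in _TIME_FACTORS:
            return value / _TIME_FACTORS[den]
        if num in _CONC_FACTORS and den in _TIME_FACTORS:
            return value * _CONC_FACTORS[num] / _TIME_FACTORS[den]
    raise UnitError(f"unknown unit {unit!r}")
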