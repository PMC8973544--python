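"""Unit handling for mass rates and surface densities.

Internal canon: acceptable-intake arithmetic runs in μg/day; surface
densities and dermal intakes run in ng/cm² and ng/day.  Conversions are
exact powers of ten (1 μg = 1000 ng = 1,000,000 pg).
"""

from __future__ import annotations

from decimal import Decimal

UG_PER_DAY_TO_NG = 1000.0

# surface-density unit → decimal exponent to ng/cm² (pg ÷1000, μg ×1000)
_SURFACE_EXPONENTS = {
    "pg_cm2": -3,
    "ng_cm2": 0,
    "ug_cm2": 3,
}

_ALIASES = {
    "pg/cm2": "pg_cm2",
    "pg/cm^2": "pg_cm2",
    "pg_per_cm2": "pg_cm2",
    "ng/cm2": "ng_cm2",
    "ng/cm^2": "ng_cm2",
    "ng_per_cm2": "ng_cm2",
    "ug/cm2": "ug_cm2",
    "ug/cm^2": "ug_cm2",
    "ug_per_cm2": "ug_cm2",
    "µg/cm2": "ug_cm2",
    "μg/cm2": "ug_cm2",
}

SURFACE_UNITS = tuple(_SURFACE_EXPONENTS)


class UnitError(ValueError):
    """Raised for unknown unit labels."""


def canonical_surface_unit(unit: str) -> str:
    u = unit.strip().lower()
    u = _ALIASES.get(u, u)
    if u not in _SURFACE_EXPONENTS:
        raise UnitError(f"unknown surface-density unit: {unit!r}")
    return u


def _scale(value: float, exponent: int) -> float:
    # decimal scaleb shifts the decimal exponent without rounding, so
    # up- and down-scaling by the same power of ten round-trip bit-exactly
    # (plain float multiplication by 1e-3 does not)
    if value < 0:
        raise ValueError(f"surface density must be >= 0, got {value}")
    if exponent == 0:
        return value
    return float(Decimal(repr(value)).scaleb(exponent))


def to_ng_per_cm2(value: float, unit: str) -> float:
    """Convert a surface density to ng/cm² (exact power-of-ten scaling)."""
    return _scale(value, _SURFACE_EXPONENTS[canonical_surface_unit(unit)])


def from_ng_per_cm2(value: float, unit: str) -> float:
    """Convert a surface density from ng/cm² into ``unit``."""
    return _scale(value, -_SURFACE_EXPONENTS[canonical_surface_unit(unit)])
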