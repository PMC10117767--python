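"""Fixed unit conversions and physical constants.

This is deliberately not a general-purpose unit library: only the handful of
conversions the nutrient-cycling pipeline needs are registered, each with a
single fixed factor, so every downstream number is traceable to one constant.
"""

from __future__ import annotations

__all__ = [
    "UnitConversionError",
    "convert",
    "registered_pairs",
    "US_GALLONS_PER_M3",
    "METERS_PER_MILE",
    "M2_PER_HA",
    "KJ_PER_KCAL",
    "NITROGEN_PER_PROTEIN",
    "CARBON_PER_GLUCOSE",
    "COD_PER_CARBON",
    "GLUCOSE_PER_O2",
    "O2_G_PER_MOL",
    "PERSON_N_G_PER_DAY",
    "DAYS_PER_YEAR",
    "LITERS_PER_M3",
]

US_GALLONS_PER_M3 = 264.172      # US liquid gallon
METERS_PER_MILE = 1609.34
M2_PER_HA = 10_000.0
KJ_PER_KCAL = 4.184
LITERS_PER_M3 = 1000.0

#: kg N per kg protein (Kjeldahl convention, N x 6.25).
NITROGEN_PER_PROTEIN = 0.16
#: kg carbon per kg glucose (72/180 rounded to the conventional 0.40).
CARBON_PER_GLUCOSE = 0.40
#: kg COD per kg of glucose carbon.
COD_PER_CARBON = 2.66
#: kg glucose oxidised per kg O2 consumed: C6H12O6 + 6 O2 -> 6 CO2 + 6 H2O,
#: i.e. 180 g glucose per 192 g O2.
GLUCOSE_PER_O2 = 180.0 / 192.0
O2_G_PER_MOL = 32.0
#: Human nitrogen excretion, g N per person per day.
PERSON_N_G_PER_DAY = 13.0
DAYS_PER_YEAR = 365.0


class UnitConversionError(ValueError):
    """Raised when a conversion between two units is not registered."""


# Canonical factors: value_in_right_unit = value_in_left_unit * factor.
_BASE_FACTORS: dict[tuple[str, str], float] = {
    ("m3", "us_gal"): US_GALLONS_PER_M3,
    ("L", "m3"): 1.0 / LITERS_PER_M3,
    ("L", "us_gal"): US_GALLONS_PER_M3 / LITERS_PER_M3,
    ("mile", "m"): METERS_PER_MILE,
    ("km", "m"): 1000.0,
    ("ha", "m2"): M2_PER_HA,
    ("kcal", "kJ"): KJ_PER_KCAL,
    ("Mg", "kg"): 1000.0,
    ("kg/ha", "kg/m2"): 1.0 / M2_PER_HA,
}

_FACTORS: dict[tuple[str, str], float] = {}
for (_a, _b), _f in _BASE_FACTORS.items():
    _FACTORS[(_a, _b)] = _f
    _FACTORS[(_b, _a)] = 1.0 / _f


def registered_pairs() -> tuple[tuple[str, str], ...]:
    """Return all registered (from_unit, to_unit) pairs."""
    return tuple(_FACTORS)


def convert(value: float, from_unit: str, to_unit: str) -> float:
    """Convert ``value`` between two registered units.

    Conversion is a single multiplication by a fixed constant, so the inverse
    conversion recovers the input to floating-point precision.

    Raises
    ------
    UnitConversionError
        If the unit pair is not registered.
    """
    if from_unit == to_unit:
        return value
    try:
        factor = _FACTORS[(from_unit, to_unit)]
    except KeyError:
        raise UnitConversionError(
            f"no registered conversion from {from_unit!r} to {to_unit!r}"
        ) from None
    return value * factor
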