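"""Humid-gas unit conversions under ideal-gas assumptions.

All humidity bookkeeping in this package runs internally on molar
fractions; this module is the single place where the laboratory units
(absolute humidity in mg water per litre of humid gas, water partial
pressure in Pa) are converted to and from that representation.

Saturation properties use a Magnus-form correlation for the vapour
pressure of water over liquid (Alduchov & Eskridge coefficients):

    e_s(t) = 610.94 * exp(17.625 * t / (t + 243.04))   [Pa, t in deg C]

The correlation is accepted over 253-373 K; outside that range a
``DomainError`` is raised rather than extrapolating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

__all__ = [
    "GAS_CONSTANT",
    "MOLAR_MASS_WATER",
    "STANDARD_PRESSURE",
    "CABINET_TEMPERATURE",
    "GasConditions",
    "DomainError",
    "SupersaturationWarning",
    "saturation_vapour_pressure",
    "saturated_absolute_humidity",
    "absolute_to_fraction",
    "fraction_to_absolute",
    "fraction_to_partial_pressure",
    "partial_pressure_to_fraction",
    "expansion_factor",
    "volume_to_moles",
    "moles_to_volume",
]

# Physical constants (CODATA R; molar mass of water in g/mol).
GAS_CONSTANT = 8.314462618  # J / (mol K)
MOLAR_MASS_WATER = 18.015  # g / mol

#: Default total pressure for interface conversions, Pa.
STANDARD_PRESSURE = 101_325.0
#: Default reference temperature for mg/l values: the 38 degC test cabinet, K.
CABINET_TEMPERATURE = 311.15

# Magnus correlation (Alduchov & Eskridge 1996), Pa / deg C.
_MAGNUS_A = 610.94
_MAGNUS_B = 17.625
_MAGNUS_C = 243.04
_MAGNUS_T_MIN = 253.0  # K
_MAGNUS_T_MAX = 373.0  # K


class DomainError(ValueError):
    """Input outside the physical or correlation validity domain."""


class SupersaturationWarning(UserWarning):
    """Absolute humidity above saturation at the stated conditions.

    Measurement noise can push readings past saturation; the value is
    used as given.
    """


@dataclass(frozen=True)
class GasConditions:
    """Temperature/pressure context for ideal-gas conversions.

    Parameters
    ----------
    temperature : float
        Thermodynamic temperature in K. Must be positive.
    pressure : float
        Total pressure in Pa. Must be positive.
    """

    temperature: float = CABINET_TEMPERATURE
    pressure: float = STANDARD_PRESSURE

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise DomainError(f"temperature must be > 0 K, got {self.temperature}")
        if not self.pressure > 0:
            raise DomainError(f"pressure must be > 0 Pa, got {self.pressure}")

    @classmethod
    def from_celsius(cls, temperature_c: float, pressure_pa: float = STANDARD_PRESSURE) -> "GasConditions":
        return cls(temperature=temperature_c + 273.15, pressure=pressure_pa)

    @property
    def molar_density(self) -> float:
        """Total moles of ideal gas per litre at these conditions."""
        return self.pressure / (GAS_CONSTANT * self.temperature) * 1e-3


#: Conditions of the test cabinet (38 degC, 1 atm) used throughout the rig.
CABINET = GasConditions()


def saturation_vapour_pressure(temperature: float) -> float:
    """Saturation partial pressure of water over liquid, in Pa.

    Parameters
    ----------
    temperature : float
        Temperature in K; must lie within the correlation validity
        range 253-373 K.
    """
    if not (_MAGNUS_T_MIN <= temperature <= _MAGNUS_T_MAX):
        raise DomainError(
            f"temperature {temperature} K outside Magnus correlation "
            f"validity range [{_MAGNUS_T_MIN}, {_MAGNUS_T_MAX}] K"
        )
    t_c = temperature - 273.15
    import math

    return _MAGNUS_A * math.exp(_MAGNUS_B * t_c / (t_c + _MAGNUS_C))


def saturated_absolute_humidity(temperature: float, pressure: float = STANDARD_PRESSURE) -> float:
    """Absolute humidity (mg/l) of water-vapour-saturated gas.

    Composed from :func:`saturation_vapour_pressure` and the ideal-gas
    density of water vapour, rho = e_s * M_w / (R T).  To first order
    the result does not depend on the total pressure; ``pressure`` is
    accepted for interface symmetry and validated only.
    """
    if not pressure > 0:
        raise DomainError("pressure must be positive")
    e_s = saturation_vapour_pressure(temperature)
    # g/m^3 == mg/l
    return e_s * MOLAR_MASS_WATER / (GAS_CONSTANT * temperature)


def absolute_to_fraction(humidity: float, conditions: GasConditions = CABINET) -> float:
    """Convert absolute humidity (mg water / litre humid gas) to molar fraction.

    x = (h / M_w) / (P / (R T)) with both numerator and denominator per
    litre of humid gas.  Emits :class:`SupersaturationWarning` when the
    input exceeds saturation at the stated conditions (and proceeds).
    """
    if humidity < 0:
        raise DomainError(f"absolute humidity must be >= 0, got {humidity}")
    _warn_if_supersaturated(humidity, conditions)
    n_water = humidity * 1e-3 / MOLAR_MASS_WATER  # mol water per litre
    return n_water / conditions.molar_density


def fraction_to_absolute(x: float, conditions: GasConditions = CABINET) -> float:
    """Convert a water molar fraction to absolute humidity in mg/l.

    Exact algebraic inverse of :func:`absolute_to_fraction` at the same
    conditions.
    """
    _check_fraction(x)
    return x * conditions.molar_density * MOLAR_MASS_WATER * 1e3


def fraction_to_partial_pressure(x: float, conditions: GasConditions = CABINET) -> float:
    """Water partial pressure p_w = x * P, in Pa."""
    _check_fraction(x)
    return x * conditions.pressure


def partial_pressure_to_fraction(p_w: float, conditions: GasConditions = CABINET) -> float:
    """Molar fraction x = p_w / P."""
    if p_w < 0:
        raise DomainError(f"partial pressure must be >= 0, got {p_w}")
    x = p_w / conditions.pressure
    if x >= 1:
        raise DomainError("partial pressure >= total pressure")
    return x


def expansion_factor(x: float) -> float:
    """Relative volume increase of humid gas over its dry-gas content.

    Humidifying an initially dry gas up to water fraction x multiplies
    its volume by 1 + x/(1-x); this function returns x/(1-x).
    """
    _check_fraction(x)
    return x / (1.0 - x)


def volume_to_moles(volume: float, conditions: GasConditions = CABINET) -> float:
    """Moles of ideal gas in ``volume`` litres at the given conditions."""
    if volume < 0:
        raise DomainError(f"volume must be >= 0, got {volume}")
    return volume * conditions.molar_density


def moles_to_volume(n: float, conditions: GasConditions = CABINET) -> float:
    """Volume in litres occupied by ``n`` moles of ideal gas."""
    return n / conditions.molar_density


def _check_fraction(x: float) -> None:
    if not (0.0 <= x < 1.0):
        raise DomainError(f"molar fraction must lie in [0, 1), got {x}")


def _warn_if_supersaturated(humidity: float, conditions: GasConditions) -> None:
    try:
        h_sat = saturated_absolute_humidity(conditions.temperature, conditions.pressure)
    except DomainError:
        return  # outside correlation range: no saturation check possible
    if humidity > h_sat * (1.0 + 1e-9):
        warnings.warn(
            f"absolute humidity {humidity:.3g} mg/l exceeds saturation "
            f"{h_sat:.3g} mg/l at {conditions.temperature:.2f} K",
            SupersaturationWarning,
            stacklevel=3,
        )
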