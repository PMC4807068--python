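"""Humid-air property conversions and the mucosal latent-heat correlation.

The solver state carries the water content of air as a *mass fraction* in
percent: 100 × (vapor mass) / (vapor mass + dry-air mass).  Saturated air at
the nasal tissue state (34 °C, 101.325 kPa) holds 3.34 %MF, which is the
reference against which conditioning performance (RH34) is scored.

Saturation vapor pressure uses the Arden Buck (1981) correlation over liquid
water, accurate to a few hundredths of a percent of pressure between −20 and
+50 °C and adequate up to the boiling point.  The latent heat of vaporization
is a cubic fit (kJ/kg, T in °C) to the Rogers & Yau tabulation; it is exact at
0 °C (2500.79 kJ/kg) and decreases monotonically over physiological range.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "AmbientCondition",
    "AMBIENT_PRESETS",
    "STANDARD_PRESSURE_KPA",
    "SATURATION_MF_34C",
    "saturation_vapor_pressure",
    "rh_to_mass_fraction",
    "mass_fraction_to_rh",
    "rh34",
    "latent_heat",
]

#: Default total pressure (kPa) when a run configuration does not override it.
STANDARD_PRESSURE_KPA = 101.325

#: Ratio of molar masses, water vapor over dry air.
_EPSILON = 18.015268 / 28.9647

#: Saturation mass fraction (%) of air at the tissue state, 34 °C / 100% RH.
#: This is the conditioning reference used by RH34.
SATURATION_MF_34C = 3.34

_TEMP_MIN, _TEMP_MAX = -20.0, 100.0
_LATENT_FIT_RANGE = (0.0, 50.0)


def saturation_vapor_pressure(temperature: float) -> float:
    """Saturation vapor pressure over liquid water, in kPa.

    Arden Buck (1981) fit.  Valid between −20 and 100 °C; outside that range a
    ``ValueError`` is raised rather than extrapolating.
    """
    t = float(temperature)
    if not (_TEMP_MIN <= t <= _TEMP_MAX):
        raise ValueError(
            f"temperature {t} °C outside the correlation range "
            f"[{_TEMP_MIN}, {_TEMP_MAX}] °C"
        )
    return 0.61121 * math.exp((18.678 - t / 234.5) * t / (257.14 + t))


def rh_to_mass_fraction(
    temperature: float,
    relative_humidity: float,
    total_pressure: float = STANDARD_PRESSURE_KPA,
) -> float:
    """Water mass fraction (%) of humid air at (T °C, RH %, P kPa).

    The mass fraction is vapor mass over *total* humid-air mass,

        MF = ε p_v / (ε p_v + P − p_v),   ε = M_w / M_a ≈ 0.622,

    with p_v = RH/100 × p_sat(T).  Raises if RH is outside [0, 100] or the
    vapor pressure reaches the total pressure (saturation overflow).
    """
    rh = float(relative_humidity)
    if not (0.0 <= rh <= 100.0):
        raise ValueError(f"relative humidity {rh} outside [0, 100] %")
    if total_pressure <= 0.0:
        raise ValueError("total pressure must be positive")
    p_v = rh / 100.0 * saturation_vapor_pressure(temperature)
    if p_v >= total_pressure:
        raise ValueError(
            f"vapor pressure {p_v:.3f} kPa reaches total pressure "
            f"{total_pressure:.3f} kPa (saturation overflow)"
        )
    return 100.0 * _EPSILON * p_v / (_EPSILON * p_v + total_pressure - p_v)


def mass_fraction_to_rh(
    mass_fraction: float,
    temperature: float,
    total_pressure: float = STANDARD_PRESSURE_KPA,
) -> float:
    """Relative humidity (%) of air holding ``mass_fraction`` %MF at T, P."""
    mf = float(mass_fraction) / 100.0
    if mf < 0.0:
        raise ValueError("mass fraction must be non-negative")
    # invert MF = eps*pv / (eps*pv + P - pv) for pv
    p_v = mf * total_pressure / (_EPSILON + mf * (1.0 - _EPSILON))
    return 100.0 * p_v / saturation_vapor_pressure(temperature)


def rh34(mass_fraction: float) -> float:
    """Conditioning score: mass fraction as a percentage of 3.34 %MF.

    3.34% is the saturation mass fraction at the 34 °C tissue state, so
    ``rh34(mf)`` measures how close inhaled air has come to full conditioning.
    """
    if mass_fraction < 0.0:
        raise ValueError("mass fraction must be non-negative")
    return 100.0 * mass_fraction / SATURATION_MF_34C


def latent_heat(surface_temperature: float) -> float:
    """Specific latent heat of vaporization L(T) in kJ/kg (T in °C).

    Cubic fit L = 2500.79 − 6.14342e−6 T³ + 1.58927e−3 T² − 2.36418 T.
    Fit range 0–50 °C; outside it the polynomial is still evaluated (solver
    intermediates may transiently leave the range) but a warning is emitted.
    """
    t = float(surface_temperature)
    lo, hi = _LATENT_FIT_RANGE
    if not (lo <= t <= hi):
        warnings.warn(
            f"latent_heat evaluated at {t} °C, outside the fit range "
            f"[{lo}, {hi}] °C (extrapolating)",
            stacklevel=2,
        )
    return 2500.79 - 0.00000614342 * t**3 + 0.00158927 * t**2 - 2.36418 * t


@dataclass(frozen=True)
class AmbientCondition:
    """A labelled inlet air state.

    ``mass_fraction`` (%MF) is derived from (temperature, relative_humidity,
    total_pressure) when not given; when given it is checked against the
    recomputed value to within 0.01 percentage points.
    """

    label: str
    temperature: float  # °C
    relative_humidity: float  # % (0-100)
    total_pressure: float = STANDARD_PRESSURE_KPA  # kPa
    mass_fraction: float = field(default=None)  # % (derived)

    def __post_init__(self) -> None:
        if not (0.0 <= self.relative_humidity <= 100.0):
            raise ValueError("relative_humidity outside [0, 100] %")
        if self.total_pressure <= 0.0:
            raise ValueError("total_pressure must be positive")
        derived = rh_to_mass_fraction(
            self.temperature, self.relative_humidity, self.total_pressure
        )
        if self.mass_fraction is None:
            object.__setattr__(self, "mass_fraction", derived)
        elif abs(self.mass_fraction - derived) > 0.01:
            raise ValueError(
                f"stored mass fraction {self.mass_fraction:.4f}% disagrees with "
                f"derived {derived:.4f}% by more than 0.01 points"
            )

    @property
    def rh34(self) -> float:
        return rh34(self.mass_fraction)


def _preset(label: str, t: float, rh: float) -> AmbientCondition:
    return AmbientCondition(label=label, temperature=t, relative_humidity=rh)


#: The three ambient atmospheric conditions of the simulated experiment
#: matrix: warm-wet 60% RH at 30 °C, cold-dry 10% RH at 5 °C, and hot-dry
#: 5% RH at 40 °C.
AMBIENT_PRESETS: dict[str, AmbientCondition] = {
    "warm_wet": _preset("warm_wet", 30.0, 60.0),
    "cold_dry": _preset("cold_dry", 5.0, 10.0),
    "hot_dry": _preset("hot_dry", 40.0, 5.0),
    # the tissue state; mass fraction pinned to the 3.34% reference so the
    # equilibrium fixed point of the wall model is exact
    "equilibrium": AmbientCondition(
        label="equilibrium",
        temperature=34.0,
        relative_humidity=100.0,
        mass_fraction=SATURATION_MF_34C,
    ),
}
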