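"""Allometric resting-breathing estimates and laminar-regime screening.

Resting tidal volume and respiratory rate scale with body weight as

    TV = 7.69 · BW^1.04   (ml, BW in kg)
    f  = 0.84 · BW^−0.26  (breaths/s)

and the time-averaged inspiratory velocity through the pharyngeal outlet of
cross-sectional area CA is FV = 2 f TV / CA (the factor 2 because inhalation
occupies half the breathing cycle).  The dimensionless screening numbers
(Reynolds, Strouhal, Womersley) justify modelling the flow as steady and
laminar: Re stays well below the 2300 laminar-turbulent transition at resting
rates in all passage presets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "SubjectRespiration",
    "FlowRegime",
    "tidal_volume",
    "respiratory_rate",
    "mean_outlet_velocity",
    "flow_regime",
    "subject_respiration",
    "read_subject_table",
]

#: Laminar-turbulent transition Reynolds number for internal flow.
RE_CRITICAL = 2300.0


def tidal_volume(body_weight: float) -> float:
    """Resting tidal volume in ml from body weight in kg: 7.69·BW^1.04."""
    if body_weight <= 0.0:
        raise ValueError("body weight must be positive")
    return 7.69 * body_weight**1.04


def respiratory_rate(body_weight: float) -> float:
    """Resting respiratory rate in Hz from body weight in kg: 0.84·BW^−0.26."""
    if body_weight <= 0.0:
        raise ValueError("body weight must be positive")
    return 0.84 * body_weight**-0.26


def mean_outlet_velocity(
    tidal_volume_ml: float, respiratory_rate_hz: float, pharyngeal_area_mm2: float
) -> float:
    """Time-averaged inspiratory velocity (m/s) at the pharyngeal outlet.

    FV = 2 f TV / CA with TV converted ml → m³ and CA mm² → m².
    """
    if tidal_volume_ml <= 0.0:
        raise ValueError("tidal volume must be positive")
    if respiratory_rate_hz < 0.0:
        raise ValueError("respiratory rate must be non-negative")
    if pharyngeal_area_mm2 <= 0.0:
        raise ValueError("pharyngeal area must be positive")
    tv_m3 = tidal_volume_ml * 1e-6
    ca_m2 = pharyngeal_area_mm2 * 1e-6
    return 2.0 * respiratory_rate_hz * tv_m3 / ca_m2


@dataclass(frozen=True)
class SubjectRespiration:
    """Derived resting breathing parameters for one subject."""

    body_weight: float  # kg
    pharyngeal_area: float  # mm²
    tidal_volume: float  # ml
    respiratory_rate: float  # Hz
    flow_velocity: float  # m/s


def subject_respiration(body_weight: float, pharyngeal_area: float) -> SubjectRespiration:
    """Derive TV, f, and FV from body weight and pharyngeal area."""
    tv = tidal_volume(body_weight)
    f = respiratory_rate(body_weight)
    return SubjectRespiration(
        body_weight=body_weight,
        pharyngeal_area=pharyngeal_area,
        tidal_volume=tv,
        respiratory_rate=f,
        flow_velocity=mean_outlet_velocity(tv, f, pharyngeal_area),
    )


@dataclass(frozen=True)
class FlowRegime:
    """Dimensionless screening numbers for the steady-laminar assumption."""

    reynolds: float
    strouhal: float
    womersley: float
    laminar: bool


def flow_regime(
    velocity: float,
    characteristic_length: float,
    kinematic_viscosity: float,
    respiratory_rate_hz: float = 0.0,
) -> FlowRegime:
    """Re, Strouhal, and Womersley for a duct flow.

    Re = U·L/ν, St = f·L/U, Wo = (L/2)·sqrt(2π f/ν).  The characteristic
    length defaults in practice to the hydraulic diameter of the pharyngeal
    outlet.  The flow is flagged laminar iff Re < 2300 (boundary exclusive).
    """
    if velocity < 0.0 or characteristic_length <= 0.0 or kinematic_viscosity <= 0.0:
        raise ValueError("velocity must be >= 0; length and viscosity positive")
    if respiratory_rate_hz < 0.0:
        raise ValueError("respiratory rate must be non-negative")
    re = velocity * characteristic_length / kinematic_viscosity
    if velocity == 0.0:
        if respiratory_rate_hz > 0.0:
            raise ValueError("Strouhal number undefined at zero velocity")
        st = 0.0
    else:
        st = respiratory_rate_hz * characteristic_length / velocity
    wo = (characteristic_length / 2.0) * math.sqrt(
        2.0 * math.pi * respiratory_rate_hz / kinematic_viscosity
    )
    return FlowRegime(reynolds=re, strouhal=st, womersley=wo, laminar=re < RE_CRITICAL)


def read_subject_table(path) -> pd.DataFrame:
    """Read a subject CSV (columns body_weight, pharyngeal_area) and derive
    tidal volume, respiratory rate, and outlet velocity per row."""
    df = pd.read_csv(path)
    missing = {"body_weight", "pharyngeal_area"} - set(df.columns)
    if missing:
        raise ValueError(f"subject table missing columns: {sorted(missing)}")
    rows = [
        subject_respiration(bw, ca)
        for bw, ca in zip(df["body_weight"], df["pharyngeal_area"])
    ]
    df = df.copy()
    df["tidal_volume"] = [r.tidal_volume for r in rows]
    df["respiratory_rate"] = [r.respiratory_rate for r in rows]
    df["flow_velocity"] = [r.flow_velocity for r in rows]
    return df
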