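"""Avoided emissions from material and fuel substitution.

Displacement factors (tC avoided per tC wood) decline exponentially from
2020 as the substituted economy decarbonizes, reaching the scenario's
retained fraction exactly in 2050 and continuing at the same rate beyond.
Material credits are booked at product creation, fuel credits at combustion
(including end-of-life energy recovery); the burned carbon itself is always
emitted in full in the same year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

DECARB_START_YEAR = 2020
DECARB_TARGET_YEAR = 2050


@dataclass(frozen=True)
class SubstitutionParams:
    """Displacement factors and decarbonization pace."""

    df_material: float = 1.5
    df_fuel: float = 0.67
    #: fraction of today's displacement factors remaining in 2050
    decarb_2050: float = 0.50

    def __post_init__(self) -> None:
        if self.df_material < 0 or self.df_fuel < 0:
            raise ConfigurationError("displacement factors must be >= 0")
        if not 0.0 < self.decarb_2050 <= 1.0:
            raise ConfigurationError(
                f"decarb_2050 must lie in (0, 1], got {self.decarb_2050}"
            )


@dataclass(frozen=True)
class AvoidedEmissions:
    """Annual avoided-emission series (kgC/m2/yr)."""

    years: np.ndarray = field(repr=False)
    material: np.ndarray = field(repr=False)
    fuel: np.ndarray = field(repr=False)
    end_of_life: np.ndarray = field(repr=False)

    def total(self) -> np.ndarray:
        return self.material + self.fuel + self.end_of_life


def decarb_multiplier(year, decarb_2050: float):
    """Fraction of today's displacement factor left in ``year``.

    1 before 2020, then ``decarb_2050 ** ((year - 2020) / 30)`` — exactly
    the retained fraction in 2050, continuing past 2050 at the same
    exponential rate. Accepts scalars or arrays.
    """
    if not 0.0 < decarb_2050 <= 1.0:
        raise ConfigurationError(
            f"decarb_2050 must lie in (0, 1], got {decarb_2050}"
        )
    year = np.asarray(year, dtype=float)
    span = DECARB_TARGET_YEAR - DECARB_START_YEAR
    exponent = np.maximum(year - DECARB_START_YEAR, 0.0) / span
    out = decarb_2050**exponent
    return float(out) if out.ndim == 0 else out


def material_credit(pool_inflow: float, year: int,
                    params: SubstitutionParams) -> float:
    """Avoided emissions from material substitution, booked at creation."""
    if pool_inflow < 0:
        raise ConfigurationError("pool inflow must be >= 0")
    return params.df_material * decarb_multiplier(year, params.decarb_2050) * pool_inflow


def fuel_credit(burned: float, year: int, params: SubstitutionParams) -> float:
    """Avoided emissions from burning wood instead of the fossil alternative.

    The burned carbon itself is emitted in full in the same year; this
    returns only the displaced fossil emission.
    """
    if burned < 0:
        raise ConfigurationError("burned carbon must be >= 0")
    return params.df_fuel * decarb_multiplier(year, params.decarb_2050) * burned


def avoided_series(
    years: np.ndarray,
    material_inflow: np.ndarray,
    burned: np.ndarray,
    end_of_life_decay: np.ndarray,
    params: SubstitutionParams,
) -> AvoidedEmissions:
    """Vectorized substitution credits over annual series.

    ``burned`` combines firewood and the fuel-wood share of removed stems;
    ``end_of_life_decay`` is product decay, credited as energy recovery.
    """
    years = np.asarray(years)
    m = decarb_multiplier(years, params.decarb_2050)
    return AvoidedEmissions(
        years=years,
        material=params.df_material * m * np.asarray(material_inflow),
        fuel=params.df_fuel * m * np.asarray(burned),
        end_of_life=params.df_fuel * m * np.asarray(end_of_life_decay),
    )
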