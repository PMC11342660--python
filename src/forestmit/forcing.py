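"""Synthetic climate forcing and disturbance-probability schedules.

The climate emulator produces annual mean-temperature anomaly series
(relative to a 1951-1980-style baseline): flat noise before 1980, then a
smooth warming ramp reaching a pathway-specific end-of-century anomaly.
Noise draws are seeded from (site, seed) only — not from the pathway — so
paired scenarios share interannual variability (common random numbers).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

#: Default end-of-century mean anomaly (degC) per pathway.
RCP_END_ANOMALY: dict[str, float] = {
    "RCP2.6": 1.0,
    "RCP4.5": 2.5,
    "RCP8.5": 4.5,
}

DISTURBANCE_RESPONSES = ("constant", "linear", "exponential")

SIM_START_YEAR = 1920
SIM_END_YEAR = 2100
RAMP_START_YEAR = 1980


def stable_seed(*parts: object) -> int:
    """Deterministic 64-bit seed from arbitrary labels (hash() is salted)."""
    key = "|".join(str(p) for p in parts).encode()
    return int.from_bytes(hashlib.blake2b(key, digest_size=8).digest(), "big")


@dataclass(frozen=True)
class ClimateTrajectory:
    """Annual temperature-anomaly series for one site.

    ``dT`` is defined for every simulation year; pre-1980 values average to
    zero within noise.
    """

    site_id: str
    years: np.ndarray = field(repr=False)
    dT: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.years) != len(self.dT):
            raise ConfigurationError("years and dT must have equal length")

    def covers(self, start: int, end: int) -> bool:
        return self.years[0] <= start and self.years[-1] >= end

    def anomaly(self, year: int) -> float:
        idx = int(year - self.years[0])
        if idx < 0 or idx >= len(self.years):
            raise ConfigurationError(f"year {year} outside climate series")
        return float(self.dT[idx])


def generate_climate(
    rcp: str,
    site_id: str = "site0",
    seed: int = 0,
    *,
    start_year: int = SIM_START_YEAR,
    end_year: int = SIM_END_YEAR,
    ramp_start: int = RAMP_START_YEAR,
    end_anomaly: float | None = None,
    ramp_exponent: float = 2.0,
    noise_sd: float = 0.25,
) -> ClimateTrajectory:
    """Generate a synthetic anomaly trajectory for one pathway and site.

    The deterministic part is zero until ``ramp_start`` and then rises as
    ``target * ((year - ramp_start) / (end_year - ramp_start))**ramp_exponent``,
    hitting the pathway's end-of-century anomaly exactly at ``end_year``.
    Gaussian interannual noise (sd ``noise_sd``) is added on top; the noise
    stream depends only on (site, seed), so different pathways at the same
    site share their weather realization.
    """
    if end_anomaly is None:
        try:
            end_anomaly = RCP_END_ANOMALY[rcp]
        except KeyError:
            raise ConfigurationError(
                f"unknown rcp {rcp!r}; expected one of {sorted(RCP_END_ANOMALY)}"
            ) from None
    years = np.arange(start_year, end_year + 1)
    frac = np.clip((years - ramp_start) / (end_year - ramp_start), 0.0, None)
    ramp = end_anomaly * frac**ramp_exponent
    rng = np.random.default_rng(stable_seed("climate", site_id, seed))
    noise = rng.normal(0.0, noise_sd, size=len(years)) if noise_sd > 0 else 0.0
    return ClimateTrajectory(site_id=site_id, years=years, dT=ramp + noise)


def disturbance_probability(
    p0: float,
    dT: float,
    response: str,
    *,
    linear_slope: float = 1.0,
    doubling_dT: float = 1.0,
) -> float:
    """Annual stand-replacing disturbance probability under warming.

    ``constant`` returns the baseline ``p0``. ``linear`` scales it by
    ``1 + linear_slope * max(dT, 0)``; ``exponential`` by
    ``2**(max(dT, 0) / doubling_dT)``. Negative anomalies never reduce the
    probability below baseline, and the result is clamped to [0, 1].
    """
    if not (0.0 < p0 < 1.0):
        raise ConfigurationError(f"p0 must lie in (0, 1), got {p0}")
    if not np.isfinite(dT):
        raise ConfigurationError(f"dT must be finite, got {dT}")
    warm = max(float(dT), 0.0)
    if response == "constant":
        p = p0
    elif response == "linear":
        p = p0 * (1.0 + linear_slope * warm)
    elif response == "exponential":
        p = p0 * 2.0 ** (warm / doubling_dT)
    else:
        raise ConfigurationError(
            f"unknown disturbance response {response!r}; "
            f"expected one of {DISTURBANCE_RESPONSES}"
        )
    return min(max(p, 0.0), 1.0)


@dataclass(frozen=True)
class DisturbanceSchedule:
    """Annual disturbance-probability series derived from a climate series."""

    p0: float
    response: str
    p: np.ndarray = field(repr=False)

    @classmethod
    def from_climate(
        cls,
        p0: float,
        climate: ClimateTrajectory,
        response: str,
        *,
        linear_slope: float = 1.0,
        doubling_dT: float = 1.0,
    ) -> "DisturbanceSchedule":
        p = np.array(
            [
                disturbance_probability(
                    p0,
                    dT,
                    response,
                    linear_slope=linear_slope,
                    doubling_dT=doubling_dT,
                )
                for dT in climate.dT
            ]
        )
        return cls(p0=p0, response=response, p=p)
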