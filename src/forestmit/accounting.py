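"""Headline mitigation metrics derived from annual trajectories.

The combined carbon sink is the change since end-of-2020 in the summed
carbon of vegetation, deadwood, soil, and wood products; the total
mitigation potential adds the cumulative avoided emissions from
substitution over 2021 up to the horizon.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import InputError

BASELINE_YEAR = 2020
HORIZONS = (2050, 2100)

#: Stock columns summed into the combined sink.
STOCK_COLUMNS = (
    "veg_c",
    "deadwood_c",
    "soil_c",
    "product_short_c",
    "product_medium_c",
    "product_long_c",
)

#: Avoided-emission flux columns summed into the substitution term.
AVOIDED_COLUMNS = ("avoided_material", "avoided_fuel", "avoided_eol")


@dataclass(frozen=True)
class MitigationResult:
    scenario_id: str
    horizon: int
    combined_sink: float
    cumulative_avoided: float

    @property
    def total_mitigation(self) -> float:
        return self.combined_sink + self.cumulative_avoided


def _stock_at(trajectory: pd.DataFrame, year: int) -> float:
    rows = trajectory.loc[trajectory["year"] == year]
    if rows.empty:
        raise InputError(f"trajectory does not cover year {year}")
    cols = [c for c in STOCK_COLUMNS if c in trajectory.columns]
    if not cols:
        raise InputError("trajectory has no carbon stock columns")
    return float(rows[list(cols)].iloc[0].sum())


def combined_sink(
    trajectory: pd.DataFrame,
    horizon: int,
    baseline_year: int = BASELINE_YEAR,
) -> float:
    """Change in total stored carbon between the baseline year and horizon.

    Positive values denote net uptake. The trajectory must contain annual
    rows with a ``year`` column and the stock columns (patch- and
    site-averaged, kgC/m2).
    """
    return _stock_at(trajectory, horizon) - _stock_at(trajectory, baseline_year)


def cumulative_avoided(
    trajectory: pd.DataFrame,
    horizon: int,
    baseline_year: int = BASELINE_YEAR,
) -> float:
    """Summed substitution credits over ``baseline_year+1 .. horizon``."""
    mask = (trajectory["year"] > baseline_year) & (trajectory["year"] <= horizon)
    window = trajectory.loc[mask]
    if window["year"].nunique() != horizon - baseline_year:
        raise InputError(
            f"trajectory does not cover {baseline_year + 1}..{horizon}"
        )
    cols = [c for c in AVOIDED_COLUMNS if c in trajectory.columns]
    return float(window[cols].to_numpy().sum())


def total_mitigation(
    trajectory: pd.DataFrame,
    horizon: int,
    scenario_id: str = "",
    baseline_year: int = BASELINE_YEAR,
) -> MitigationResult:
    """Combined sink plus cumulative avoided emissions at one horizon."""
    return MitigationResult(
        scenario_id=scenario_id,
        horizon=horizon,
        combined_sink=combined_sink(trajectory, horizon, baseline_year),
        cumulative_avoided=cumulative_avoided(trajectory, horizon, baseline_year),
    )
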