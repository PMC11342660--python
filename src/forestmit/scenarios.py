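"""Factorial scenario design.

Nine management / environment factors span the full experiment. Enumerating
their cross product yields the scenario ensemble; each scenario carries a
reproducible ``seed_base`` derived from its position in the enumeration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, fields
from typing import Any, Mapping, Sequence

from .errors import ConfigurationError

#: Canonical factor order; enumeration is lexicographic in this order.
FACTOR_ORDER: tuple[str, ...] = (
    "rcp",
    "disturbance_response",
    "forest_age",
    "forest_type",
    "harvest_intensity",
    "salvage",
    "material_usage",
    "cascade",
    "decarb_2050",
)

#: Default factor levels (3*3*2*2*4*2*2*2*3 = 3456 combinations).
DEFAULT_FACTOR_LEVELS: dict[str, tuple[Any, ...]] = {
    "rcp": ("RCP2.6", "RCP4.5", "RCP8.5"),
    "disturbance_response": ("constant", "linear", "exponential"),
    "forest_age": ("mature", "young"),
    "forest_type": ("BD", "NE"),
    "harvest_intensity": (0.0, 0.5, 1.0, 1.5),
    "salvage": (True, False),
    "material_usage": (1.0, 1.5),
    "cascade": (1.0, 1.5),
    "decarb_2050": (0.25, 0.50, 0.75),
}

#: Planting windows (inclusive year ranges) for the two age classes.
PLANTING_WINDOWS: dict[str, tuple[int, int]] = {
    "mature": (1921, 1940),
    "young": (1981, 2000),
}


@dataclass(frozen=True)
class ScenarioConfig:
    """One point in the 9-factor design space.

    Attributes
    ----------
    rcp:
        Climate pathway label (``RCP2.6`` / ``RCP4.5`` / ``RCP8.5``).
    disturbance_response:
        How annual stand-replacing disturbance probability responds to the
        temperature anomaly (``constant`` / ``linear`` / ``exponential``).
    forest_age:
        ``mature`` (planted 1921-1940) or ``young`` (planted 1981-2000).
    forest_type:
        ``BD`` broad-leaved deciduous or ``NE`` needle-leaved evergreen.
    harvest_intensity:
        Multiplier on the baseline per-event harvest fraction, applied
        directly after 2020 (0.0, 0.5, 1.0 or 1.5).
    salvage:
        Whether killed trees are salvage-logged after disturbances post 2020.
    material_usage:
        1.0 keeps current product allocation; 1.5 ramps long/medium-lived
        product shares up by 50% over 2020-2050.
    cascade:
        1.0 keeps product lifetimes; 1.5 extends the decay median of
        products created after 2020 by 50%.
    decarb_2050:
        Fraction of today's displacement factors remaining in 2050.
    seed_base:
        Reproducible integer derived from the enumeration index.
    """

    rcp: str
    disturbance_response: str
    forest_age: str
    forest_type: str
    harvest_intensity: float
    salvage: bool
    material_usage: float
    cascade: float
    decarb_2050: float
    seed_base: int = 0

    @property
    def scenario_id(self) -> str:
        return f"s{self.seed_base:04d}"

    def factor_values(self) -> dict[str, Any]:
        """Factor name -> level mapping (excludes ``seed_base``)."""
        return {name: getattr(self, name) for name in FACTOR_ORDER}


_FACTOR_FIELDS = {f.name for f in fields(ScenarioConfig)} - {"seed_base"}


def enumerate_scenarios(
    factor_levels: Mapping[str, Sequence[Any]] | None = None,
) -> list[ScenarioConfig]:
    """Enumerate the full factorial cross product of factor levels.

    Factors iterate in :data:`FACTOR_ORDER`, levels in listed order, so the
    result is deterministic and lexicographic. Factors omitted from
    ``factor_levels`` fall back to their defaults.

    Raises
    ------
    ConfigurationError
        On unknown factor names, empty level lists, or duplicate levels.
    """
    levels = dict(DEFAULT_FACTOR_LEVELS)
    if factor_levels is not None:
        for name, values in factor_levels.items():
            if name not in _FACTOR_FIELDS:
                raise ConfigurationError(f"unknown factor {name!r}")
            levels[name] = tuple(values)

    for name in FACTOR_ORDER:
        vals = levels[name]
        if len(vals) == 0:
            raise ConfigurationError(f"factor {name!r} has no levels")
        if len(set(vals)) != len(vals):
            raise ConfigurationError(f"duplicate level within factor {name!r}: {vals}")
        for v in vals:
            if v not in DEFAULT_FACTOR_LEVELS[name]:
                raise ConfigurationError(
                    f"level {v!r} not in the enumerated set for factor {name!r}"
                )

    scenarios = []
    for i, combo in enumerate(
        itertools.product(*(levels[name] for name in FACTOR_ORDER))
    ):
        kwargs = dict(zip(FACTOR_ORDER, combo))
        scenarios.append(ScenarioConfig(seed_base=i, **kwargs))
    return scenarios
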