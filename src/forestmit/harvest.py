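"""Partitioning of cut and salvaged tree carbon.

Every operation books the processed carbon into exactly three destinations —
removed stem wood (enters the product chain), firewood (burned in the event
year), and on-site residue (enters the deadwood pool) — and the three always
sum to the input carbon.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .errors import ConfigurationError


@dataclass(frozen=True)
class HarvestParams:
    """Fixed partition fractions for cutting and salvage operations."""

    stem_fraction: float = 0.65          # share of woody biomass that is stem
    harvest_efficiency: float = 0.90     # stem share removed in a fresh cut
    salvage_efficiency: float = 0.75     # stem share removed when salvaging
    branch_fraction: float = 0.13        # share of woody biomass in branches
    branch_removed_burned: float = 0.40  # branch share removed and burned
    salvage_trees_left: float = 0.20     # killed trees left on site
    firewood_age_threshold: int = 20     # younger cohorts go fully to firewood

    def __post_init__(self) -> None:
        for name in (
            "stem_fraction",
            "harvest_efficiency",
            "salvage_efficiency",
            "branch_fraction",
            "branch_removed_burned",
            "salvage_trees_left",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if self.stem_fraction + self.branch_fraction > 1.0:
            raise ConfigurationError("stem_fraction + branch_fraction exceeds 1")


@dataclass
class HarvestEvent:
    """Carbon partition of one cutting or salvage operation (kgC/m2)."""

    year: int
    removed_stem: float
    firewood: float
    residue: float
    source: str  # "fresh" or "salvage"

    @property
    def total(self) -> float:
        return self.removed_stem + self.firewood + self.residue

    def __post_init__(self) -> None:
        if min(self.removed_stem, self.firewood, self.residue) < 0:
            raise ConfigurationError("harvest event components must be >= 0")


def partition_fresh(
    cut_biomass_by_cohort_age: Mapping[int, float],
    params: HarvestParams = HarvestParams(),
    *,
    year: int = 0,
) -> HarvestEvent:
    """Partition freshly cut carbon, keyed by cohort age.

    Cohorts at or above the firewood age threshold split into removed stem
    (stem fraction x harvest efficiency), burned branches, and residue (the
    unremoved stem share, unburned branches, and the root/other remainder).
    Younger cohorts are used entirely as firewood.
    """
    removed = firewood = residue = 0.0
    stem, eff = params.stem_fraction, params.harvest_efficiency
    branch, burn = params.branch_fraction, params.branch_removed_burned
    rest = 1.0 - stem - branch
    for age, biomass in cut_biomass_by_cohort_age.items():
        if biomass < 0:
            raise ConfigurationError(f"negative cut biomass for age {age}")
        if age < params.firewood_age_threshold:
            firewood += biomass
        else:
            removed += biomass * stem * eff
            firewood += biomass * branch * burn
            residue += biomass * (stem * (1 - eff) + branch * (1 - burn) + rest)
    return HarvestEvent(
        year=year, removed_stem=removed, firewood=firewood, residue=residue,
        source="fresh",
    )


def partition_salvage(
    killed_biomass_by_cohort_age: Mapping[int, float],
    params: HarvestParams = HarvestParams(),
    *,
    year: int = 0,
) -> HarvestEvent:
    """Partition disturbance-killed carbon under salvage logging.

    A fixed share of killed trees is left on site (residue); the processed
    remainder follows the fresh-cut rules but with the lower salvage stem
    efficiency. Salvaged wood follows the same downstream usage patterns as
    fresh wood.
    """
    removed = firewood = residue = 0.0
    processed_share = 1.0 - params.salvage_trees_left
    stem, eff = params.stem_fraction, params.salvage_efficiency
    branch, burn = params.branch_fraction, params.branch_removed_burned
    rest = 1.0 - stem - branch
    for age, biomass in killed_biomass_by_cohort_age.items():
        if biomass < 0:
            raise ConfigurationError(f"negative killed biomass for age {age}")
        residue += biomass * params.salvage_trees_left
        proc = biomass * processed_share
        if age < params.firewood_age_threshold:
            firewood += proc
        else:
            removed += proc * stem * eff
            firewood += proc * branch * burn
            residue += proc * (stem * (1 - eff) + branch * (1 - burn) + rest)
    return HarvestEvent(
        year=year, removed_stem=removed, firewood=firewood, residue=residue,
        source="salvage",
    )
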