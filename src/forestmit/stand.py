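"""Reduced-form, patch-replicated stand dynamics.

Each patch carries a list of age cohorts plus deadwood and soil pools on an
annual timestep. Stand growth is logistic in total vegetation carbon with a
quadratic climate modifier; stochastic stand-replacing disturbances kill all
established cohorts of a patch; partial harvests remove a fixed fraction of
every cohort on a staggered per-patch schedule. Dead pools decay with a Q10
temperature response, routing part of deadwood decay into the soil pool.

Per year and patch the sequencing is: growth -> background mortality ->
disturbance draw (with optional salvage) -> scheduled harvest -> dead-pool
decay. The annual carbon balance closes exactly:

    d(veg + deadwood + soil) = npp - removed_stem - firewood
                               - deadwood_respiration - soil_respiration
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError
from .forcing import ClimateTrajectory, DisturbanceSchedule, stable_seed
from .harvest import HarvestEvent, HarvestParams, partition_fresh, partition_salvage
from .scenarios import PLANTING_WINDOWS, ScenarioConfig

#: First year in which the scenario factor levels take effect.
SCENARIO_SWITCH_YEAR = 2020


@dataclass(frozen=True)
class StandParams:
    """Calibration constants of the stand emulator.

    Growth follows ``npp = npp_max * max(0, 1 - B/K) * max(0, 1 + a*dT - b*dT^2)``
    with ``B`` the patch vegetation carbon and ``K`` the carrying capacity;
    all rates are annual and all carbon densities are kgC/m2.
    """

    n_patches: int = 100
    npp_max: float = 0.714
    # calibrated so partial-harvest vegetation deficits persist on the
    # multi-decade timescale of wood-product decay (see notes on the
    # harvest-intensity sign structure); the density feedback is npp_max/K
    carrying_capacity: float = 60.0
    background_mortality: float = 0.01
    harvest_fraction: float = 0.24
    harvest_interval_ne: int = 20
    harvest_interval_bd: int = 25
    disturbance_interval_ne: int = 300
    disturbance_interval_bd: int = 1000
    climate_growth_a: float = 0.05
    climate_growth_b: float = 0.01
    deadwood_k: float = 0.04
    humification: float = 0.3
    soil_k: float = 0.01
    q10: float = 2.0
    #: growth-allocation weight (kgC/m2 equivalent) of a zero-biomass cohort,
    #: so regeneration cohorts can capture a share of stand growth
    seedling_weight: float = 0.1
    linear_slope: float = 1.0
    doubling_dT: float = 1.0

    def __post_init__(self) -> None:
        for name in ("background_mortality", "harvest_fraction", "deadwood_k",
                     "humification", "soil_k"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        for name in ("harvest_interval_ne", "harvest_interval_bd",
                     "disturbance_interval_ne", "disturbance_interval_bd"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ConfigurationError(f"{name} must be a positive integer")

    def harvest_interval(self, forest_type: str) -> int:
        if forest_type == "NE":
            return self.harvest_interval_ne
        if forest_type == "BD":
            return self.harvest_interval_bd
        raise ConfigurationError(f"unknown forest type {forest_type!r}")

    def disturbance_p0(self, forest_type: str) -> float:
        if forest_type == "NE":
            return 1.0 / self.disturbance_interval_ne
        if forest_type == "BD":
            return 1.0 / self.disturbance_interval_bd
        raise ConfigurationError(f"unknown forest type {forest_type!r}")


@dataclass
class Cohort:
    """One age class on a patch (biomass in kgC/m2, patch-area basis)."""

    establishment_year: int
    biomass: float = 0.0


@dataclass
class PatchState:
    """One stochastic replicate of stand dynamics."""

    cohorts: list[Cohort] = field(default_factory=list)
    deadwood: float = 0.0
    soil: float = 0.0
    harvest_phase: int = 0

    def vegetation(self, year: int | None = None) -> float:
        """Total established vegetation carbon (cohorts planted by ``year``)."""
        if year is None:
            return sum(c.biomass for c in self.cohorts)
        return sum(
            c.biomass for c in self.cohorts if c.establishment_year <= year
        )


@dataclass
class StandState:
    """All patches of one simulated stand."""

    patches: list[PatchState]
    forest_type: str
    forest_age: str


@dataclass
class DisturbanceKill:
    """Outcome of one stand-replacing disturbance on a patch."""

    year: int
    killed_by_age: dict[int, float]

    @property
    def total(self) -> float:
        return sum(self.killed_by_age.values())


def initialize_stand(
    scenario: ScenarioConfig,
    params: StandParams,
    seed: int = 0,
) -> StandState:
    """Create the founding patch states for one scenario.

    Each patch receives one zero-biomass founding cohort per planting year of
    the age class's window; cohorts only participate in dynamics once the
    simulation reaches their establishment year. Harvest phases are drawn
    uniformly in [0, interval) from ``seed`` so cuttings are staggered across
    patches; the draw does not depend on any scenario factor beyond forest
    type (whose interval differs), preserving common random numbers.
    """
    try:
        first, last = PLANTING_WINDOWS[scenario.forest_age]
    except KeyError:
        raise ConfigurationError(
            f"unknown forest age {scenario.forest_age!r}"
        ) from None
    interval = params.harvest_interval(scenario.forest_type)
    rng = np.random.default_rng(stable_seed("phases", seed))
    phases = rng.integers(0, interval, size=params.n_patches)
    patches = [
        PatchState(
            cohorts=[Cohort(establishment_year=y) for y in range(first, last + 1)],
            harvest_phase=int(phases[i]),
        )
        for i in range(params.n_patches)
    ]
    return StandState(
        patches=patches,
        forest_type=scenario.forest_type,
        forest_age=scenario.forest_age,
    )


def annual_growth(
    patch: PatchState,
    dT: float,
    params: StandParams,
    year: int,
) -> tuple[float, float]:
    """Apply one year of growth and background mortality to a patch.

    Returns ``(npp, mortality_to_deadwood)`` in kgC/m2. Stand-level NPP is
    shared among established cohorts proportional to biomass, with
    zero-biomass cohorts weighted at ``seedling_weight`` so regeneration can
    establish (when every cohort has zero biomass this reduces to an equal
    split). Background mortality moves a fixed fraction of each cohort to
    deadwood.
    """
    live = [c for c in patch.cohorts if c.establishment_year <= year]
    if not live:
        return 0.0, 0.0
    B = sum(c.biomass for c in live)
    density = max(0.0, 1.0 - B / params.carrying_capacity)
    modifier = max(
        0.0, 1.0 + params.climate_growth_a * dT - params.climate_growth_b * dT**2
    )
    npp = params.npp_max * density * modifier
    weights = [c.biomass if c.biomass > 0 else params.seedling_weight for c in live]
    wsum = sum(weights)
    if wsum > 0 and npp > 0:
        for c, w in zip(live, weights):
            c.biomass += npp * w / wsum
    else:
        npp = 0.0
    mortality = 0.0
    m = params.background_mortality
    for c in live:
        dead = m * c.biomass
        c.biomass -= dead
        mortality += dead
    patch.deadwood += mortality
    return npp, mortality


def disturbance_step(
    patch: PatchState,
    u: float,
    p: float,
    year: int,
) -> DisturbanceKill | None:
    """Apply the annual stand-replacing disturbance draw to a patch.

    An event fires iff ``u < p`` and kills every established cohort; cohorts
    whose establishment year lies in the future (unplanted) are untouched.
    The caller routes the killed biomass (salvage or deadwood) and schedules
    regeneration. Returns ``None`` when no event fires.
    """
    if not 0.0 <= p <= 1.0:
        raise ConfigurationError(f"disturbance probability {p} outside [0, 1]")
    if not 0.0 <= u < 1.0:
        raise ConfigurationError(f"uniform draw {u} outside [0, 1)")
    if u >= p:
        return None
    killed: dict[int, float] = {}
    survivors = []
    for c in patch.cohorts:
        if c.establishment_year > year:
            survivors.append(c)
        else:
            age = year - c.establishment_year
            killed[age] = killed.get(age, 0.0) + c.biomass
    patch.cohorts = survivors
    return DisturbanceKill(year=year, killed_by_age=killed)


def scheduled_harvest(
    patch: PatchState,
    year: int,
    scenario: ScenarioConfig,
    params: StandParams,
    harvest_params: HarvestParams,
) -> HarvestEvent | None:
    """Run the periodic partial harvest if this is the patch's cutting year.

    The event fires iff ``(year - harvest_phase) mod interval == 0`` and the
    effective per-cohort removal fraction is positive. The fraction is the
    baseline harvest fraction times the scenario's intensity multiplier,
    which switches from 1.0 to the scenario value directly after 2020.
    Removed carbon is partitioned via the fresh-cut rules (cohorts younger
    than the firewood threshold go entirely to firewood). Returns ``None``
    when nothing fires or nothing is cut.
    """
    interval = params.harvest_interval(scenario.forest_type)
    if (year - patch.harvest_phase) % interval != 0:
        return None
    multiplier = 1.0 if year <= SCENARIO_SWITCH_YEAR else scenario.harvest_intensity
    f = params.harvest_fraction * multiplier
    if f <= 0.0:
        return None
    cut_by_age: dict[int, float] = {}
    for c in patch.cohorts:
        if c.establishment_year > year or c.biomass <= 0:
            continue
        cut = f * c.biomass
        c.biomass -= cut
        age = year - c.establishment_year
        cut_by_age[age] = cut_by_age.get(age, 0.0) + cut
    if not cut_by_age or sum(cut_by_age.values()) <= 0.0:
        return None
    event = partition_fresh(cut_by_age, harvest_params, year=year)
    patch.deadwood += event.residue
    return event


def decay_dead_pools(
    patch: PatchState,
    dT: float,
    params: StandParams,
) -> tuple[float, float, float]:
    """Decay the deadwood and soil pools for one year.

    Returns ``(deadwood_respiration, humified_to_soil, soil_respiration)``.
    Both pools decay at their base rate scaled by ``q10**(dT/10)`` (clamped
    to at most 1); the humification share of deadwood decay enters the soil
    pool instead of the atmosphere.
    """
    scale = params.q10 ** (dT / 10.0)
    dw_rate = min(1.0, params.deadwood_k * scale)
    loss = patch.deadwood * dw_rate
    to_soil = params.humification * loss
    dw_resp = loss - to_soil
    patch.deadwood -= loss
    patch.soil += to_soil
    soil_rate = min(1.0, params.soil_k * scale)
    soil_resp = patch.soil * soil_rate
    patch.soil -= soil_resp
    return dw_resp, to_soil, soil_resp


@dataclass(frozen=True)
class AnnualAccounts:
    """Stand-side carbon fluxes of one year (patch means, kgC/m2/yr)."""

    npp: float
    mortality_to_deadwood: float
    disturbance_kill: float
    removed_stem: float
    firewood: float
    residue_to_deadwood: float
    deadwood_respiration: float
    soil_respiration: float


#: Per-year output columns of :func:`simulate` (patch means, kgC/m2 or /yr).
_FLUX_NAMES = (
    "npp",
    "mortality_to_deadwood",
    "disturbance_kill",
    "removed_stem",
    "firewood",
    "residue_to_deadwood",
    "deadwood_respiration",
    "soil_respiration",
)


@dataclass
class StandSimOutput:
    """Patch-mean annual series of one stand simulation."""

    years: np.ndarray
    veg: np.ndarray
    deadwood: np.ndarray
    soil: np.ndarray
    fluxes: dict[str, np.ndarray]
    event_count: np.ndarray  # disturbance events per year, summed over patches

    def accounts(self, year: int) -> AnnualAccounts:
        t = int(year - self.years[0])
        if t < 0 or t >= len(self.years):
            raise InputError(f"year {year} outside simulated span")
        return AnnualAccounts(
            **{name: float(self.fluxes[name][t]) for name in _FLUX_NAMES}
        )

    def to_frame(self) -> pd.DataFrame:
        data = {
            "year": self.years,
            "veg_c": self.veg,
            "deadwood_c": self.deadwood,
            "soil_c": self.soil,
        }
        data.update(self.fluxes)
        data["disturbance_events"] = self.event_count
        return pd.DataFrame(data)

    def closure_residual(self) -> np.ndarray:
        """Annual stand-side carbon-balance residual (should be ~0).

        ``d(veg+deadwood+soil) - (npp - removed_stem - firewood
        - deadwood_respiration - soil_respiration)`` for every year after
        the first.
        """
        total = self.veg + self.deadwood + self.soil
        dstock = np.diff(total)
        f = self.fluxes
        net = (
            f["npp"]
            - f["removed_stem"]
            - f["firewood"]
            - f["deadwood_respiration"]
            - f["soil_respiration"]
        )[1:]
        return dstock - net


def simulate(
    scenario: ScenarioConfig,
    climate: ClimateTrajectory,
    params: StandParams = StandParams(),
    harvest_params: HarvestParams = HarvestParams(),
    *,
    seed: int = 0,
    start_year: int = 1920,
    end_year: int = 2100,
) -> StandSimOutput:
    """Simulate one stand over ``start_year..end_year``.

    The annual uniform disturbance draws are seeded from ``seed`` and the
    patch index only — independent of scenario factors — so scenarios that
    differ only in disturbance response share draws and the lower-probability
    schedule's event set is a subset of the higher one's.
    """
    if not climate.covers(start_year, end_year):
        raise InputError(
            f"climate series {climate.years[0]}-{climate.years[-1]} does not "
            f"cover simulation years {start_year}-{end_year}"
        )
    years = np.arange(start_year, end_year + 1)
    n_years = len(years)
    p0 = params.disturbance_p0(scenario.forest_type)
    offset = int(start_year - climate.years[0])
    dT_series = np.asarray(climate.dT[offset : offset + n_years], dtype=float)
    schedule = DisturbanceSchedule.from_climate(
        p0,
        ClimateTrajectory(site_id=climate.site_id, years=years, dT=dT_series),
        scenario.disturbance_response,
        linear_slope=params.linear_slope,
        doubling_dT=params.doubling_dT,
    )
    state = initialize_stand(scenario, params, seed)
    rng = np.random.default_rng(stable_seed("disturbance", climate.site_id, seed))
    u_draws = rng.random((params.n_patches, n_years))

    veg = np.zeros(n_years)
    deadwood = np.zeros(n_years)
    soil = np.zeros(n_years)
    fluxes = {name: np.zeros(n_years) for name in _FLUX_NAMES}
    event_count = np.zeros(n_years, dtype=int)
    n = params.n_patches
    salvage_on = scenario.salvage

    for t, year in enumerate(years):
        dT = dT_series[t]
        p = float(schedule.p[t])
        for i, patch in enumerate(state.patches):
            npp, mort = annual_growth(patch, dT, params, year)
            fluxes["npp"][t] += npp
            fluxes["mortality_to_deadwood"][t] += mort

            kill = disturbance_step(patch, float(u_draws[i, t]), p, year)
            if kill is not None:
                event_count[t] += 1
                if kill.total > 0:
                    fluxes["disturbance_kill"][t] += kill.total
                    if salvage_on and year > SCENARIO_SWITCH_YEAR:
                        ev = partition_salvage(
                            kill.killed_by_age, harvest_params, year=year
                        )
                        patch.deadwood += ev.residue
                        fluxes["removed_stem"][t] += ev.removed_stem
                        fluxes["firewood"][t] += ev.firewood
                        fluxes["residue_to_deadwood"][t] += ev.residue
                    else:
                        patch.deadwood += kill.total
                        fluxes["residue_to_deadwood"][t] += kill.total
                # regeneration establishes the following year
                patch.cohorts.append(Cohort(establishment_year=year + 1))
            else:
                ev = scheduled_harvest(patch, year, scenario, params, harvest_params)
                if ev is not None:
                    fluxes["removed_stem"][t] += ev.removed_stem
                    fluxes["firewood"][t] += ev.firewood
                    fluxes["residue_to_deadwood"][t] += ev.residue
                    patch.cohorts.append(Cohort(establishment_year=year + 1))

            dw_resp, _, soil_resp = decay_dead_pools(patch, dT, params)
            fluxes["deadwood_respiration"][t] += dw_resp
            fluxes["soil_respiration"][t] += soil_resp

            veg[t] += patch.vegetation(year)
            deadwood[t] += patch.deadwood
            soil[t] += patch.soil

    veg /= n
    deadwood /= n
    soil /= n
    for name in _FLUX_NAMES:
        fluxes[name] /= n
    return StandSimOutput(
        years=years,
        veg=veg,
        deadwood=deadwood,
        soil=soil,
        fluxes=fluxes,
        event_count=event_count,
    )
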