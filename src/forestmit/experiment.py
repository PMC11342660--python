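"""Full-factorial experiment driver and pairwise-difference attribution.

The scenario pipeline is staged so runs that share upstream factor levels
share computations (and, by the common-random-numbers seed policy, share
stochastic draws): the climate depends only on the pathway, the stand
trajectory only on the six stand-side factors, the product chain adds the
usage and cascade factors, and substitution finally adds the
decarbonization pace. ``run_experiment`` memoizes each stage, which makes
the 3456-scenario factorial tractable while every scenario's outputs are
bit-identical to an uncached run.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import accounting, products, stand, substitution
from .errors import ConfigurationError, InputError
from .forcing import ClimateTrajectory, generate_climate
from .harvest import HarvestParams
from .scenarios import (
    FACTOR_ORDER,
    ScenarioConfig,
    enumerate_scenarios,
)

logger = logging.getLogger("forestmit")

#: Factor columns in results tables, in design order.
FACTOR_COLUMNS = list(FACTOR_ORDER)

METRICS = ("combined_sink", "total_mitigation")


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to run one (possibly reduced) factorial ensemble."""

    factor_levels: Mapping[str, Sequence[Any]] | None = None
    sites: tuple[str, ...] = ("site0",)
    seed: int = 0
    stand_params: stand.StandParams = field(default_factory=stand.StandParams)
    harvest_params: HarvestParams = field(default_factory=HarvestParams)
    df_material: float = 1.5
    df_fuel: float = 0.67
    gamma_shape: float = products.DEFAULT_GAMMA_SHAPE
    noise_sd: float = 0.25
    horizons: tuple[int, ...] = accounting.HORIZONS
    start_year: int = 1920
    end_year: int = 2100

    def scenarios(self) -> list[ScenarioConfig]:
        return enumerate_scenarios(self.factor_levels)


def load_config(path: str) -> ExperimentConfig:
    """Read an experiment configuration from a flat YAML file.

    Recognized top-level keys: ``factors`` (factor -> level list),
    ``sites``, ``seed``, ``n_patches``, ``noise_sd``, ``gamma_shape``,
    ``df_material``, ``df_fuel``, ``horizons``, plus ``stand`` and
    ``harvest`` mappings overriding individual parameter fields.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return config_from_dict(raw)


def config_from_dict(raw: Mapping[str, Any]) -> ExperimentConfig:
    known = {
        "factors", "sites", "seed", "n_patches", "noise_sd", "gamma_shape",
        "df_material", "df_fuel", "horizons", "stand", "harvest",
    }
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    stand_params = stand.StandParams(**raw.get("stand", {}))
    if "n_patches" in raw:
        stand_params = replace(stand_params, n_patches=int(raw["n_patches"]))
    kwargs: dict[str, Any] = {
        "factor_levels": raw.get("factors"),
        "stand_params": stand_params,
        "harvest_params": HarvestParams(**raw.get("harvest", {})),
    }
    if "sites" in raw:
        kwargs["sites"] = tuple(raw["sites"])
    for key in ("seed", "noise_sd", "gamma_shape", "df_material", "df_fuel"):
        if key in raw:
            kwargs[key] = raw[key]
    if "horizons" in raw:
        kwargs["horizons"] = tuple(int(h) for h in raw["horizons"])
    return ExperimentConfig(**kwargs)


# ---------------------------------------------------------------------------
# Staged scenario pipeline with memoization.

def _stand_key(scenario: ScenarioConfig, site: str) -> tuple:
    return (
        site, scenario.rcp, scenario.disturbance_response, scenario.forest_age,
        scenario.forest_type, scenario.harvest_intensity, scenario.salvage,
    )


def _get_climate(cfg: ExperimentConfig, rcp: str, site: str,
                 caches: dict) -> ClimateTrajectory:
    key = (rcp, site)
    if key not in caches["climate"]:
        caches["climate"][key] = generate_climate(
            rcp, site_id=site, seed=cfg.seed,
            start_year=cfg.start_year, end_year=cfg.end_year,
            noise_sd=cfg.noise_sd,
        )
    return caches["climate"][key]


def _get_stand(cfg: ExperimentConfig, scenario: ScenarioConfig, site: str,
               caches: dict) -> stand.StandSimOutput:
    key = _stand_key(scenario, site)
    if key not in caches["stand"]:
        climate = _get_climate(cfg, scenario.rcp, site, caches)
        caches["stand"][key] = stand.simulate(
            scenario, climate, cfg.stand_params, cfg.harvest_params,
            seed=cfg.seed, start_year=cfg.start_year, end_year=cfg.end_year,
        )
    return caches["stand"][key]


def _get_products(cfg: ExperimentConfig, scenario: ScenarioConfig, site: str,
                  caches: dict) -> products.ProductSeries:
    key = _stand_key(scenario, site) + (scenario.material_usage, scenario.cascade)
    if key not in caches["products"]:
        out = _get_stand(cfg, scenario, site, caches)
        caches["products"][key] = products.build_product_series(
            out.years, out.fluxes["removed_stem"], scenario.forest_type,
            material_scenario=scenario.material_usage,
            cascade_factor=scenario.cascade,
            shape=cfg.gamma_shape,
        )
    return caches["products"][key]


def new_caches() -> dict:
    return {"climate": {}, "stand": {}, "products": {}}


def simulate_scenario(
    scenario: ScenarioConfig,
    cfg: ExperimentConfig,
    caches: dict | None = None,
) -> pd.DataFrame:
    """Run the full pipeline for one scenario; site-averaged trajectory.

    Returns an annual DataFrame with stock columns (``veg_c``,
    ``deadwood_c``, ``soil_c``, ``product_*_c``), the stand and product
    fluxes, and the avoided-emission series.
    """
    if caches is None:
        caches = new_caches()
    sub_params = substitution.SubstitutionParams(
        df_material=cfg.df_material, df_fuel=cfg.df_fuel,
        decarb_2050=scenario.decarb_2050,
    )
    frames = []
    for site in cfg.sites:
        out = _get_stand(cfg, scenario, site, caches)
        prod = _get_products(cfg, scenario, site, caches)
        burned = out.fluxes["firewood"] + prod.fuelwood_burned
        avoided = substitution.avoided_series(
            out.years, prod.material_inflow, burned, prod.decayed, sub_params,
        )
        frame = out.to_frame()
        frame["product_short_c"] = prod.pool_short
        frame["product_medium_c"] = prod.pool_medium
        frame["product_long_c"] = prod.pool_long
        frame["product_inflow"] = prod.material_inflow
        frame["fuelwood_burned"] = prod.fuelwood_burned
        frame["product_decay"] = prod.decayed
        frame["avoided_material"] = avoided.material
        frame["avoided_fuel"] = avoided.fuel
        frame["avoided_eol"] = avoided.end_of_life
        frames.append(frame)
    if len(frames) == 1:
        traj = frames[0]
    else:
        traj = (
            pd.concat(frames).groupby("year", as_index=False).mean()
        )
    traj.insert(0, "scenario_id", scenario.scenario_id)
    return traj


def run_experiment(
    cfg: ExperimentConfig,
    caches: dict | None = None,
) -> pd.DataFrame:
    """Simulate every scenario of the factorial and tabulate the metrics.

    Returns one row per (scenario, horizon) with all factor levels,
    ``combined_sink``, ``cumulative_avoided`` and ``total_mitigation``
    (kgC/m2). Deterministic for a fixed config.
    """
    if caches is None:
        caches = new_caches()
    scenarios = cfg.scenarios()
    logger.info("running %d scenarios x %d horizons", len(scenarios),
                len(cfg.horizons))
    rows = []
    for k, scenario in enumerate(scenarios):
        try:
            traj = simulate_scenario(scenario, cfg, caches)
            for horizon in cfg.horizons:
                res = accounting.total_mitigation(
                    traj, horizon, scenario_id=scenario.scenario_id
                )
                row = {"scenario_id": scenario.scenario_id}
                row.update(scenario.factor_values())
                row.update(
                    horizon=horizon,
                    combined_sink=res.combined_sink,
                    cumulative_avoided=res.cumulative_avoided,
                    total_mitigation=res.total_mitigation,
                )
                rows.append(row)
        except Exception:
            logger.error("scenario %s failed", scenario.scenario_id)
            raise
        if (k + 1) % 500 == 0:
            logger.info("finished %d/%d scenarios", k + 1, len(scenarios))
    return pd.DataFrame(rows)


def design_frame(scenarios: Sequence[ScenarioConfig]) -> pd.DataFrame:
    """Factor table of a scenario list (no simulation)."""
    rows = [
        {"scenario_id": s.scenario_id, **s.factor_values()} for s in scenarios
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pairwise-difference attribution.

@dataclass(frozen=True)
class ComparisonSpec:
    """One factor contrast: level_a minus level_b, within a response subset."""

    factor: str
    level_a: Any
    level_b: Any
    metric: str = "total_mitigation"
    horizon: int = 2100
    subset: str | None = "exponential"

    def __post_init__(self) -> None:
        if self.factor not in FACTOR_ORDER:
            raise ConfigurationError(f"unknown factor {self.factor!r}")
        if self.level_a == self.level_b:
            raise ConfigurationError("comparison levels must differ")
        if self.metric not in METRICS:
            raise ConfigurationError(f"unknown metric {self.metric!r}")


@dataclass
class ComparisonResult:
    spec: ComparisonSpec
    differences: pd.Series

    @property
    def n_pairs(self) -> int:
        return len(self.differences)

    def summary(self) -> dict[str, float]:
        d = self.differences
        return {
            "n_pairs": float(len(d)),
            "median": float(d.median()),
            "min": float(d.min()),
            "max": float(d.max()),
            "positive_share": float((d > 0).mean()),
            "nonnegative_share": float((d >= 0).mean()),
        }


def match_pairs(
    frame: pd.DataFrame,
    factor: str,
    level_a: Any,
    level_b: Any,
    subset: str | None = "exponential",
) -> pd.DataFrame:
    """Exact-join rows at ``level_a`` to their partners at ``level_b``.

    Pairs are matched on all remaining factor columns; an unmatched row
    means the design is incomplete and raises. Rows outside the requested
    disturbance-response subset are dropped first (unless the contrast is on
    the response factor itself or ``subset`` is None).
    """
    sub = frame
    if subset is not None and factor != "disturbance_response":
        sub = sub[sub["disturbance_response"] == subset]
        if sub.empty:
            raise InputError(f"no rows in disturbance subset {subset!r}")
    for level in (level_a, level_b):
        if not (sub[factor] == level).any():
            raise InputError(f"level {level!r} of {factor!r} absent from results")
    keys = [c for c in FACTOR_COLUMNS if c != factor]
    a = sub[sub[factor] == level_a]
    b = sub[sub[factor] == level_b]
    merged = a.merge(b, on=keys, how="outer", suffixes=("_a", "_b"),
                     indicator=True)
    if (merged["_merge"] != "both").any():
        raise InputError(
            f"design incomplete: {(merged['_merge'] != 'both').sum()} "
            f"unmatched rows for {factor} {level_a} vs {level_b}"
        )
    return merged.drop(columns="_merge")


def count_pairs(
    frame: pd.DataFrame,
    factor: str,
    level_a: Any,
    level_b: Any,
    subset: str | None = "exponential",
) -> int:
    """Number of matched pairs for a contrast (works on a design table)."""
    return len(match_pairs(frame, factor, level_a, level_b, subset))


def pairwise_differences(
    results: pd.DataFrame,
    spec: ComparisonSpec,
) -> ComparisonResult:
    """Within-pair metric differences (level_a minus level_b)."""
    sub = results[results["horizon"] == spec.horizon]
    if sub.empty:
        raise InputError(f"no results at horizon {spec.horizon}")
    merged = match_pairs(sub, spec.factor, spec.level_a, spec.level_b,
                         spec.subset)
    diff = merged[f"{spec.metric}_a"] - merged[f"{spec.metric}_b"]
    return ComparisonResult(spec=spec, differences=diff.reset_index(drop=True))


#: Canonical factor contrasts mirroring the attribution analysis.
DEFAULT_CONTRASTS: tuple[tuple[str, Any, Any], ...] = (
    ("rcp", "RCP8.5", "RCP4.5"),
    ("rcp", "RCP2.6", "RCP4.5"),
    ("forest_age", "young", "mature"),
    ("forest_type", "NE", "BD"),
    ("harvest_intensity", 1.5, 1.0),
    ("harvest_intensity", 0.5, 1.0),
    ("harvest_intensity", 0.0, 1.0),
    ("salvage", True, False),
    ("material_usage", 1.5, 1.0),
    ("cascade", 1.5, 1.0),
    ("decarb_2050", 0.25, 0.50),
    ("decarb_2050", 0.75, 0.50),
)


def summarize(
    results: pd.DataFrame,
    *,
    contrasts: Sequence[tuple[str, Any, Any]] = DEFAULT_CONTRASTS,
    metrics: Sequence[str] = METRICS,
    subset: str | None = "exponential",
) -> pd.DataFrame:
    """Per-factor effect summary across horizons and metrics."""
    if results.empty:
        raise InputError("empty results table")
    rows = []
    for horizon in sorted(results["horizon"].unique()):
        for factor, a, b in contrasts:
            if factor in results and not (
                (results[factor] == a).any() and (results[factor] == b).any()
            ):
                continue
            for metric in metrics:
                spec = ComparisonSpec(
                    factor=factor, level_a=a, level_b=b, metric=metric,
                    horizon=int(horizon), subset=subset,
                )
                comp = pairwise_differences(results, spec)
                rows.append({
                    "factor": factor, "level_a": a, "level_b": b,
                    "metric": metric, "horizon": int(horizon),
                    **comp.summary(),
                })
    return pd.DataFrame(rows)


def setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
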