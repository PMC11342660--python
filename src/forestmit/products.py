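"""Wood-product pools: allocation, Gamma decay, usage ramp, cascading.

Removed stem carbon splits into long-, medium- and short-lived product pools
plus fuel wood (burned in the creation year). Each product vintage decays
following a Gamma survival curve calibrated so that half the carbon is gone
after the pool's median lifetime (3 / 18 / 93 years for short / medium /
long); cascading extends the median of post-2020 vintages by raising the
Gamma shape parameter at fixed scale. Decayed carbon is emitted and handed
to end-of-life energy recovery in the same year.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .errors import ConfigurationError, NumericalError

POOL_CLASSES = ("short", "medium", "long")

#: Median product lifetimes in years (half the carbon decayed by then).
MEDIAN_YEARS: dict[str, float] = {"short": 3.0, "medium": 18.0, "long": 93.0}

#: Year after which the cascade and usage-ramp scenarios apply.
CASCADE_VINTAGE_YEAR = 2020

DEFAULT_GAMMA_SHAPE = 2.0

#: Maximum tracked product age; survival beyond this is booked as decayed.
MAX_PRODUCT_AGE = 600


@dataclass(frozen=True)
class ProductFractions:
    """Allocation of removed stem carbon to product classes plus fuel wood."""

    long: float
    medium: float
    short: float
    fuel: float

    def __post_init__(self) -> None:
        vals = (self.long, self.medium, self.short, self.fuel)
        if min(vals) < 0:
            raise ConfigurationError(f"negative product fraction in {vals}")
        if abs(sum(vals) - 1.0) > 1e-9:
            raise ConfigurationError(f"product fractions must sum to 1, got {vals}")

    def as_dict(self) -> dict[str, float]:
        return {
            "long": self.long, "medium": self.medium,
            "short": self.short, "fuel": self.fuel,
        }


#: Default allocation per forest type; the fuel share is the remainder.
DEFAULT_FRACTIONS: dict[str, ProductFractions] = {
    "NE": ProductFractions(long=0.37, medium=0.17, short=0.36, fuel=0.10),
    "BD": ProductFractions(long=0.06, medium=0.34, short=0.25, fuel=0.35),
}


@dataclass(frozen=True)
class DecaySpec:
    """Gamma decay curve of one product class."""

    pool_class: str
    median_years: float
    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.shape <= 0 or self.scale <= 0:
            raise ConfigurationError("Gamma shape and scale must be positive")

    def survival(self, t):
        """Fraction of a vintage still in use at age ``t`` (1 at t=0)."""
        return 1.0 - stats.gamma.cdf(t, a=self.shape, scale=self.scale)

    def survival_table(self, max_age: int = MAX_PRODUCT_AGE) -> np.ndarray:
        ages = np.arange(max_age + 1)
        table = self.survival(ages)
        table[-1] = 0.0  # close the tail so every vintage fully decays
        return table


def calibrate_gamma(median_years: float, shape: float = DEFAULT_GAMMA_SHAPE,
                    pool_class: str = "long") -> DecaySpec:
    """Solve the Gamma scale so that survival(median_years) = 1/2.

    With the shape fixed, the scale is the target median divided by the
    median of the standard (scale=1) Gamma distribution.
    """
    if median_years <= 0 or shape <= 0:
        raise ConfigurationError("median_years and shape must be positive")
    standard_median = stats.gamma.ppf(0.5, a=shape)
    scale = median_years / standard_median
    spec = DecaySpec(pool_class=pool_class, median_years=median_years,
                     shape=shape, scale=scale)
    if abs(spec.survival(median_years) - 0.5) > 1e-6:
        raise NumericalError(
            f"gamma calibration failed: survival({median_years}) = "
            f"{spec.survival(median_years)!r} for shape={shape}"
        )
    return spec


def default_decay_specs(shape: float = DEFAULT_GAMMA_SHAPE) -> dict[str, DecaySpec]:
    return {
        cls: calibrate_gamma(MEDIAN_YEARS[cls], shape, pool_class=cls)
        for cls in POOL_CLASSES
    }


def apply_cascading(spec: DecaySpec, factor: float) -> DecaySpec:
    """Extend a decay spec's median lifetime by ``factor`` via the shape.

    The scale is held fixed and the shape increased until the Gamma median
    equals ``factor`` times the old median. Applies to product vintages
    created after 2020 only (the caller keeps older vintages on the base
    spec).
    """
    if factor < 1.0:
        raise ConfigurationError(f"cascade factor must be >= 1, got {factor}")
    if factor == 1.0:
        return spec
    target = factor * spec.median_years

    def median_gap(shape: float) -> float:
        return stats.gamma.ppf(0.5, a=shape, scale=spec.scale) - target

    lo, hi = spec.shape, spec.shape
    for _ in range(60):
        hi *= 1.5
        if median_gap(hi) > 0:
            break
    else:
        raise NumericalError(
            f"cascading solve failed to bracket for factor={factor}"
        )
    try:
        new_shape = optimize.brentq(median_gap, lo, hi, xtol=1e-12, rtol=1e-14)
    except (RuntimeError, ValueError) as exc:
        raise NumericalError(f"cascading shape solve failed: {exc}") from exc
    return replace(spec, shape=float(new_shape), median_years=target)


def usage_fractions(
    forest_type: str,
    year: int,
    material_scenario: float,
    *,
    base: ProductFractions | None = None,
    ramp_start: int = 2020,
    ramp_end: int = 2050,
    mode: str = "proportional",
) -> ProductFractions:
    """Product allocation fractions for one harvest year.

    Under the default scenario (multiplier 1.0) the base fractions apply in
    every year. Under the increased-usage scenario the long- and medium-lived
    shares scale by ``1 + (material_scenario - 1) * ramp(year)``, phased in
    linearly over 2020-2050, at the expense of the short-lived and fuel
    shares. ``mode="proportional"`` removes the deficit from short and fuel
    in proportion to their base shares; ``mode="short_first"`` takes it from
    the short-lived share before touching fuel.
    """
    if base is None:
        try:
            base = DEFAULT_FRACTIONS[forest_type]
        except KeyError:
            raise ConfigurationError(
                f"unknown forest type {forest_type!r}"
            ) from None
    if material_scenario == 1.0:
        return base
    ramp = min(max((year - ramp_start) / (ramp_end - ramp_start), 0.0), 1.0)
    boost = 1.0 + (material_scenario - 1.0) * ramp
    long_, medium = base.long * boost, base.medium * boost
    deficit = (long_ + medium) - (base.long + base.medium)
    if mode == "proportional":
        pool = base.short + base.fuel
        short = base.short - deficit * base.short / pool
        fuel = base.fuel - deficit * base.fuel / pool
    elif mode == "short_first":
        short = base.short - deficit
        fuel = base.fuel
        if short < 0:
            fuel += short
            short = 0.0
    else:
        raise ConfigurationError(f"unknown usage ramp mode {mode!r}")
    if min(short, fuel) < -1e-12:
        raise ConfigurationError(
            f"usage ramp drove a fraction negative: short={short}, fuel={fuel}"
        )
    return ProductFractions(long=long_, medium=medium,
                            short=max(short, 0.0), fuel=max(fuel, 0.0))


@dataclass
class ProductLedger:
    """Vintage-resolved carbon in the product pools.

    Cohorts are stored in parallel arrays; each cohort references a decay
    spec through a precomputed annual survival table, so a ledger step is a
    vectorized lookup.
    """

    specs: list[DecaySpec] = field(default_factory=list)
    _tables: list[np.ndarray] = field(default_factory=list)
    vintage: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int))
    spec_idx: np.ndarray = field(
        default_factory=lambda: np.empty(0, dtype=int))
    initial: np.ndarray = field(default_factory=lambda: np.empty(0))
    remaining: np.ndarray = field(default_factory=lambda: np.empty(0))

    def register_spec(self, spec: DecaySpec) -> int:
        self.specs.append(spec)
        self._tables.append(spec.survival_table())
        return len(self.specs) - 1

    def add(self, vintage_year: int, carbon: float, spec_index: int) -> None:
        """Book a new product cohort (created in ``vintage_year``)."""
        if carbon < 0:
            raise ConfigurationError("cohort carbon must be >= 0")
        if carbon == 0:
            return
        self.vintage = np.append(self.vintage, vintage_year)
        self.spec_idx = np.append(self.spec_idx, spec_index)
        self.initial = np.append(self.initial, carbon)
        self.remaining = np.append(self.remaining, carbon)

    def total(self) -> float:
        return float(self.remaining.sum())

    def total_by_class(self) -> dict[str, float]:
        out = dict.fromkeys(POOL_CLASSES, 0.0)
        for i, spec in enumerate(self.specs):
            mask = self.spec_idx == i
            out[spec.pool_class] += float(self.remaining[mask].sum())
        return out

    def step(self, year: int) -> dict[str, float]:
        """Advance the ledger to ``year`` and return decayed carbon by class.

        A cohort of age ``a = year - vintage`` releases
        ``initial * (survival(a-1) - survival(a))``; age-0 cohorts do not
        decay yet.
        """
        decayed = dict.fromkeys(POOL_CLASSES, 0.0)
        if len(self.vintage) == 0:
            return decayed
        age = year - self.vintage
        for i, spec in enumerate(self.specs):
            # the tail is released in full at the maximum tracked age; older
            # cohorts are already empty and must not decay again
            mask = (self.spec_idx == i) & (age >= 1) & (age <= MAX_PRODUCT_AGE)
            if not mask.any():
                continue
            a = age[mask]
            table = self._tables[i]
            dec = self.initial[mask] * (table[a - 1] - table[a])
            # clamp float dust so emptied cohorts never go microscopically negative
            self.remaining[mask] = np.maximum(self.remaining[mask] - dec, 0.0)
            decayed[spec.pool_class] += float(dec.sum())
        return decayed


# ---------------------------------------------------------------------------
# Pipeline helper: drive a ledger from an annual removed-stem series.

@dataclass
class ProductSeries:
    """Annual product-chain series for one stand trajectory (kgC/m2)."""

    years: np.ndarray
    pool_short: np.ndarray
    pool_medium: np.ndarray
    pool_long: np.ndarray
    material_inflow: np.ndarray   # short+medium+long product creation
    fuelwood_burned: np.ndarray   # fuel-share of removed stem, burned same year
    decayed: np.ndarray           # end-of-life releases (all classes)

    def pool_total(self) -> np.ndarray:
        return self.pool_short + self.pool_medium + self.pool_long

    def balance_residual(self) -> np.ndarray:
        """Annual ledger mass-balance residual (inflow - decay - dStock)."""
        return (self.material_inflow - self.decayed)[1:] - np.diff(
            self.pool_total()
        )


def build_product_series(
    years: np.ndarray,
    removed_stem: np.ndarray,
    forest_type: str,
    material_scenario: float = 1.0,
    cascade_factor: float = 1.0,
    *,
    shape: float = DEFAULT_GAMMA_SHAPE,
    base_fractions: ProductFractions | None = None,
    ramp_mode: str = "proportional",
) -> ProductSeries:
    """Run the product chain over an annual removed-stem carbon series.

    Each year's removal is split by the (possibly ramped) usage fractions;
    the fuel share burns immediately, the rest enters the ledger. Vintages
    created after 2020 use the cascaded decay specs.
    """
    if len(years) != len(removed_stem):
        raise ConfigurationError("years and removed_stem must align")
    base_specs = default_decay_specs(shape)
    cascaded = {
        cls: apply_cascading(spec, cascade_factor)
        for cls, spec in base_specs.items()
    }
    ledger = ProductLedger()
    base_idx = {cls: ledger.register_spec(base_specs[cls]) for cls in POOL_CLASSES}
    casc_idx = {cls: ledger.register_spec(cascaded[cls]) for cls in POOL_CLASSES}

    n = len(years)
    pools = {cls: np.zeros(n) for cls in POOL_CLASSES}
    material_inflow = np.zeros(n)
    fuelwood = np.zeros(n)
    decayed_total = np.zeros(n)
    for t, year in enumerate(np.asarray(years, dtype=int)):
        decayed = ledger.step(int(year))
        decayed_total[t] = sum(decayed.values())
        stem = float(removed_stem[t])
        if stem > 0:
            fr = usage_fractions(
                forest_type, int(year), material_scenario,
                base=base_fractions, mode=ramp_mode,
            )
            idx = casc_idx if year > CASCADE_VINTAGE_YEAR else base_idx
            for cls in POOL_CLASSES:
                ledger.add(int(year), stem * getattr(fr, cls), idx[cls])
            material_inflow[t] = stem * (fr.long + fr.medium + fr.short)
            fuelwood[t] = stem * fr.fuel
        totals = ledger.total_by_class()
        for cls in POOL_CLASSES:
            pools[cls][t] = totals[cls]
    return ProductSeries(
        years=np.asarray(years, dtype=int),
        pool_short=pools["short"],
        pool_medium=pools["medium"],
        pool_long=pools["long"],
        material_inflow=material_inflow,
        fuelwood_burned=fuelwood,
        decayed=decayed_total,
    )
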