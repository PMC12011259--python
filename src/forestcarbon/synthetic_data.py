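"""Synthetic stands, inventories and project ledgers.

Generators with the statistical structure the toolkit expects, so every
stage runs without external data. Tree growth follows monotone
piecewise-linear DBH/height curves over age (default anchors are the
Chinese-fir validation means), biomass follows a power law with
multiplicative lognormal noise, and mortality thins the stand at a
constant annual rate. Every public generator takes a mandatory seed.

``simulate_project_ledger`` additionally returns the analytically known
net sink per year, computed by direct arithmetic inside the generator so
round-trip tests of the accounting module have an independent truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .carbon_accounting import CO2_PER_C, GhgRecord, Pool, PoolLedgerEntry
from .inventory_io import PlotInventory, TreeRecord
from .sampling_design import Stratum

__all__ = [
    "FIR_AGE_ANCHORS",
    "FIR_DBH_ANCHORS",
    "FIR_HEIGHT_ANCHORS",
    "GrowthScenario",
    "simulate_stand",
    "simulate_project_ledger",
]

# Chinese-fir growth anchors: (age a, mean DBH cm, mean height m) means
# of even-aged stands, used as the default monotone growth curve.
FIR_AGE_ANCHORS = (5, 6, 7, 8, 9, 10, 11, 12, 13, 15, 16, 17, 18, 19, 20, 21, 22)
FIR_DBH_ANCHORS = (
    8.75, 9.25, 9.75, 10.35, 11.15, 11.65, 12.15, 12.65, 13.15, 13.65,
    14.15, 14.35, 14.75, 14.95, 15.15, 15.45, 15.75,
)
FIR_HEIGHT_ANCHORS = (
    5.37, 5.97, 6.87, 7.87, 8.27, 8.97, 9.87, 10.07, 10.67, 11.07,
    11.77, 11.97, 12.87, 12.87, 13.27, 13.57, 13.97,
)


def _interp_curve(ages: Sequence[float], values: Sequence[float]) -> Callable:
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    if np.any(np.diff(ages) <= 0):
        raise ValueError("anchor ages must be strictly increasing")
    if np.any(np.diff(values) < 0):
        raise ValueError("anchor values must be non-decreasing")

    def curve(age):
        return float(np.interp(age, ages, values))

    return curve


@dataclass
class GrowthScenario:
    """Age-indexed growth model for one species.

    ``dbh_curve``/``height_curve`` map age (years) to cm / m and must be
    monotone over ``age_range``. Biomass is ``a * D^b * exp(eps)`` with
    ``eps ~ N(0, noise_sd^2)``; DBH and height get the same multiplicative
    noise model. ``mortality_rate`` is the annual death probability.
    """

    species: str = "Cunninghamia lanceolata"
    age_range: tuple[float, float] = (5.0, 22.0)
    dbh_curve: Callable[[float], float] = field(
        default_factory=lambda: _interp_curve(FIR_AGE_ANCHORS, FIR_DBH_ANCHORS)
    )
    height_curve: Callable[[float], float] = field(
        default_factory=lambda: _interp_curve(
            FIR_AGE_ANCHORS, FIR_HEIGHT_ANCHORS
        )
    )
    biomass_a: float = 0.1
    biomass_b: float = 2.4
    noise_sd: float = 0.1
    mortality_rate: float = 0.01
    region_code: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.age_range[0] >= self.age_range[1]:
            raise ValueError("age_range must be (lo, hi) with lo < hi")
        if self.biomass_a <= 0:
            raise ValueError("biomass_a must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.mortality_rate < 1.0):
            raise ValueError("mortality_rate must be in [0, 1)")

    def mean_dbh(self, age: float) -> float:
        """Analytic mean DBH at ``age``: curve value times exp(sd^2/2)."""
        return self.dbh_curve(age) * math.exp(self.noise_sd**2 / 2.0)

    def survival_probability(self, age: float) -> float:
        return (1.0 - self.mortality_rate) ** age


def simulate_stand(
    scenario: GrowthScenario,
    n_trees: int,
    age: float,
    plot_id: str = "sim-plot",
    area: float = 0.08,
    stratum_id: str = "stratum-1",
    year: int = 0,
) -> PlotInventory:
    """Draw one even-aged plot inventory from a growth scenario.

    DBH, height and biomass are the curve/power-law values perturbed by
    lognormal noise; each tree survives to ``age`` with probability
    ``(1 - mortality_rate)^age``. Deterministic given ``scenario.seed``.
    """
    if n_trees <= 0:
        raise ValueError("n_trees must be > 0")
    lo, hi = scenario.age_range
    if not (lo <= age <= hi):
        raise ValueError(f"age {age} outside scenario range [{lo}, {hi}]")
    rng = np.random.default_rng(scenario.seed)
    dbh0 = scenario.dbh_curve(age)
    h0 = scenario.height_curve(age)
    eps = rng.normal(0.0, scenario.noise_sd, size=(3, n_trees))
    dbh = dbh0 * np.exp(eps[0])
    height = h0 * np.exp(eps[1])
    mass = scenario.biomass_a * dbh**scenario.biomass_b * np.exp(eps[2])
    alive = rng.random(n_trees) < scenario.survival_probability(age)
    trees = [
        TreeRecord(
            tree_id=f"{plot_id}-{i:04d}",
            species_raw=scenario.species,
            species_canonical=scenario.species,
            dbh=float(dbh[i]),
            height=float(height[i]),
            age=age,
            region_code=scenario.region_code,
            biomass_total=float(mass[i]),
            alive=bool(alive[i]),
        )
        for i in range(n_trees)
    ]
    return PlotInventory(
        plot_id=plot_id,
        area=area,
        stratum_id=stratum_id,
        trees=trees,
        year=year,
    )


def simulate_project_ledger(
    scenario: GrowthScenario,
    strata: Sequence[Stratum],
    years: Sequence[int],
    start_age: float = 5.0,
    area_per_stratum: float = 10.0,
    carbon_fraction: float = 0.5,
    root_shoot_ratio: float = 0.25,
    stems_per_hm2: float = 400.0,
    ghg_per_year: float = 0.0,
) -> tuple[list[PoolLedgerEntry], list[GhgRecord], dict[int, float]]:
    """Emit a multi-year pool ledger plus its analytically true net sink.

    The stand in stratum ``i`` starts at ``start_age`` in ``years[0]`` and
    ages one year per calendar year. Per-hectare aboveground biomass is
    the deterministic stand value (noise off here so the truth is exact):
    ``stems_per_hm2 * a * D(age)^b / 1000`` t/hm2, scaled by the stratum's
    area weight to make strata heterogeneous; belowground is the
    root-shoot fraction of it.

    Returns ``(entries, ghg_records, true_net_sink_by_year)``; the truth
    covers ``years[1:]`` (the first year has no preceding stock) and is
    computed by direct closed-form arithmetic, independent of the
    accounting module.
    """
    years = sorted(years)
    if len(years) < 2:
        raise ValueError("need at least two years for a stock change")
    if any(b - a != 1 for a, b in zip(years[:-1], years[1:])):
        raise ValueError("years must be consecutive")
    lo, hi = scenario.age_range
    cohort = int(start_age)  # age-class label is the cohort, fixed over time
    entries: list[PoolLedgerEntry] = []
    biomass_at: dict[tuple[str, int], float] = {}  # (stratum, year) -> AA t/hm2
    for yi, year in enumerate(years):
        age = min(max(start_age + yi, lo), hi)
        for s in strata:
            dbh = scenario.dbh_curve(age)
            kg_per_tree = scenario.biomass_a * dbh**scenario.biomass_b
            b_aa = (1.0 + s.area_weight) * stems_per_hm2 * kg_per_tree / 1000.0
            b_bb = b_aa * root_shoot_ratio
            biomass_at[(s.stratum_id, year)] = b_aa
            for pool, biomass in (
                (Pool.TREE_AA, b_aa),
                (Pool.TREE_BB, b_bb),
            ):
                entries.append(
                    PoolLedgerEntry(
                        stratum=s.stratum_id,
                        species=scenario.species,
                        age_class=cohort,
                        year=year,
                        pool=pool,
                        biomass=biomass,
                        carbon_fraction=carbon_fraction,
                        area=area_per_stratum,
                    )
                )
    ghg_records = [
        GhgRecord(year=y, fuel_emissions=ghg_per_year) for y in years
    ]
    # independent closed-form truth: 44/12 * CF * A * (1 + ratio) * dB_AA
    truth: dict[int, float] = {}
    for prev, year in zip(years[:-1], years[1:]):
        sink = 0.0
        for s in strata:
            d_baa = biomass_at[(s.stratum_id, year)] - biomass_at[
                (s.stratum_id, prev)
            ]
            sink += (
                CO2_PER_C
                * carbon_fraction
                * area_per_stratum
                * (1.0 + root_shoot_ratio)
                * d_baa
            )
        truth[year] = sink - ghg_per_year
    return entries, ghg_records, truth
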