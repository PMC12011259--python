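"""Carbon-pool stock-change accounting to a net project CO2e sink.

The ledger tracks biomass carbon per (stratum, species, age-class, year,
pool). Pools are tree/shrub x aboveground/belowground; stocks are
``biomass (t d.m./hm2) * carbon fraction * area (hm2)`` in t C, and
year-over-year changes convert to t CO2e through the single 44/12
molecular-weight operator. The net sink for year t is

    C_P(t) = dC_P(t) - GHG_E(t) - LK(t) - dC_BSL(t)

with leakage LK defaulting to 0 and the baseline dC_BSL 0 for sites
cleared before project start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "CO2_PER_C",
    "Pool",
    "PoolLedgerEntry",
    "GhgRecord",
    "ProjectAccount",
    "pool_carbon_stock",
    "stock_change_co2e",
    "shrub_pool_change",
    "project_stock_change",
    "ghg_emissions",
    "baseline_change",
    "net_carbon_sink",
    "read_ledger_csv",
    "read_ghg_csv",
]

#: Molecular-weight ratio of CO2 to C; the only t C -> t CO2e conversion.
CO2_PER_C = 44.0 / 12.0


class Pool(str, Enum):
    """Biomass carbon pools tracked by default.

    Soil, litter and deadwood are accepted by the ledger schema but are
    deliberately not part of the default accounting set.
    """

    TREE_AA = "tree_AA"
    TREE_BB = "tree_BB"
    SHRUB_AA = "shrub_AA"
    SHRUB_BB = "shrub_BB"
    SOIL = "soil"
    LITTER = "litter"
    DEADWOOD = "deadwood"


DEFAULT_POOLS = frozenset(
    {Pool.TREE_AA, Pool.TREE_BB, Pool.SHRUB_AA, Pool.SHRUB_BB}
)


def _check_cf(cf: float) -> None:
    if not (0.0 < cf < 1.0):
        raise ValueError(f"carbon fraction {cf} outside (0, 1)")


@dataclass(frozen=True)
class PoolLedgerEntry:
    """Carbon stock of one pool for a (stratum, species, age, year) cell."""

    stratum: str
    species: str
    age_class: int
    year: int
    pool: Pool
    biomass: float  # t d.m. / hm2
    carbon_fraction: float
    area: float  # hm2

    def __post_init__(self) -> None:
        _check_cf(self.carbon_fraction)
        if self.biomass < 0:
            raise ValueError("biomass must be >= 0")
        if self.area < 0:
            raise ValueError("area must be >= 0")

    @property
    def key(self) -> tuple[str, str, int, Pool]:
        return (self.stratum, self.species, self.age_class, self.pool)

    @property
    def carbon_stock(self) -> float:
        """Stock in t C = biomass * CF * area."""
        return pool_carbon_stock(self.biomass, self.carbon_fraction, self.area)


@dataclass(frozen=True)
class GhgRecord:
    """Project GHG emission increases for one year, both in t CO2e."""

    year: int
    fuel_emissions: float = 0.0
    fertilizer_emissions: float = 0.0

    def __post_init__(self) -> None:
        if self.fuel_emissions < 0 or self.fertilizer_emissions < 0:
            raise ValueError("emission terms must be >= 0")


def pool_carbon_stock(biomass: float, cf: float, area: float) -> float:
    """Carbon stock (t C) of one pool: biomass (t/hm2) x CF x area (hm2)."""
    _check_cf(cf)
    if biomass < 0 or area < 0:
        raise ValueError("biomass and area must be >= 0")
    return biomass * cf * area


def stock_change_co2e(c_t: float, c_prev: float) -> float:
    """Stock change in t CO2e: (44/12) * (C_t - C_{t-1}).

    Sign is preserved — a falling stock yields a negative value
    (carbon source).
    """
    return CO2_PER_C * (c_t - c_prev)


def shrub_pool_change(delta_biomass: float, cf: float, area: float) -> float:
    """Shrub pool change in t CO2e from a per-hectare biomass delta."""
    _check_cf(cf)
    if area < 0:
        raise ValueError("area must be >= 0")
    return CO2_PER_C * delta_biomass * cf * area


def _stocks_by_key(
    entries: Iterable[PoolLedgerEntry], year: int
) -> dict[tuple, float]:
    out: dict[tuple, float] = {}
    for e in entries:
        if e.year != year:
            continue
        if e.key in out:
            raise ValueError(
                f"duplicate ledger entry for {e.key} in year {year}"
            )
        out[e.key] = e.carbon_stock
    return out


def project_stock_change(
    entries: Iterable[PoolLedgerEntry],
    year: int,
    pools: frozenset[Pool] = DEFAULT_POOLS,
) -> float:
    """Project-wide stock change dC_P for ``year`` in t CO2e.

    Triple sum over stratum x species x age of the AA+BB changes of each
    selected pool between ``year - 1`` and ``year``. A key present in only
    one of the two years is treated as stock 0 in the other, with a
    warning.
    """
    entries = list(entries)
    now = _stocks_by_key(entries, year)
    prev = _stocks_by_key(entries, year - 1)
    total = 0.0
    for key in sorted(set(now) | set(prev), key=str):
        if key[3] not in pools:
            continue
        if key not in now or key not in prev:
            warnings.warn(
                f"ledger key {key} present in only one of years "
                f"{year - 1}/{year}; missing stock treated as 0",
                stacklevel=2,
            )
        total += stock_change_co2e(now.get(key, 0.0), prev.get(key, 0.0))
    return total


def ghg_emissions(record: GhgRecord) -> float:
    """Total GHG emission increase for one year (t CO2e)."""
    return record.fuel_emissions + record.fertilizer_emissions


def baseline_change(
    baseline: Mapping[str, tuple[float, float]] | None,
) -> float:
    """Baseline stock change dC_BSL (t CO2e): sum of per-stratum AA+BB.

    ``baseline`` maps stratum id -> (AA change, BB change). ``None`` or an
    empty mapping is the cleared-site scenario and returns 0.
    """
    if not baseline:
        return 0.0
    return sum(aa + bb for aa, bb in baseline.values())


@dataclass
class ProjectAccount:
    """Full project: ledger entries, GHG records, leakage and baseline."""

    entries: list[PoolLedgerEntry] = field(default_factory=list)
    ghg: dict[int, GhgRecord] = field(default_factory=dict)
    leakage: dict[int, float] = field(default_factory=dict)
    #: per-year baseline mapping stratum -> (AA, BB) change in t CO2e;
    #: absent year == cleared site == 0
    baseline: dict[int, dict[str, tuple[float, float]]] = field(
        default_factory=dict
    )
    pools: frozenset[Pool] = DEFAULT_POOLS

    @classmethod
    def from_records(
        cls,
        entries: Iterable[PoolLedgerEntry],
        ghg: Iterable[GhgRecord] = (),
        leakage: Mapping[int, float] | None = None,
        baseline: Mapping[int, Mapping[str, tuple[float, float]]] | None = None,
    ) -> "ProjectAccount":
        acct = cls(entries=list(entries))
        for rec in ghg:
            if rec.year in acct.ghg:
                raise ValueError(f"duplicate GHG record for year {rec.year}")
            acct.ghg[rec.year] = rec
        if leakage:
            acct.leakage.update(leakage)
        if baseline:
            acct.baseline.update({y: dict(b) for y, b in baseline.items()})
        return acct

    @property
    def years(self) -> list[int]:
        return sorted({e.year for e in self.entries})

    def stock_change(self, year: int) -> float:
        return project_stock_change(self.entries, year, self.pools)

    def components(self, year: int) -> dict[str, float]:
        """All four terms of the net-sink identity for one year."""
        if year not in {e.year for e in self.entries}:
            raise KeyError(f"no ledger entries for year {year}")
        ghg_t = ghg_emissions(self.ghg[year]) if year in self.ghg else 0.0
        return {
            "delta_C_P": self.stock_change(year),
            "GHG": ghg_t,
            "LK": self.leakage.get(year, 0.0),
            "delta_C_BSL": baseline_change(self.baseline.get(year)),
        }

    def net_sink(self, year: int) -> float:
        c = self.components(year)
        return c["delta_C_P"] - c["GHG"] - c["LK"] - c["delta_C_BSL"]


def net_carbon_sink(account: ProjectAccount, year: int) -> float:
    """Net project carbon sink C_P for ``year`` in t CO2e."""
    return account.net_sink(year)


def read_ledger_csv(path) -> list[PoolLedgerEntry]:
    """Read ledger entries from CSV.

    Expected columns: stratum, species, age_class, year, pool,
    biomass_t_per_hm2, cf, area_hm2.
    """
    df = pd.read_csv(path)
    required = {
        "stratum", "species", "age_class", "year", "pool",
        "biomass_t_per_hm2", "cf", "area_hm2",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ledger CSV missing columns: {sorted(missing)}")
    return [
        PoolLedgerEntry(
            stratum=str(r.stratum),
            species=str(r.species),
            age_class=int(r.age_class),
            year=int(r.year),
            pool=Pool(r.pool),
            biomass=float(r.biomass_t_per_hm2),
            carbon_fraction=float(r.cf),
            area=float(r.area_hm2),
        )
        for r in df.itertuples(index=False)
    ]


def read_ghg_csv(path) -> list[GhgRecord]:
    """Read per-year GHG records from CSV with columns t, fuel, fertilizer."""
    df = pd.read_csv(path)
    required = {"t", "fuel", "fertilizer"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"GHG CSV missing columns: {sorted(missing)}")
    return [
        GhgRecord(
            year=int(r.t),
            fuel_emissions=float(r.fuel),
            fertilizer_emissions=float(r.fertilizer),
        )
        for r in df.itertuples(index=False)
    ]
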