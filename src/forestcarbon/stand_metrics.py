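"""Stand-level volume statistics.

Per-species volume/count subtotals over sample groups, survival ratios
(surviving vs total standing volume) and stand volume densities. Values
are kept at full precision; display rounding to 2 decimal places matches
the convention of printed inventory tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "SpeciesVolumeGroup",
    "PlotVolumeSummary",
    "species_subtotals",
    "subtotals_from_frame",
    "survival_ratio",
    "volume_density",
    "summarize_plot",
]


@dataclass(frozen=True)
class SpeciesVolumeGroup:
    """Volume (m3) and stem count of one species in one sample group."""

    group_id: int
    species: str
    volume: float
    count: int

    def __post_init__(self) -> None:
        if self.volume < 0:
            raise ValueError("volume must be >= 0")
        if self.count < 0:
            raise ValueError("count must be >= 0")


@dataclass(frozen=True)
class PlotVolumeSummary:
    """Whole-plot volume summary; ratios recomputed from the volumes."""

    total_volume: float  # m3
    surviving_volume: float  # m3
    volume_density: float  # m3/hm2
    surviving_density: float  # m3/hm2
    survival_ratio: float  # fraction in [0, 1]

    def __post_init__(self) -> None:
        if self.surviving_volume > self.total_volume + 1e-9:
            raise ValueError("surviving volume exceeds total volume")

    @property
    def survival_percent(self) -> float:
        return 100.0 * self.survival_ratio

    def as_dict(self) -> dict:
        return {
            "total_volume_m3": self.total_volume,
            "surviving_volume_m3": self.surviving_volume,
            "volume_density_m3_hm2": self.volume_density,
            "surviving_density_m3_hm2": self.surviving_density,
            "survival_ratio_pct": round(self.survival_percent, 2),
        }


def species_subtotals(
    groups: Iterable[SpeciesVolumeGroup],
) -> dict[str, tuple[float, int]]:
    """Exact per-species (volume, count) sums over sample groups."""
    groups = list(groups)
    if not groups:
        raise ValueError("groups must be non-empty")
    out: dict[str, tuple[float, int]] = {}
    for g in groups:
        vol, cnt = out.get(g.species, (0.0, 0))
        out[g.species] = (vol + g.volume, cnt + g.count)
    return out


def subtotals_from_frame(
    table: pd.DataFrame,
    species_columns: Mapping[str, tuple[str, str]],
) -> dict[str, tuple[float, int]]:
    """Subtotals from a wide table.

    ``species_columns`` maps species -> (volume column, count column),
    e.g. ``{"Robinia pseudoacacia": ("volume_robinia_m3", "count_robinia")}``.
    """
    groups = []
    for species, (vcol, ccol) in species_columns.items():
        for gid, vol, cnt in zip(table["group_id"], table[vcol], table[ccol]):
            groups.append(
                SpeciesVolumeGroup(
                    group_id=int(gid),
                    species=species,
                    volume=float(vol),
                    count=int(cnt),
                )
            )
    return species_subtotals(groups)


def survival_ratio(total: float, surviving: float) -> float:
    """Surviving share of standing volume, as a percentage."""
    if total <= 0:
        raise ValueError("total volume must be > 0")
    if surviving < 0:
        raise ValueError("surviving volume must be >= 0")
    return 100.0 * surviving / total


def volume_density(volume: float, area: float) -> float:
    """Stand volume density, m3/hm2."""
    if area <= 0:
        raise ValueError("area must be > 0")
    if volume < 0:
        raise ValueError("volume must be >= 0")
    return volume / area


def summarize_plot(
    total_volume: float, surviving_volume: float, area: float
) -> PlotVolumeSummary:
    """Build the full PlotVolumeSummary for one plot of ``area`` hm2."""
    return PlotVolumeSummary(
        total_volume=total_volume,
        surviving_volume=surviving_volume,
        volume_density=volume_density(total_volume, area),
        surviving_density=volume_density(surviving_volume, area),
        survival_ratio=surviving_volume / total_volume,
    )
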