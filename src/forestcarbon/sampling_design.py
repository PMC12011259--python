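"""Stratified sampling design for carbon monitoring plots.

Computes how many permanent plots a project needs to hit an absolute
error bound ``E`` (t/hm2) at a chosen reliability index ``t_val``, and how
to split them across carbon strata by optimal (Neyman-style) allocation.

The full finite-population formula is

    n = N * t^2 * sum_i(W_i * S_i^2) / (N * E^2 + t^2 * sum_i(W_i * S_i^2))

with ``N = total_area / plot_area`` the sampling population. Its N->inf
limit ``n = (t/E)^2 * sum_i(W_i * S_i^2)`` is exposed as the simplified
formula, and a finite-population adjustment ``n_a = n / (1 + n/N)`` is
available as a second pass.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "Stratum",
    "SamplingConfig",
    "required_plot_count",
    "adjust_plot_count",
    "simplified_plot_count",
    "allocate_plots",
    "error_bound_from_relative",
]

#: Two-sided 90% standard-normal quantile, the default reliability index.
T_90 = 1.645


@dataclass(frozen=True)
class Stratum:
    """One carbon stratum: area weight W and carbon-stock SD (t/hm2)."""

    stratum_id: str
    area_weight: float
    stock_sd: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.area_weight <= 1.0):
            raise ValueError(
                f"stratum {self.stratum_id!r}: area_weight {self.area_weight} "
                "outside [0, 1]"
            )
        if self.stock_sd < 0 or not math.isfinite(self.stock_sd):
            raise ValueError(
                f"stratum {self.stratum_id!r}: stock_sd must be finite and >= 0"
            )


@dataclass(frozen=True)
class SamplingConfig:
    """Project-level sampling parameters.

    total_area and plot_area are in hm2; error_bound is the absolute
    error bound E in t/hm2; reliability_index is the quantile t_val.
    """

    total_area: float
    plot_area: float
    reliability_index: float = T_90
    error_bound: float = 5.0
    min_plots: int = 1

    def __post_init__(self) -> None:
        if self.total_area <= 0:
            raise ValueError("total_area must be > 0")
        if self.plot_area <= 0:
            raise ValueError("plot_area must be > 0")
        if self.plot_area >= self.total_area:
            raise ValueError("plot_area must be smaller than total_area")
        if self.reliability_index <= 0:
            raise ValueError("reliability_index must be > 0")
        if self.error_bound <= 0:
            raise ValueError("error_bound must be > 0")

    @property
    def population(self) -> float:
        """Sampling population N = total_area / plot_area."""
        return self.total_area / self.plot_area


def _check_strata(strata: Sequence[Stratum]) -> None:
    if not strata:
        raise ValueError("at least one stratum is required")
    total_w = sum(s.area_weight for s in strata)
    if abs(total_w - 1.0) > 1e-9:
        warnings.warn(
            f"stratum area weights sum to {total_w:.6g}, not 1",
            stacklevel=3,
        )


def _weighted_variance(strata: Sequence[Stratum]) -> float:
    return sum(s.area_weight * s.stock_sd**2 for s in strata)


def required_plot_count(
    strata: Sequence[Stratum], config: SamplingConfig
) -> int:
    """Number of monitoring plots under the finite-population formula.

    Returns the ceiling of the raw count; if every stratum has zero
    variance the formula gives 0 and ``config.min_plots`` is returned
    with a warning.
    """
    _check_strata(strata)
    wvar = _weighted_variance(strata)
    if wvar == 0.0:
        warnings.warn(
            "all stratum SDs are zero; returning configured minimum "
            f"({config.min_plots})",
            stacklevel=2,
        )
        return config.min_plots
    n_pop = config.population
    t2 = config.reliability_index**2
    raw = (n_pop * t2 * wvar) / (n_pop * config.error_bound**2 + t2 * wvar)
    return max(math.ceil(raw), config.min_plots)


def required_plot_count_raw(
    strata: Sequence[Stratum], config: SamplingConfig
) -> float:
    """Unrounded value of the finite-population plot-count formula."""
    _check_strata(strata)
    wvar = _weighted_variance(strata)
    n_pop = config.population
    t2 = config.reliability_index**2
    if wvar == 0.0:
        return 0.0
    return (n_pop * t2 * wvar) / (n_pop * config.error_bound**2 + t2 * wvar)


def adjust_plot_count(n: float, population: float) -> int:
    """Finite-population second-pass adjustment n_a = n / (1 + n/N).

    Always <= n. ``population`` is the sampling population N.
    """
    if n <= 0:
        raise ValueError("n must be > 0")
    if population <= 0:
        raise ValueError("population must be > 0")
    return math.ceil(n / (1.0 + n / population))


def simplified_plot_count(
    strata: Sequence[Stratum],
    reliability_index: float = T_90,
    error_bound: float = 5.0,
) -> int:
    """Simplified plot count (t/E)^2 * sum(W_i S_i^2).

    Valid when the sampled fraction is small (plot area below ~5% of the
    project); exactly the N->inf limit of :func:`required_plot_count`.
    """
    _check_strata(strata)
    if error_bound <= 0:
        raise ValueError("error_bound must be > 0")
    if reliability_index <= 0:
        raise ValueError("reliability_index must be > 0")
    raw = (reliability_index / error_bound) ** 2 * _weighted_variance(strata)
    return math.ceil(raw)


def allocate_plots(n: int, strata: Sequence[Stratum]) -> dict[str, int]:
    """Optimal allocation n_i = n * W_i S_i / sum(W_j S_j).

    Uses largest-remainder rounding so the allocation sums to ``n``
    exactly. Strata with zero W*S receive zero plots.
    """
    _check_strata(strata)
    if n < 0:
        raise ValueError("n must be >= 0")
    products = [s.area_weight * s.stock_sd for s in strata]
    total = sum(products)
    if total == 0.0:
        raise ValueError("sum of W_i * S_i is zero; allocation undefined")
    n_active = sum(1 for p in products if p > 0)
    if 0 < n < n_active:
        warnings.warn(
            f"n={n} is below the number of non-degenerate strata "
            f"({n_active}); some strata receive no plot",
            stacklevel=2,
        )
    quotas = [n * p / total for p in products]
    floors = [math.floor(q) for q in quotas]
    shortfall = n - sum(floors)
    # distribute remaining plots to the largest fractional remainders;
    # ties broken by stratum order for determinism
    order = sorted(
        range(len(strata)), key=lambda i: (quotas[i] - floors[i]), reverse=True
    )
    for i in order[:shortfall]:
        floors[i] += 1
    return {s.stratum_id: c for s, c in zip(strata, floors)}


def error_bound_from_relative(
    strata: Sequence[Stratum],
    mean_stock: float,
    relative_precision: float = 0.10,
) -> float:
    """Absolute error bound E implied by a relative precision target.

    Convenience helper: E = relative_precision * mean_stock, where
    ``mean_stock`` is the stratum-weighted mean carbon stock (t/hm2).
    """
    _check_strata(strata)
    if mean_stock <= 0:
        raise ValueError("mean_stock must be > 0")
    if not (0 < relative_precision <= 1):
        raise ValueError("relative_precision must be in (0, 1]")
    return relative_precision * mean_stock
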