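"""Prediction-error statistics for model verification.

Given per-age (predicted, observed) stand carbon pairs, recompute absolute
errors |p - o| (t/hm2) and relative errors 100*|p - o|/o (%), then
summarize with the mean relative error and the absolute-error range. The
denominator of the relative error is always the observed value. Errors are
always recomputed from the predicted/observed pairs, never read from
pre-printed error columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "PredictionRow",
    "ErrorSummary",
    "absolute_error",
    "relative_error",
    "error_summary",
    "rows_from_frame",
]


@dataclass(frozen=True)
class PredictionRow:
    """One validation row: stand age plus predicted/observed carbon."""

    age: float
    predicted: float  # t/hm2
    observed: float  # t/hm2
    mean_dbh: float | None = None  # cm
    mean_height: float | None = None  # m

    def __post_init__(self) -> None:
        if self.predicted <= 0 or self.observed <= 0:
            raise ValueError(
                f"age {self.age}: predicted and observed must be > 0"
            )


@dataclass(frozen=True)
class ErrorSummary:
    """Per-row errors plus their summary statistics."""

    per_row: tuple[tuple[float, float], ...]  # (absolute t/hm2, relative %)
    mean_relative: float  # %
    min_absolute: float  # t/hm2
    max_absolute: float  # t/hm2

    def as_dict(self) -> dict:
        return {
            "per_row": [
                {"absolute_t_hm2": a, "relative_pct": r}
                for a, r in self.per_row
            ],
            "mean_relative_pct": self.mean_relative,
            "min_absolute_t_hm2": self.min_absolute,
            "max_absolute_t_hm2": self.max_absolute,
        }


def absolute_error(predicted: float, observed: float) -> float:
    """|predicted - observed|, same units as the inputs."""
    return abs(predicted - observed)


def relative_error(predicted: float, observed: float) -> float:
    """100 * |predicted - observed| / observed, in percent."""
    if observed <= 0:
        raise ValueError("observed must be > 0")
    return 100.0 * abs(predicted - observed) / observed


def error_summary(rows: Sequence[PredictionRow]) -> ErrorSummary:
    """Summary of recomputed errors over all validation rows."""
    if not rows:
        raise ValueError("rows must be non-empty")
    per_row = tuple(
        (absolute_error(r.predicted, r.observed),
         relative_error(r.predicted, r.observed))
        for r in rows
    )
    abs_errors = [a for a, _ in per_row]
    rel_errors = [r for _, r in per_row]
    return ErrorSummary(
        per_row=per_row,
        mean_relative=sum(rel_errors) / len(rel_errors),
        min_absolute=min(abs_errors),
        max_absolute=max(abs_errors),
    )


def rows_from_frame(df: pd.DataFrame) -> list[PredictionRow]:
    """Build PredictionRows from a validation table.

    Accepts the packaged fixture schema (``predicted_t_hm2`` /
    ``observed_t_hm2``) or plain ``predicted`` / ``observed`` columns.
    """
    cols = set(df.columns)
    if {"predicted_t_hm2", "observed_t_hm2"} <= cols:
        pcol, ocol = "predicted_t_hm2", "observed_t_hm2"
    elif {"predicted", "observed"} <= cols:
        pcol, ocol = "predicted", "observed"
    else:
        raise ValueError("table lacks predicted/observed columns")
    return [
        PredictionRow(
            age=float(r["age"]),
            predicted=float(r[pcol]),
            observed=float(r[ocol]),
            mean_dbh=float(r["mean_dbh_cm"]) if "mean_dbh_cm" in cols else None,
            mean_height=(
                float(r["mean_height_m"]) if "mean_height_m" in cols else None
            ),
        )
        for _, r in df.iterrows()
    ]
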