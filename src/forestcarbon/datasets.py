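"""Packaged reference tables.

Small CSV fixtures shipped with the package: the Chinese-fir validation
table (per-age predicted vs observed stand carbon), the per-plot standing
and living wood volume tables, the plot volume summaries and the plot
carbon-sink comparison values. All loaders return pandas DataFrames.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

_PKG = "forestcarbon.data"


def _load(name: str) -> pd.DataFrame:
    with resources.files(_PKG).joinpath(name).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh)


def load_fir_validation() -> pd.DataFrame:
    """Per-age validation table for Chinese fir stands.

    Columns: ``age``, ``mean_dbh_cm``, ``mean_height_m``,
    ``predicted_t_hm2``, ``observed_t_hm2`` plus the printed error columns
    (kept for regression tests; recompute errors from predicted/observed).
    """
    return _load("table2_fir_validation.csv")


def load_standing_volume(plot: int) -> pd.DataFrame:
    """Standing-timber volume/count table for plot 1 or 2."""
    if plot == 1:
        return _load("table3_plot1_standing.csv")
    if plot == 2:
        return _load("table5_plot2_standing.csv")
    raise ValueError(f"no standing-volume table for plot {plot!r}")


def load_living_volume(plot: int) -> pd.DataFrame:
    """Living (surviving) wood volume/count table for plot 1 or 2."""
    if plot == 1:
        return _load("table4_plot1_living.csv")
    if plot == 2:
        return _load("table6_plot2_living.csv")
    raise ValueError(f"no living-volume table for plot {plot!r}")


def load_plot_summaries() -> pd.DataFrame:
    """Per-plot totals: forest stock, surviving volume, volume density."""
    return _load("table7_plot_summaries.csv")


def load_plot_carbon_sink() -> pd.DataFrame:
    """Measured vs model carbon-sink values for the monitoring plots."""
    return _load("plot_carbon_sink.csv")
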