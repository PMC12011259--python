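"""Inventory ingestion: unify, splice, and clean tree tally tables.

Input tables are UTF-8 CSV with a header row (one row per measured stem).
Field names may vary between sources; a column-mapping dict renames them
onto the canonical schema. Units are fixed at ingestion: DBH in cm, height
in m, biomass in kg, region codes 0-5.

Cleaning drops stems with no biomass information at all, drops stems whose
total biomass deviates from a reference allometric prediction by more than
a relative tolerance, and imputes a single missing organ from the recorded
total. Every action is tallied in a CleaningReport.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .biomass_models import AllometricModel

__all__ = [
    "TreeRecord",
    "PlotInventory",
    "CleaningReport",
    "DEFAULT_SYNONYMS",
    "normalize_species",
    "splice_tables",
    "clean_records",
    "diff_tables",
    "read_tree_table",
    "read_plot_metadata",
    "records_to_frame",
]

ORGANS = ("stem", "branch", "leaf", "root")

#: Common-name aliases for the species handled out of the box. Chinese fir
#: goes by several regional trade names; all fold to the botanical name.
DEFAULT_SYNONYMS: dict[str, str] = {
    "sand wood": "Cunninghamia lanceolata",
    "sand tree": "Cunninghamia lanceolata",
    "thorn fir": "Cunninghamia lanceolata",
    "cedar": "Cunninghamia lanceolata",
    "chinese fir": "Cunninghamia lanceolata",
    "cunninghamia lanceolata": "Cunninghamia lanceolata",
}


@dataclass
class TreeRecord:
    """One measured stem after unit unification."""

    tree_id: str
    species_raw: str
    species_canonical: str
    dbh: float  # cm
    height: float  # m
    age: float  # years
    region_code: int
    biomass_total: float | None = None  # kg
    biomass_by_organ: dict[str, float] | None = None  # organ -> kg
    alive: bool = True

    def __post_init__(self) -> None:
        import math

        for name, v in (("dbh", self.dbh), ("height", self.height)):
            if not math.isfinite(v) or v <= 0:
                raise ValueError(
                    f"tree {self.tree_id!r}: {name} must be finite and > 0"
                )
        if self.age < 0:
            raise ValueError(f"tree {self.tree_id!r}: age must be >= 0")
        if self.region_code not in range(6):
            raise ValueError(
                f"tree {self.tree_id!r}: region_code {self.region_code} "
                "not in 0..5"
            )
        if self.biomass_total is not None and self.biomass_total < 0:
            raise ValueError(f"tree {self.tree_id!r}: biomass_total < 0")
        if self.biomass_total is not None and self.biomass_by_organ:
            organ_sum = sum(self.biomass_by_organ.values())
            if len(self.biomass_by_organ) >= len(ORGANS) and organ_sum > 0:
                rel = abs(self.biomass_total - organ_sum) / organ_sum
                if rel > 1e-6:
                    raise ValueError(
                        f"tree {self.tree_id!r}: organ sum {organ_sum:.6g} "
                        f"!= total {self.biomass_total:.6g}"
                    )


@dataclass
class PlotInventory:
    """A monitoring plot: area (hm2), stratum, year and its stems."""

    plot_id: str
    area: float
    stratum_id: str
    trees: list[TreeRecord] = field(default_factory=list)
    year: int = 0

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError(f"plot {self.plot_id!r}: area must be > 0")
        regions = {t.region_code for t in self.trees}
        if len(regions) > 1:
            warnings.warn(
                f"plot {self.plot_id!r} mixes region codes {sorted(regions)}",
                stacklevel=2,
            )

    @property
    def n_trees(self) -> int:
        return len(self.trees)


@dataclass
class CleaningReport:
    """Tally of cleaning actions; input = output + drops always holds."""

    n_input: int = 0
    n_dropped_missing_biomass: int = 0
    n_dropped_outlier: int = 0
    n_imputed_organ: int = 0
    messages: list[str] = field(default_factory=list)

    @property
    def n_output(self) -> int:
        return (
            self.n_input
            - self.n_dropped_missing_biomass
            - self.n_dropped_outlier
        )

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_output": self.n_output,
            "n_dropped_missing_biomass": self.n_dropped_missing_biomass,
            "n_dropped_outlier": self.n_dropped_outlier,
            "n_imputed_organ": self.n_imputed_organ,
            "messages": list(self.messages),
        }


def normalize_species(
    name_raw: str,
    synonym_table: Mapping[str, str] | None = None,
) -> tuple[str, bool]:
    """Fold a raw species name to its canonical botanical name.

    Lookup is on the lowercased, whitespace-trimmed alias. Returns
    ``(canonical_name, known)``; unknown names come back unchanged
    (stripped) with ``known=False`` and a warning so the decision is
    auditable.
    """
    if not name_raw or not name_raw.strip():
        raise ValueError("species name is empty")
    table = DEFAULT_SYNONYMS if synonym_table is None else synonym_table
    key = " ".join(name_raw.strip().lower().split())
    if key in table:
        return table[key], True
    warnings.warn(
        f"species {name_raw.strip()!r} not in synonym table; kept as-is",
        stacklevel=2,
    )
    return name_raw.strip(), False


def splice_tables(
    tables: Sequence[pd.DataFrame],
    source_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Merge tree-record tables into one, outer-unioning their columns.

    Row count is conserved; a ``source_table`` column records provenance.
    Shared fields must agree on kind (numeric vs not) or a ValueError
    names the offending field.
    """
    if source_names is None:
        source_names = [f"table_{i}" for i in range(len(tables))]
    if len(source_names) != len(tables):
        raise ValueError("source_names must match number of tables")
    if not tables:
        return pd.DataFrame(columns=["source_table"])

    kinds: dict[str, bool] = {}
    for name, tbl in zip(source_names, tables):
        for col in tbl.columns:
            numeric = pd.api.types.is_numeric_dtype(tbl[col])
            if col in kinds and kinds[col] != numeric and len(tbl) > 0:
                raise ValueError(
                    f"field {col!r} has conflicting types across tables "
                    f"(numeric vs non-numeric at {name!r})"
                )
            if len(tbl) > 0:
                kinds[col] = numeric

    tagged = []
    for name, tbl in zip(source_names, tables):
        t = tbl.copy()
        t["source_table"] = name
        tagged.append(t)
    merged = pd.concat(tagged, ignore_index=True, sort=False)
    # canonical column order: first-seen order, provenance last
    cols = [c for c in merged.columns if c != "source_table"]
    return merged[cols + ["source_table"]]


def clean_records(
    records: Iterable[TreeRecord],
    reference_model: AllometricModel,
    tolerance: float = 0.5,
) -> tuple[list[TreeRecord], CleaningReport]:
    """Apply the cleaning rules and return survivors plus a report.

    Rules, in order per record:

    1. no ``biomass_total`` and no organ masses -> dropped;
    2. exactly one organ missing while the total is present -> the organ
       is imputed as total minus the others;
    3. total present but no organs -> relative deviation from the
       reference allometric prediction above ``tolerance`` -> dropped.
    """
    if tolerance <= 0 or tolerance > 1:
        raise ValueError("tolerance must be in (0, 1]")
    report = CleaningReport()
    kept: list[TreeRecord] = []
    for rec in records:
        report.n_input += 1
        organs = rec.biomass_by_organ or {}
        if rec.biomass_total is None and not organs:
            report.n_dropped_missing_biomass += 1
            report.messages.append(
                f"dropped {rec.tree_id}: biomass missing entirely"
            )
            continue
        if rec.biomass_total is not None and organs:
            missing = [o for o in ORGANS if o not in organs]
            if len(missing) == 1:
                imputed = rec.biomass_total - sum(organs.values())
                if imputed >= 0:
                    organs = {**organs, missing[0]: imputed}
                    rec = TreeRecord(
                        tree_id=rec.tree_id,
                        species_raw=rec.species_raw,
                        species_canonical=rec.species_canonical,
                        dbh=rec.dbh,
                        height=rec.height,
                        age=rec.age,
                        region_code=rec.region_code,
                        biomass_total=rec.biomass_total,
                        biomass_by_organ=organs,
                        alive=rec.alive,
                    )
                    report.n_imputed_organ += 1
                    report.messages.append(
                        f"imputed {missing[0]} for {rec.tree_id}"
                    )
        total = (
            rec.biomass_total
            if rec.biomass_total is not None
            else sum(organs.values())
        )
        expected = float(reference_model.predict(rec.dbh))
        if expected > 0:
            rel_dev = abs(total - expected) / expected
            if rel_dev > tolerance:
                report.n_dropped_outlier += 1
                report.messages.append(
                    f"dropped {rec.tree_id}: biomass {total:.6g} deviates "
                    f"{rel_dev:.2%} from reference {expected:.6g}"
                )
                continue
        kept.append(rec)
    return kept, report


def diff_tables(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Cell-level diff of two same-shaped tables (dual-entry check).

    Returns a long-format frame (row, column, value_a, value_b) of
    mismatching cells; empty means the two entries agree.
    """
    if a.shape != b.shape or list(a.columns) != list(b.columns):
        raise ValueError("tables must have identical shape and columns")
    rows = []
    for col in a.columns:
        sa, sb = a[col].reset_index(drop=True), b[col].reset_index(drop=True)
        neq = ~((sa == sb) | (sa.isna() & sb.isna()))
        for idx in sa.index[neq]:
            rows.append(
                {"row": int(idx), "column": col,
                 "value_a": sa[idx], "value_b": sb[idx]}
            )
    return pd.DataFrame(rows, columns=["row", "column", "value_a", "value_b"])


DEFAULT_COLUMNS = {
    "tree_id": "tree_id",
    "species": "species",
    "dbh_cm": "dbh_cm",
    "height_m": "height_m",
    "age_a": "age_a",
    "region": "region",
    "biomass_kg": "biomass_kg",
}


def read_tree_table(
    path,
    column_map: Mapping[str, str] | None = None,
    synonym_table: Mapping[str, str] | None = None,
) -> list[TreeRecord]:
    """Read a tree tally CSV into TreeRecord objects.

    ``column_map`` maps canonical field -> actual column name in the file,
    for sources whose headers differ from the default schema. Organ
    columns ``stem_kg``/``branch_kg``/``leaf_kg``/``root_kg`` are optional.
    """
    df = pd.read_csv(path)
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    missing = [v for k, v in cmap.items() if k != "biomass_kg" and v not in df.columns]
    if missing:
        raise ValueError(f"tree table missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        raw = str(row[cmap["species"]])
        canonical, _known = normalize_species(raw, synonym_table)
        organs = {}
        for organ in ORGANS:
            col = f"{organ}_kg"
            if col in df.columns and pd.notna(row[col]):
                organs[organ] = float(row[col])
        total = None
        if cmap["biomass_kg"] in df.columns and pd.notna(row[cmap["biomass_kg"]]):
            total = float(row[cmap["biomass_kg"]])
        records.append(
            TreeRecord(
                tree_id=str(row[cmap["tree_id"]]),
                species_raw=raw,
                species_canonical=canonical,
                dbh=float(row[cmap["dbh_cm"]]),
                height=float(row[cmap["height_m"]]),
                age=float(row[cmap["age_a"]]),
                region_code=int(row[cmap["region"]]),
                biomass_total=total,
                biomass_by_organ=organs or None,
            )
        )
    return records


def read_plot_metadata(path) -> pd.DataFrame:
    """Read plot metadata CSV (plot_id, area_hm2, stratum, year)."""
    df = pd.read_csv(path)
    required = {"plot_id", "area_hm2", "stratum", "year"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plot metadata missing columns: {sorted(missing)}")
    if (df["area_hm2"] <= 0).any():
        raise ValueError("plot areas must be > 0")
    return df


def records_to_frame(records: Iterable[TreeRecord]) -> pd.DataFrame:
    """Flatten TreeRecords to the canonical tabular schema."""
    rows = []
    for r in records:
        row = {
            "tree_id": r.tree_id,
            "species": r.species_canonical,
            "dbh_cm": r.dbh,
            "height_m": r.height,
            "age_a": r.age,
            "region": r.region_code,
            "biomass_kg": r.biomass_total,
            "alive": r.alive,
        }
        for organ in ORGANS:
            row[f"{organ}_kg"] = (r.biomass_by_organ or {}).get(organ)
        rows.append(row)
    return pd.DataFrame(rows)
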