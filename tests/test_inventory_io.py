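import numpy as np
import pandas as pd
import pytest

from forestcarbon.biomass_models import AllometricModel
from forestcarbon.inventory_io import (
    CleaningReport,
    PlotInventory,
    TreeRecord,
    clean_records,
    diff_tables,
    normalize_species,
    read_plot_metadata,
    read_tree_table,
    records_to_frame,
    splice_tables,
)


def make_tree(tree_id="t1", dbh=10.0, biomass=None, organs=None, **kwargs):
    return TreeRecord(
        tree_id=tree_id,
        species_raw="cedar",
        species_canonical="Cunninghamia lanceolata",
        dbh=dbh,
        height=kwargs.pop("height", 8.0),
        age=kwargs.pop("age", 10.0),
        region_code=kwargs.pop("region_code", 0),
        biomass_total=biomass,
        biomass_by_organ=organs,
        **kwargs,
    )


class TestNormalizeSpecies:
    @pytest.mark.parametrize(
        "alias",
        ["sand wood", "sand tree", "thorn fir", "cedar"],
    )
    def test_known_aliases(self, alias):
        name, known = normalize_species(alias)
        assert name == "Cunninghamia lanceolata"
        assert known

    def test_identity_on_canonical(self):
        name, known = normalize_species("Cunninghamia lanceolata")
        assert name == "Cunninghamia lanceolata"
        assert known

    def test_case_and_whitespace_folding(self):
        name, known = normalize_species("  CEDAR ")
        assert name == "Cunninghamia lanceolata"
        assert known

    def test_unknown_kept_with_warning(self):
        with pytest.warns(UserWarning, match="not in synonym table"):
            name, known = normalize_species("mystery oak")
        assert name == "mystery oak"
        assert not known

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            normalize_species("   ")

    def test_custom_table(self):
        name, known = normalize_species("mao zhu", {"mao zhu": "Phyllostachys edulis"})
        assert name == "Phyllostachys edulis"
        assert known


class TestSpliceTables:
    def test_row_count_conserved(self):
        a = pd.DataFrame({"id": [1, 2, 3], "dbh": [10.0, 11.0, 12.0]})
        b = pd.DataFrame({"id": [4, 5, 6, 7], "dbh": [9.0, 8.0, 7.0, 6.0]})
        merged = splice_tables([a, b])
        assert len(merged) == 7

    def test_outer_union_of_columns(self):
        a = pd.DataFrame({"id": [1], "dbh": [10.0]})
        b = pd.DataFrame({"id": [2], "dbh": [11.0], "height": [8.0]})
        merged = splice_tables([a, b], ["src_a", "src_b"])
        assert list(merged.columns) == ["id", "dbh", "height", "source_table"]
        assert merged["height"].isna().tolist() == [True, False]
        assert merged["source_table"].tolist() == ["src_a", "src_b"]

    def test_empty_list(self):
        merged = splice_tables([])
        assert len(merged) == 0

    def test_conflicting_types_named(self):
        a = pd.DataFrame({"id": [1], "dbh": [10.0]})
        b = pd.DataFrame({"id": [2], "dbh": ["ten"]})
        with pytest.raises(ValueError, match="dbh"):
            splice_tables([a, b])


class TestCleanRecords:
    REF = AllometricModel(a=1.0, b=2.0)  # predicts 100 kg at D=10

    def test_missing_biomass_dropped(self):
        kept, report = clean_records([make_tree(biomass=None)], self.REF)
        assert kept == []
        assert report.n_dropped_missing_biomass == 1

    def test_exact_prediction_retained(self):
        kept, report = clean_records([make_tree(biomass=100.0)], self.REF)
        assert len(kept) == 1
        assert report.n_dropped_outlier == 0

    def test_outlier_dropped(self):
        # deviation |200-100|/100 = 1.0 > 0.5
        kept, report = clean_records(
            [make_tree(biomass=200.0)], self.REF, tolerance=0.5
        )
        assert kept == []
        assert report.n_dropped_outlier == 1

    def test_within_tolerance_retained(self):
        kept, _ = clean_records(
            [make_tree(biomass=140.0)], self.REF, tolerance=0.5
        )
        assert len(kept) == 1

    def test_single_missing_organ_imputed(self):
        organs = {"stem": 60.0, "branch": 20.0, "leaf": 10.0}  # root missing
        kept, report = clean_records(
            [make_tree(biomass=100.0, organs=organs)], self.REF
        )
        assert report.n_imputed_organ == 1
        assert kept[0].biomass_by_organ["root"] == pytest.approx(10.0)

    def test_row_conservation_invariant(self):
        records = [
            make_tree("a", biomass=100.0),
            make_tree("b", biomass=None),
            make_tree("c", biomass=500.0),
            make_tree("d", biomass=90.0),
        ]
        kept, report = clean_records(records, self.REF, tolerance=0.5)
        assert report.n_input == 4
        assert (
            report.n_input
            == len(kept)
            + report.n_dropped_missing_biomass
            + report.n_dropped_outlier
        )
        assert report.n_output == len(kept)

    def test_idempotence(self):
        records = [make_tree("a", biomass=100.0), make_tree("b", biomass=95.0)]
        kept1, _ = clean_records(records, self.REF)
        kept2, report2 = clean_records(kept1, self.REF)
        assert len(kept2) == len(kept1)
        assert report2.n_dropped_missing_biomass == 0
        assert report2.n_dropped_outlier == 0

    def test_bad_tolerance(self):
        with pytest.raises(ValueError):
            clean_records([], self.REF, tolerance=0.0)
        with pytest.raises(ValueError):
            clean_records([], self.REF, tolerance=-0.1)


class TestTreeRecordValidation:
    def test_positive_measurements_required(self):
        with pytest.raises(ValueError):
            make_tree(dbh=0.0)
        with pytest.raises(ValueError):
            make_tree(dbh=float("nan"))
        with pytest.raises(ValueError):
            make_tree(height=-1.0)

    def test_region_code_range(self):
        for code in range(6):
            make_tree(region_code=code)
        with pytest.raises(ValueError):
            make_tree(region_code=6)

    def test_organ_sum_consistency(self):
        organs = {"stem": 50.0, "branch": 30.0, "leaf": 10.0, "root": 10.0}
        make_tree(biomass=100.0, organs=organs)  # consistent
        with pytest.raises(ValueError, match="organ sum"):
            make_tree(biomass=150.0, organs=organs)


class TestPlotInventory:
    def test_mixed_regions_warn(self):
        trees = [make_tree("a", region_code=0), make_tree("b", region_code=1)]
        with pytest.warns(UserWarning, match="region"):
            PlotInventory("p1", area=0.08, stratum_id="s1", trees=trees)

    def test_area_positive(self):
        with pytest.raises(ValueError):
            PlotInventory("p1", area=0.0, stratum_id="s1")


class TestDiffTables:
    def test_identical_tables_empty_diff(self):
        a = pd.DataFrame({"x": [1, 2], "y": ["u", "v"]})
        assert diff_tables(a, a.copy()).empty

    def test_mismatch_located(self):
        a = pd.DataFrame({"x": [1, 2]})
        b = pd.DataFrame({"x": [1, 3]})
        diff = diff_tables(a, b)
        assert len(diff) == 1
        assert diff.iloc[0]["row"] == 1
        assert diff.iloc[0]["column"] == "x"

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            diff_tables(pd.DataFrame({"x": [1]}), pd.DataFrame({"y": [1]}))


class TestCsvIngestion:
    def test_tree_table_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {
                "tree_id": ["t1", "t2"],
                "species": ["cedar", "sand wood"],
                "dbh_cm": [10.0, 12.0],
                "height_m": [8.0, 9.0],
                "age_a": [10, 12],
                "region": [0, 0],
                "biomass_kg": [95.0, 140.0],
            }
        )
        path = tmp_path / "trees.csv"
        df.to_csv(path, index=False)
        records = read_tree_table(path)
        assert len(records) == 2
        assert all(
            r.species_canonical == "Cunninghamia lanceolata" for r in records
        )
        out = records_to_frame(records)
        np.testing.assert_allclose(out["dbh_cm"], df["dbh_cm"])
        np.testing.assert_allclose(out["height_m"], df["height_m"])
        np.testing.assert_allclose(out["biomass_kg"], df["biomass_kg"])

    def test_column_mapping(self, tmp_path):
        df = pd.DataFrame(
            {
                "stem_no": ["t1"],
                "sp": ["cedar"],
                "D": [10.0],
                "H": [8.0],
                "age_a": [10],
                "region": [0],
            }
        )
        path = tmp_path / "alt.csv"
        df.to_csv(path, index=False)
        records = read_tree_table(
            path,
            column_map={
                "tree_id": "stem_no",
                "species": "sp",
                "dbh_cm": "D",
                "height_m": "H",
            },
        )
        assert records[0].dbh == 10.0
        assert records[0].biomass_total is None

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"tree_id": ["t1"]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="missing columns"):
            read_tree_table(path)

    def test_plot_metadata(self, tmp_path):
        path = tmp_path / "plots.csv"
        pd.DataFrame(
            {
                "plot_id": ["p1"],
                "area_hm2": [0.08],
                "stratum": ["s1"],
                "year": [2024],
            }
        ).to_csv(path, index=False)
        meta = read_plot_metadata(path)
        assert meta.iloc[0]["area_hm2"] == 0.08
        pd.DataFrame(
            {"plot_id": ["p1"], "area_hm2": [0.0], "stratum": ["s1"], "year": [2024]}
        ).to_csv(path, index=False)
        with pytest.raises(ValueError):
            read_plot_metadata(path)


def test_cleaning_report_counts():
    r = CleaningReport(n_input=10, n_dropped_missing_biomass=2, n_dropped_outlier=3)
    assert r.n_output == 5
    assert r.as_dict()["n_output"] == 5
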