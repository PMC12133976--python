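"""Reading, validation and cleaning of the capture dialect."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from perohr import neon_io
from conftest import make_captures

HEADER = ("siteID,plotID,trapCoordinate,collectDate,tagID,taxonID,sex,"
          "pregnancyStatus,lifeStage,weight,hindfootLength,nlcdClass,"
          "decimalLatitude")


def write_csv(tmp_path, rows):
    p = tmp_path / "captures.csv"
    p.write_text("\n".join([HEADER] + rows) + "\n")
    return p


ROW = "S00,S00_P1,{trap},2020-06-01,{tag},Peromyscus leucopus,F,nonpregnant,adult,{mass},19.5,deciduousForest,38.0"


class TestReadCaptures:
    def test_reads_one_record_per_row(self, tmp_path):
        p = write_csv(tmp_path, [ROW.format(trap="A1", tag=f"t{i}", mass=20)
                                 for i in range(3)])
        df = neon_io.read_captures(p)
        assert len(df) == 3
        assert list(df.columns) == neon_io.COLUMNS

    def test_na_mass_becomes_missing_not_zero(self, tmp_path):
        p = write_csv(tmp_path, [ROW.format(trap="A1", tag="t0", mass="NA")])
        df = neon_io.read_captures(p)
        assert np.isnan(df.loc[0, "mass_g"])

    def test_invalid_trap_coordinate_excluded_with_warning(self, tmp_path, caplog):
        p = write_csv(tmp_path, [ROW.format(trap="K3", tag="t0", mass=20),
                                 ROW.format(trap="B2", tag="t1", mass=20)])
        with caplog.at_level(logging.WARNING, logger="perohr.neon_io"):
            df = neon_io.read_captures(p)
        assert len(df) == 1 and df.loc[0, "tag_id"] == "t1"
        assert "K3" in caplog.text

    def test_missing_column_raises_naming_it(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("siteID,plotID\nS00,S00_P1\n")
        with pytest.raises(neon_io.ColumnError, match="trapCoordinate"):
            neon_io.read_captures(p)

    def test_empty_file_distinct_error(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text(HEADER + "\n")
        with pytest.raises(neon_io.EmptyInputError):
            neon_io.read_captures(p)

    def test_round_trip_preserves_every_field(self, tmp_path):
        df = make_captures([
            ("t0", "2020-06-01", "A1", "F", "nonpregnant", 20.5, 19.5),
            ("t1", "2020-06-02", "J10", "M", np.nan, np.nan, np.nan),
        ])
        out = tmp_path / "rt.csv"
        neon_io.write_captures(df, out)
        back = neon_io.read_captures(
            out, column_map={c: c for c in neon_io.COLUMNS})
        pd.testing.assert_frame_equal(back, df.reset_index(drop=True),
                                      check_dtype=False)


class TestTrapToXY:
    @pytest.mark.parametrize("coord,expected", [
        ("A1", (0.0, 0.0)),
        ("J10", (90.0, 90.0)),
        ("E5", (40.0, 40.0)),
    ])
    def test_known_positions(self, coord, expected):
        assert neon_io.trap_to_xy(coord) == expected

    def test_injective_on_the_lattice(self):
        coords = [f"{letter}{num}" for letter in "ABCDEFGHIJ"
                  for num in range(1, 11)]
        points = {neon_io.trap_to_xy(c) for c in coords}
        assert len(points) == 100
        assert all(x % 10 == 0 and y % 10 == 0 and 0 <= x <= 90 and 0 <= y <= 90
                   for x, y in points)

    @pytest.mark.parametrize("bad", ["K3", "A0", "A11", "5E", "", "AA1"])
    def test_malformed_raises(self, bad):
        with pytest.raises(ValueError):
            neon_io.trap_to_xy(bad)


class TestFilterTaxa:
    def test_keeps_only_nonmonogamous_peromyscus(self):
        df = make_captures([(f"t{i}", "2020-06-01", "A1", "F", np.nan, 20, 19)
                            for i in range(3)])
        df["taxon"] = ["Peromyscus leucopus", "Peromyscus californicus",
                       "Microtus pennsylvanicus"]
        out = neon_io.filter_taxa(df)
        assert list(out["taxon"]) == ["Peromyscus leucopus"]

    @pytest.mark.parametrize("taxon,kept", [
        ("Peromyscus eremicus", False),
        ("Peromyscus polionotus", False),
        ("Peromyscus leucopus/maniculatus", True),
        ("Peromyscus sp.", True),
        ("Peromyscus gossypinus/leucopus", True),
    ])
    def test_species_rules(self, taxon, kept):
        df = make_captures([("t0", "2020-06-01", "A1", "F", np.nan, 20, 19)])
        df["taxon"] = taxon
        assert (len(neon_io.filter_taxa(df)) == 1) is kept

    @given(st.lists(st.sampled_from([
        "Peromyscus leucopus", "Peromyscus maniculatus", "Peromyscus eremicus",
        "Microtus pennsylvanicus", "Peromyscus sp."]), min_size=0, max_size=12))
    def test_never_increases_count(self, taxa):
        df = make_captures([(f"t{i}", "2020-06-01", "A1", "F", np.nan, 20, 19)
                            for i in range(len(taxa))])
        if len(df):
            df["taxon"] = taxa
        else:
            df = df.reindex(columns=neon_io.COLUMNS)
        assert len(neon_io.filter_taxa(df)) <= len(taxa)


class TestOutlierRules:
    def test_heavy_mass_set_missing_record_kept(self):
        df = make_captures([("t0", "2020-06-01", "A1", "F", np.nan, 52.0, 19.5),
                            ("t0", "2020-06-02", "A2", "F", np.nan, 20.0, 19.5)])
        out = neon_io.apply_outlier_rules(df)
        assert len(out) == 2
        assert np.isnan(out.loc[0, "mass_g"]) and out.loc[1, "mass_g"] == 20.0

    def test_long_hindfoot_set_missing(self):
        df = make_captures([("t0", "2020-06-01", "A1", "F", np.nan, 20.0, 29.0),
                            ("t0", "2020-06-02", "A2", "F", np.nan, 20.0, 19.0)])
        out = neon_io.apply_outlier_rules(df)
        assert np.isnan(out.loc[0, "hindfoot_mm"])
        assert out.loc[1, "hindfoot_mm"] == 19.0

    def test_alternating_pregnancy_individual_removed(self):
        df = make_captures([
            ("t0", "2020-06-01", "A1", "F", "pregnant", 20, 19),
            ("t0", "2020-06-02", "A1", "F", "nonpregnant", 20, 19),
            ("t0", "2020-06-03", "A1", "F", "pregnant", 20, 19),
            ("t1", "2020-06-01", "B1", "F", "pregnant", 20, 19),
        ])
        out = neon_io.apply_outlier_rules(df)
        assert set(out["tag_id"]) == {"t1"}

    def test_only_implausibly_light_masses_removes_individual(self):
        df = make_captures([("t0", "2020-06-01", "A1", "M", np.nan, 9.0, 17.0),
                            ("t1", "2020-06-01", "A2", "M", np.nan, 22.0, 20.0)])
        out = neon_io.apply_outlier_rules(df)
        assert set(out["tag_id"]) == {"t1"}


class TestHabitat:
    @pytest.mark.parametrize("nlcd,habitat", [
        ("woodyWetlands", "forest"),
        ("deciduousForest", "forest"),
        ("mixedForest", "forest"),
        ("evergreenForest", "forest"),
        ("pastureHay", "grassland"),
        ("grasslandHerbaceous", "grassland"),
        ("cultivatedCrops", "grassland"),
        ("shrubScrub", "shrubland"),
    ])
    def test_total_over_the_eight_classes(self, nlcd, habitat):
        assert neon_io.group_habitat(nlcd) == habitat

    def test_unknown_class_raises_listing_it(self):
        with pytest.raises(neon_io.HabitatError, match="openWater"):
            neon_io.group_habitat("openWater")
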