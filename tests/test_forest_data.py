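import numpy as np
import pandas as pd
import pytest

from cndd.forest_data import (PlotMetadata, build_observations, clean_statuses,
                              classify_growth_form, compute_abundance,
                              consolidate_stems, group_abundance,
                              read_census_tables, read_observations,
                              write_observations)


@pytest.fixture
def plot():
    return PlotMetadata("demo", 300.0, 200.0, 10.0, [2000.0, 2005.0])


def stem_rows(rows):
    cols = ["tree_id", "stem_id", "species", "x", "y", "dbh",
            "status", "census_index", "date"]
    return pd.DataFrame(rows, columns=cols)


class TestPlotMetadata:
    def test_area(self, plot):
        assert plot.area_ha == pytest.approx(6.0)

    def test_invalid_dimensions(self):
        with pytest.raises(ValueError):
            PlotMetadata("x", -1.0, 100.0, 0.0)

    def test_nonincreasing_dates(self):
        with pytest.raises(ValueError):
            PlotMetadata("x", 100.0, 100.0, 0.0, [2005.0, 2000.0])


class TestReadCensusTables:
    def test_missing_coordinates_dropped(self, tmp_path):
        path = tmp_path / "census.csv"
        path.write_text(
            "tree_id,stem_id,species,x,y,dbh,status,census_index,date\n"
            "1,1,spA,10,10,5,alive,1,2000\n"
            "2,2,spA,,10,4,alive,1,2000\n"
            "3,3,spB,20,20,3,dead,1,2000\n"
            "4,4,spB,30,30,2,alive,1,2000\n")
        tables, drops = read_census_tables([path])
        assert len(tables[0]) == 3
        assert drops == [1]

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("tree_id,stem_id,species,x,y,dbh,status,census_index,date\n")
        with pytest.warns(UserWarning):
            tables, drops = read_census_tables([path])
        assert len(tables[0]) == 0

    def test_status_code_mapping(self, tmp_path):
        path = tmp_path / "coded.csv"
        path.write_text("tid,sid,sp,px,py,d,st,ci,dt\n"
                        "1,1,spA,10,10,5,A,1,2000\n"
                        "2,2,spA,11,10,5,D,1,2000\n")
        schema = {"columns": {"tree_id": "tid", "stem_id": "sid", "species": "sp",
                              "x": "px", "y": "py", "dbh": "d", "status": "st",
                              "census_index": "ci", "date": "dt"},
                  "status_codes": {"A": "alive", "D": "dead"}}
        tables, _ = read_census_tables([path], schema)
        assert list(tables[0]["status"]) == ["alive", "dead"]

    def test_unknown_status_fail_mode(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("tree_id,stem_id,species,x,y,dbh,status,census_index,date\n"
                        "1,1,spA,10,10,5,zombie,1,2000\n")
        with pytest.raises(ValueError):
            read_census_tables([path], on_unknown_status="fail")
        tables, drops = read_census_tables([path], on_unknown_status="drop")
        assert len(tables[0]) == 0 and drops == [1]

    def test_unparseable_file_fatal(self, tmp_path):
        path = tmp_path / "nope.csv"
        path.write_bytes(b"\xff\xfe\xfa\x00")
        with pytest.raises(ValueError):
            read_census_tables([path])


class TestConsolidateStems:
    def test_pythagorean_dbh(self, plot):
        stems = stem_rows([[1, 1, "spA", 10, 10, 3.0, "alive", 1, 2000],
                           [1, 2, "spA", 10.5, 10, 4.0, "alive", 1, 2000]])
        out = consolidate_stems(stems, plot)
        assert out["dbh"].iloc[0] == pytest.approx(5.0, rel=1e-12)

    def test_any_alive_means_alive(self, plot):
        stems = stem_rows([[1, 1, "spA", 10, 10, 3.0, "dead", 1, 2000],
                           [1, 2, "spA", 10, 10, 4.0, "alive", 1, 2000]])
        out = consolidate_stems(stems, plot)
        assert out["status"].iloc[0] == "alive"

    def test_single_stem_passthrough(self, plot):
        stems = stem_rows([[1, 1, "spA", 10, 10, 3.0, "alive", 1, 2000]])
        out = consolidate_stems(stems, plot)
        assert out["dbh"].iloc[0] == pytest.approx(3.0)
        assert out["x"].iloc[0] == 10

    def test_main_stem_coordinates(self, plot):
        stems = stem_rows([[1, 1, "spA", 10, 10, 3.0, "alive", 1, 2000],
                           [1, 2, "spA", 99, 99, 8.0, "alive", 1, 2000]])
        out = consolidate_stems(stems, plot)
        assert out["x"].iloc[0] == 99  # largest-DBH living stem

    def test_idempotent_and_preserves_live_basal_area(self, plot):
        stems = stem_rows([[1, 1, "spA", 10, 10, 3.0, "alive", 1, 2000],
                           [1, 2, "spA", 10, 10, 4.0, "alive", 1, 2000],
                           [1, 3, "spA", 10, 10, 6.0, "dead", 1, 2000]])
        once = consolidate_stems(stems, plot)
        live_ba = np.pi * ((3 / 2) ** 2 + (4 / 2) ** 2)
        assert np.pi * (once["dbh"].iloc[0] / 2) ** 2 == pytest.approx(live_ba)
        again = consolidate_stems(once.assign(stem_id=once["tree_id"]), plot)
        assert again["dbh"].iloc[0] == pytest.approx(once["dbh"].iloc[0])

    def test_empty_errors(self, plot):
        with pytest.raises(ValueError):
            consolidate_stems(stem_rows([]), plot)

    def test_stems_as_individuals_passthrough(self):
        plot = PlotMetadata("stemwise", 100.0, 100.0, 3.0, stems_as_individuals=True)
        stems = stem_rows([[1, 1, "spA", 10, 10, 3.0, "alive", 1, 2000],
                           [1, 2, "spA", 10, 10, 4.0, "alive", 1, 2000]])
        out = consolidate_stems(stems, plot)
        assert len(out) == 2
        assert set(out["tree_id"]) == {1, 2}  # stems become individuals


class TestCleanStatuses:
    def tree(self, statuses, species=None):
        n = len(statuses)
        species = species or ["spA"] * n
        return pd.DataFrame({"tree_id": 1, "species": species,
                             "x": 10.0, "y": 10.0, "dbh": 5.0,
                             "status": statuses, "census_index": range(1, n + 1),
                             "date": [2000.0 + 5 * i for i in range(n)]})

    def test_resurrection_rule(self):
        out = clean_statuses(self.tree(["alive", "dead", "alive"]))
        assert list(out["status"]) == ["alive", "alive", "alive"]

    def test_terminal_death_unchanged(self):
        out = clean_statuses(self.tree(["alive", "dead"]))
        assert list(out["status"]) == ["alive", "dead"]

    def test_most_recent_species_wins(self):
        out = clean_statuses(self.tree(["alive", "alive"], species=["spA", "spB"]))
        assert set(out["species"]) == {"spB"}

    def test_never_converts_alive_to_dead(self, rng):
        statuses = rng.choice(["alive", "dead"], 30).tolist()
        out = clean_statuses(self.tree(statuses))
        before = np.array(statuses)
        after = out.sort_values("census_index")["status"].to_numpy()
        assert not ((before == "alive") & (after == "dead")).any()


class TestBuildObservations:
    def trees(self, rows):
        cols = ["tree_id", "species", "x", "y", "dbh", "status", "census_index", "date"]
        return pd.DataFrame(rows, columns=cols)

    def test_inclusion_and_outcome(self, plot):
        t = self.trees([[1, "spA", 100, 100, 9.9, "alive", 1, 2000.0],
                        [1, "spA", 100, 100, 9.9, "dead", 2, 2005.1]])
        obs = build_observations(t, plot)
        assert len(obs) == 1
        assert obs["Y"].iloc[0] == 1
        assert obs["dt"].iloc[0] == pytest.approx(5.1)

    def test_dbh_10_excluded(self, plot):
        t = self.trees([[1, "spA", 100, 100, 10.0, "alive", 1, 2000.0],
                        [1, "spA", 100, 100, 10.2, "alive", 2, 2005.0]])
        assert len(build_observations(t, plot)) == 0

    def test_edge_flag(self, plot):
        t = self.trees([[1, "spA", 12, 100, 5.0, "alive", 1, 2000.0],
                        [1, "spA", 12, 100, 5.5, "alive", 2, 2005.0]])
        obs = build_observations(t, plot)
        assert obs["edge_excluded"].iloc[0]

    def test_interior_not_flagged(self, plot):
        t = self.trees([[1, "spA", 150, 100, 5.0, "alive", 1, 2000.0],
                        [1, "spA", 150, 100, 5.5, "alive", 2, 2005.0]])
        assert not build_observations(t, plot)["edge_excluded"].iloc[0]

    def test_single_census_errors(self, plot):
        t = self.trees([[1, "spA", 100, 100, 5.0, "alive", 1, 2000.0]])
        with pytest.raises(ValueError):
            build_observations(t, plot)

    def test_fern_palm_excluded(self, plot):
        t = self.trees([[1, "fern1", 100, 100, 5.0, "alive", 1, 2000.0],
                        [1, "fern1", 100, 100, 5.5, "alive", 2, 2005.0]])
        assert len(build_observations(t, plot, fern_palm_species={"fern1"})) == 0

    def test_missing_followup_excluded(self, plot):
        t = self.trees([[1, "spA", 100, 100, 5.0, "alive", 1, 2000.0],
                        [1, "spA", 100, 100, np.nan, "missing", 2, 2005.0]])
        assert len(build_observations(t, plot)) == 0

    def test_nonpositive_dt_dropped_with_warning(self, plot):
        t = self.trees([[1, "spA", 100, 100, 5.0, "alive", 1, 2005.0],
                        [1, "spA", 100, 100, 5.5, "alive", 2, 2005.0]])
        with pytest.warns(UserWarning):
            obs = build_observations(t, plot)
        assert len(obs) == 0

    def test_roundtrip_csv(self, plot, tmp_path):
        t = self.trees([[1, "spA", 100, 100, 5.0, "alive", 1, 2000.0],
                        [1, "spA", 100, 100, 5.5, "alive", 2, 2005.0],
                        [2, "spB", 40, 40, 2.0, "alive", 1, 2000.0],
                        [2, "spB", 40, 40, np.nan, "dead", 2, 2005.0]])
        obs = build_observations(t, plot)
        path = tmp_path / "obs.csv"
        write_observations(obs, path)
        back = read_observations(path)
        pd.testing.assert_frame_equal(obs.reset_index(drop=True), back,
                                      check_dtype=False)


class TestGrowthForm:
    def trees_of(self, dbhs, census=1):
        return pd.DataFrame({"tree_id": range(len(dbhs)), "species": "spA",
                             "dbh": dbhs, "status": "alive",
                             "census_index": census})

    def test_six_largest_mean_above_10(self):
        t = self.trees_of([12.0] * 6 + [1.0] * 10)
        assert classify_growth_form(t)["spA"] == "tree"

    def test_fewer_than_six_uses_all(self):
        t = self.trees_of([4.0, 5.0, 6.0])
        assert classify_growth_form(t)["spA"] == "shrub"

    def test_exactly_10_is_shrub(self):
        t = self.trees_of([10.0] * 6)
        assert classify_growth_form(t)["spA"] == "shrub"

    def test_no_individuals_unknown(self):
        t = self.trees_of([np.nan])
        assert classify_growth_form(t)["spA"] == "unknown"


class TestSpeciesAttributes:
    def test_roundtrip(self, tmp_path):
        from cndd.forest_data import read_species_attributes
        path = tmp_path / "attrs.csv"
        path.write_text("species,growth_form_override,is_fern_or_palm\n"
                        "fern1,,1\nspA,shrub,0\nspB,,0\n")
        ferns, overrides = read_species_attributes(path)
        assert ferns == {"fern1"}
        assert overrides == {"spA": "shrub"}


class TestAbundance:
    def test_per_hectare(self, plot):
        census = pd.DataFrame({"species": "spA", "dbh": [5.0] * 12,
                               "status": "alive"})
        assert compute_abundance(census, plot) == pytest.approx(2.0)  # 12 / 6 ha

    def test_group_mean(self):
        assert group_abundance([0.2, 0.4]) == pytest.approx(0.3)

    def test_sub_centimetre_excluded(self, plot):
        census = pd.DataFrame({"species": "spA", "dbh": [0.9] * 5,
                               "status": "alive"})
        assert compute_abundance(census, plot) == 0.0

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            group_abundance([])
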