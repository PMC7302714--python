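"""Ingestion: packaged study tables, alignment, imputation and geometry."""

import numpy as np
import pandas as pd
import pytest

from deerssm import (
    StudyConfig,
    TimeIndex,
    compute_area_ratios,
    compute_carcass_area_ratio,
    impute_block_count,
    load_harvest_table,
    load_survey_tables,
    load_winter_table,
    study_covariates,
    write_survey_tables,
)

# printed yearly totals of the nuisance-control table: harvest (effort)
HARVEST_TOTALS = {
    2007: (0, 0), 2008: (10, 30), 2009: (3, 32), 2010: (7, 6),
    2011: (5, 16), 2012: (8, 19), 2013: (22, 50), 2014: (32, 26),
    2015: (12, 43), 2016: (17, 51), 2017: (5, 34), 2018: (6, 24),
}


def test_harvest_fixture_row_sums_match_printed_totals():
    df = load_harvest_table()
    for year, (h_tot, ef_tot) in HARVEST_TOTALS.items():
        sub = df[df.year == year]
        assert len(sub) == 4
        assert sub.harvest.sum() == h_tot
        assert sub.effort.sum() == ef_tot


@pytest.mark.parametrize(
    "year, carcasses, distance, sd50, maxs",
    [
        (2008, 30, 78.5, 52, 132.0),
        (2010, 0, 98.5, 0, 36.7),
        (2011, 25, 88.5, 76, 141.7),
        (2012, 4, 83.5, 87, 138.3),
        (2016, 2, 92.5, 0, 31.0),
        (2018, 0, 93.0, 7, 87.0),
    ],
)
def test_winter_fixture_values(year, carcasses, distance, sd50, maxs):
    df = load_winter_table().set_index("year")
    row = df.loc[year]
    assert row.carcasses == carcasses
    assert row.distance_km == distance
    assert row.sd50_days == sd50
    assert row.maxs_cm == maxs


def test_winter_fixture_covers_exactly_the_winter_transitions():
    time = TimeIndex(2007, 12)
    df = load_winter_table()
    assert sorted(df.year) == [time.year(t) for t in time.winter_transitions]
    cov = study_covariates(time)
    for key in ("carcasses", "sd50", "maxs"):
        assert cov[key].shape == (time.n_winters,)


def test_study_covariates_alignment():
    time = TimeIndex(2007, 12)
    cov = study_covariates(time)
    # Nov-Dec 2008 effort and winter entering 2012 snow days
    assert cov["effort"][time.t_of(2008, "NOV_DEC") - 1] == 24
    assert cov["sd50"][list(time.winter_transitions).index(time.t_of(2012, "MAY_JUN"))] == 87
    assert cov["harvest"].sum() == sum(v[0] for v in HARVEST_TOTALS.values())


class TestImputation:
    def test_mean_of_neighbours(self):
        out = impute_block_count({2016: 10, 2018: 14, 2017: None})
        assert out[2017] == 12

    def test_half_up_rounding(self):
        assert impute_block_count({2016: 7, 2018: 8, 2017: None})[2017] == 8
        assert impute_block_count(
            {2016: 7, 2018: 8, 2017: None}, rounding="nearest-even"
        )[2017] == 8

    def test_present_year_unchanged(self):
        out = impute_block_count({2016: 10, 2017: 3, 2018: 14})
        assert out[2017] == 3

    def test_missing_neighbour_rejected(self):
        with pytest.raises(ValueError):
            impute_block_count({2016: 10, 2017: None})


class TestAreaRatios:
    def test_study_route_geometry(self):
        ratios = compute_area_ratios(
            {"A": 4.7, "B": 3.3, "E": 0.7}, 15.0, 46.12
        )
        assert ratios["A"] == pytest.approx(0.00153, abs=5e-6)
        assert ratios["B"] == pytest.approx(0.00107, abs=5e-6)
        assert ratios["E"] == pytest.approx(0.00023, abs=5e-6)

    def test_carcass_strip(self):
        ratio = compute_carcass_area_ratio(100.0, 50.0, 46.12)
        assert ratio[0] == pytest.approx(100.0 * 0.05 / 46.12)

    def test_degenerate_geometry_rejected(self):
        with pytest.raises(ValueError):
            compute_area_ratios({"A": 4.7}, 0.0, 46.12)
        with pytest.raises(ValueError):
            compute_carcass_area_ratio(0.0, 50.0, 46.12)
        with pytest.raises(ValueError):
            # strip as wide as the forest: ratio would reach 1
            compute_carcass_area_ratio(46.12, 1000.0, 46.12)


class TestLoadAndRoundTrip:
    def test_round_trip(self, tmp_path, small_dataset):
        data, _ = small_dataset
        paths = write_survey_tables(data, tmp_path)
        loaded = load_survey_tables(
            paths["road"], paths["block"], paths["harvest"], paths["carcass"]
        )
        np.testing.assert_array_equal(loaded.road_counts, data.road_counts)
        np.testing.assert_array_equal(loaded.road_occasions, data.road_occasions)
        np.testing.assert_array_equal(loaded.block_counts, data.block_counts)
        np.testing.assert_array_equal(loaded.harvest, data.harvest)
        np.testing.assert_allclose(loaded.effort, data.effort)
        np.testing.assert_array_equal(loaded.carcasses, data.carcasses)
        np.testing.assert_allclose(
            loaded.carcass_area_ratio, data.carcass_area_ratio
        )
        np.testing.assert_allclose(loaded.snow_days, data.snow_days)
        np.testing.assert_allclose(loaded.snow_max, data.snow_max)

    def test_empty_road_file_warns_and_zeroes_occasions(
        self, tmp_path, small_dataset
    ):
        data, _ = small_dataset
        paths = write_survey_tables(data, tmp_path)
        pd.DataFrame(
            columns=["year", "season", "route", "count", "occasions"]
        ).to_csv(tmp_path / "road.csv", index=False)
        with pytest.warns(UserWarning, match="no records"):
            loaded = load_survey_tables(
                tmp_path / "road.csv", paths["block"], paths["harvest"],
                paths["carcass"],
            )
        assert np.all(loaded.road_occasions == 0)

    def test_validation_errors_aggregated(self, tmp_path, small_dataset):
        data, _ = small_dataset
        paths = write_survey_tables(data, tmp_path)
        road = pd.read_csv(paths["road"])
        road.loc[0, "route"] = "Z"          # unknown route
        road.to_csv(paths["road"], index=False)
        block = pd.read_csv(paths["block"])
        block.loc[len(block)] = {"year": 2007, "count": 5, "area_ratio": 0.04}
        block.to_csv(paths["block"], index=False)  # non-winter year
        with pytest.raises(ValueError) as exc:
            load_survey_tables(
                paths["road"], paths["block"], paths["harvest"],
                paths["carcass"],
            )
        msg = str(exc.value)
        assert "unknown route" in msg and "non-winter" in msg
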