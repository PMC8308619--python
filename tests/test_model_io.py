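"""Schema validation, registry closure, and result round-trips."""

import math

import pandas as pd
import pytest

from ncspath.model_io import (
    ResultRecord,
    SchemaError,
    UnresolvedKeyError,
    ValidationError,
    read_inputs,
    read_results,
    write_results,
)
from ncspath.registry import ActivityKey, RegistryError, validate_key


def _write_toy_inputs(tmp_path, baseline_rows, rate_rows, counties=None):
    counties = counties or [
        {"county_id": 1, "name": "A", "region": "west", "area_ha": 1000.0,
         "timber_excluded": False},
        {"county_id": 3, "name": "B", "region": "east", "area_ha": 2000.0,
         "timber_excluded": False},
    ]
    paths = {
        "counties": tmp_path / "counties.csv",
        "baselines": tmp_path / "baselines.csv",
        "rates": tmp_path / "rates.csv",
        "scenario_params": tmp_path / "scenario_params.csv",
    }
    pd.DataFrame(counties).to_csv(paths["counties"], index=False)
    pd.DataFrame(baseline_rows).to_csv(paths["baselines"], index=False)
    pd.DataFrame(rate_rows).to_csv(paths["rates"], index=False)
    pd.DataFrame(
        columns=["scenario", "pathway", "sub_activity", "ownership"]
    ).to_csv(paths["scenario_params"], index=False)
    return paths


def _baseline_row(**kw):
    row = {
        "county_id": 1, "pathway": "riparian_restoration", "sub_activity": "",
        "ownership": "na", "year": "", "amount": 5.0, "units": "ha_per_yr",
        "max_resource": "",
    }
    row.update(kw)
    return row


def _rate_row(**kw):
    row = {
        "pathway": "riparian_restoration", "sub_activity": "", "ownership": "na",
        "region": "statewide", "mean_rate": -8.0, "sd_rate": 0.5,
        "units": "ha_per_yr", "age_profile": "",
    }
    row.update(kw)
    return row


class TestRegistry:
    def test_known_activities_resolve(self):
        assert validate_key(ActivityKey("agriculture", "cover_crops")).units == "ha_per_yr"
        assert validate_key(
            ActivityKey("extended_rotation", "harvest", "private")
        ).units == "volume_per_yr"

    def test_unknown_pathway_rejected(self):
        with pytest.raises(RegistryError):
            ActivityKey("geoengineering")

    def test_unregistered_combination_rejected(self):
        with pytest.raises(RegistryError):
            validate_key(ActivityKey("agriculture", "vertical_farming"))


class TestReadInputs:
    def test_toy_round_trip_identity(self, tmp_path):
        rows = [
            _baseline_row(county_id=1),
            _baseline_row(county_id=3),
            _baseline_row(county_id=1, pathway="agriculture",
                          sub_activity="cover_crops", amount=12.0),
            _baseline_row(county_id=3, pathway="agriculture",
                          sub_activity="cover_crops", amount=7.0),
        ]
        rates = [
            _rate_row(),
            _rate_row(pathway="agriculture", sub_activity="cover_crops",
                      mean_rate=-1.5),
        ]
        paths = _write_toy_inputs(tmp_path, rows, rates)
        bundle = read_inputs(*paths.values())
        assert len(bundle.baselines) == 4
        assert {r.key.pathway for r in bundle.baselines} == {
            "riparian_restoration", "agriculture",
        }

    def test_unknown_pathway_in_file_is_registry_error(self, tmp_path):
        paths = _write_toy_inputs(
            tmp_path, [_baseline_row(pathway="geoengineering")], [_rate_row()]
        )
        with pytest.raises(RegistryError):
            read_inputs(*paths.values())

    def test_missing_column_names_it(self, tmp_path):
        paths = _write_toy_inputs(tmp_path, [_baseline_row()], [_rate_row()])
        df = pd.read_csv(paths["baselines"]).drop(columns=["units"])
        df.to_csv(paths["baselines"], index=False)
        with pytest.raises(SchemaError, match="units"):
            read_inputs(*paths.values())

    def test_negative_activity_rejected(self, tmp_path):
        paths = _write_toy_inputs(tmp_path, [_baseline_row(amount=-1.0)], [_rate_row()])
        with pytest.raises(ValidationError):
            read_inputs(*paths.values())

    def test_baseline_without_rate_lists_key(self, tmp_path):
        paths = _write_toy_inputs(
            tmp_path,
            [_baseline_row(pathway="tidal_wetland_restoration")],
            [_rate_row()],
        )
        with pytest.raises(UnresolvedKeyError, match="tidal_wetland_restoration"):
            read_inputs(*paths.values())

    def test_statewide_fallback_used_and_logged(self, tmp_path):
        # east county has no east rate for the key, but west + statewide exist
        rows = [
            _baseline_row(county_id=1, pathway="avoided_forest_conversion",
                          sub_activity="forest_to_urban"),
            _baseline_row(county_id=3, pathway="avoided_forest_conversion",
                          sub_activity="forest_to_urban"),
        ]
        rates = [
            _rate_row(pathway="avoided_forest_conversion",
                      sub_activity="forest_to_urban", region="west",
                      mean_rate=-80.0),
            _rate_row(pathway="avoided_forest_conversion",
                      sub_activity="forest_to_urban", region="statewide",
                      mean_rate=-60.0),
        ]
        paths = _write_toy_inputs(tmp_path, rows, rates)
        bundle = read_inputs(*paths.values())
        key = ActivityKey("avoided_forest_conversion", "forest_to_urban")
        assert bundle.rate_for(1, key).mean_rate == -80.0  # west resolves directly
        assert bundle.rate_for(3, key).mean_rate == -60.0  # east falls back
        assert any("statewide" in w for w in bundle.warnings)

    def test_unit_mismatch_rejected(self, tmp_path):
        paths = _write_toy_inputs(
            tmp_path, [_baseline_row()], [_rate_row(units="volume_per_yr")]
        )
        with pytest.raises(ValidationError, match="units"):
            read_inputs(*paths.values())


class TestResultsIO:
    @staticmethod
    def _record(**kw):
        base = dict(
            geography="statewide", pathway="total", sub_activity="",
            scenario="ambitious", year=31, median=-8.8, p05=-9.1, p95=-8.5,
            cumulative_median=-120.0,
        )
        base.update(kw)
        return ResultRecord(**base)

    def test_empty_records_write_header_only(self, tmp_path):
        path = tmp_path / "out.csv"
        write_results([], path)
        df = pd.read_csv(path)
        assert len(df) == 0 and "median" in df.columns

    def test_two_records_in_canonical_order(self, tmp_path):
        path = tmp_path / "out.csv"
        write_results(
            [self._record(geography="statewide"), self._record(geography="41")],
            path,
        )
        df = pd.read_csv(path)
        assert list(df["geography"]) == ["41", "statewide"]
        assert list(df["calendar_year"]) == [2050, 2050]

    def test_write_read_round_trip(self, tmp_path):
        records = [
            self._record(),
            self._record(geography="41", pathway="extended_rotation", year=1,
                         median=-0.65, p05=-0.7, p95=-0.6, cumulative_median=-0.65),
        ]
        path = tmp_path / "out.csv"
        write_results(records, path)
        back = read_results(path)
        assert sorted(back, key=lambda r: r.geography) == sorted(
            records, key=lambda r: r.geography
        )

    def test_year_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            self._record(year=32)
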