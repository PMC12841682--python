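import datetime as dt
import math

import numpy as np
import pytest

from pinedemog import (
    CensusRecord,
    aggregate_densities,
    branch_area,
    read_census_csv,
    record_density,
    write_census_csv,
)
from pinedemog.census import read_density_csv, write_density_csv
from pinedemog.lifetable import STAGE_SERIES, STAGES, stage_schedule_from_series
from pinedemog.synth import SynthConfig, generate_census


def _record(length=100.0, diameter=10.0, counts=None, date=dt.date(1998, 8, 5),
            tree="T01", position="upper"):
    return CensusRecord(date, tree, position, length, diameter, counts or {})


class TestBranchArea:
    @pytest.mark.parametrize(
        "length,diameter,expected",
        [(100, 10, 1000.0), (50, 10, 500.0), (123.4, 5.6, 691.04)],
    )
    def test_length_times_diameter(self, length, diameter, expected):
        assert branch_area(length, diameter) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "length,diameter,field",
        [(0, 10, "branch_length_cm"), (10, -1, "branch_diameter_cm")],
    )
    def test_nonpositive_dimension_names_field(self, length, diameter, field):
        with pytest.raises(ValueError, match=field):
            branch_area(length, diameter)


class TestRecordDensity:
    def test_unit_branch_and_zero_count(self, unit_record):
        assert record_density(unit_record, "egg") == 5.0
        assert record_density(unit_record, "pupa") == 0.0

    def test_scaling_with_area(self):
        rec = _record(length=250, diameter=10, counts={"larva": 7})  # 2500 cm²
        assert record_density(rec, "larva") == pytest.approx(2.8)

    def test_unknown_stage_lists_valid_labels(self, unit_record):
        with pytest.raises(ValueError, match="egg.*larva.*pupa"):
            record_density(unit_record, "adult")

    def test_homogeneity_in_count_and_area(self):
        base = record_density(_record(counts={"larva": 3}), "larva")
        assert record_density(_record(counts={"larva": 9}), "larva") == 3 * base
        doubled_area = _record(length=200, counts={"larva": 3})
        assert record_density(doubled_area, "larva") == base / 2


class TestAggregateDensities:
    def test_mean_and_se_over_two_branches(self):
        recs = [
            _record(counts={"larva": 4}, position="upper"),
            _record(counts={"larva": 8}, position="lower"),
        ]
        series = {s.stage: s for s in aggregate_densities(recs)}
        assert series["larva"].mean_density == pytest.approx(6.0)
        assert series["larva"].se_density == pytest.approx(2.0)
        assert series["larva"].n_branches == 2

    def test_identical_branches_have_zero_se(self):
        recs = [_record(counts={"egg": 3}, tree=f"T{i}") for i in range(5)]
        series = {s.stage: s for s in aggregate_densities(recs)}
        assert series["egg"].mean_density == pytest.approx(3.0)
        assert series["egg"].se_density == 0.0

    def test_single_record_matches_record_density(self, unit_record, caplog):
        with caplog.at_level("WARNING"):
            series = aggregate_densities([unit_record])
        for s in series:
            assert s.mean_density == record_density(unit_record, s.stage)
            assert s.se_density == 0.0
            assert s.n_branches == 1
        assert "SE reported as 0" in caplog.text

    def test_permutation_invariance(self):
        recs = [
            _record(counts={"larva": k}, tree=f"T{k}", length=50 + 10 * k)
            for k in range(6)
        ]
        forward = aggregate_densities(recs)
        backward = aggregate_densities(recs[::-1])
        assert forward == backward

    def test_tree_level_aggregation(self):
        recs = [
            _record(counts={"larva": 2}, tree="A", position="upper"),
            _record(counts={"larva": 6}, tree="A", position="lower"),
            _record(counts={"larva": 4}, tree="B", position="upper"),
            _record(counts={"larva": 8}, tree="B", position="lower"),
        ]
        by_branch = {s.stage: s for s in aggregate_densities(recs)}
        by_tree = {s.stage: s for s in aggregate_densities(recs, by_tree=True)}
        assert by_branch["larva"].n_branches == 4
        assert by_tree["larva"].n_branches == 2
        assert by_tree["larva"].mean_density == pytest.approx(5.0)
        # tree means are 4 and 6: SE = sd([4, 6]) / sqrt(2) = 1
        assert by_tree["larva"].se_density == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one record"):
            aggregate_densities([])

    def test_sample_mean_tracks_generator_truth(self):
        """60 synthetic branches recover the true density within 3 SE."""
        cfg = SynthConfig(seed=11)
        series = aggregate_densities(generate_census(cfg))
        for stage, date in cfg.stage_dates.items():
            truth = cfg.true_stage_densities[stage]
            s = next(
                x for x in series
                if x.survey_date == date and x.stage == STAGE_SERIES[stage]
            )
            assert abs(s.mean_density - truth) <= 3 * max(s.se_density, 1e-9), stage


class TestCsvRoundTrip:
    def test_write_then_read_is_lossless(self, tmp_path, unit_record):
        records = [
            unit_record,
            _record(counts={"larva": 3}, tree="T02", position="lower"),
            _record(counts={"pupa": 1}, tree="T03", length=42.5, diameter=3.25),
        ]
        path = tmp_path / "census.csv"
        write_census_csv(records, path)
        assert read_census_csv(path) == records

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("survey_date,tree_id\n1998-08-05,T01\n")
        with pytest.raises(ValueError, match="branch_length_cm"):
            read_census_csv(path)

    def test_bad_values_report_row_number(self, tmp_path):
        header = (
            "survey_date,tree_id,canopy_position,branch_length_cm,"
            "branch_diameter_cm,egg_count,larva_count,pupa_count\n"
        )
        bad_count = header + "1998-08-05,T01,upper,100,10,0,-2,0\n"
        path = tmp_path / "bad.csv"
        path.write_text(bad_count)
        with pytest.raises(ValueError, match="row 2.*larva_count"):
            read_census_csv(path)
        path.write_text(header + "not-a-date,T01,upper,100,10,0,0,0\n")
        with pytest.raises(ValueError, match="row 2.*survey_date"):
            read_census_csv(path)

    def test_density_csv_round_trip(self, tmp_path, unit_record):
        series = aggregate_densities([unit_record, _record(counts={"egg": 7})])
        path = tmp_path / "density.csv"
        write_density_csv(series, path)
        back = read_density_csv(path)
        assert back == series

    def test_table_equivalent_fixture_yields_six_stage_densities(
        self, table_equivalent_records
    ):
        series = aggregate_densities(table_equivalent_records)
        n_x = stage_schedule_from_series(series)
        assert len(n_x) == len(STAGES) == 6
        assert np.all(n_x > 0)
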