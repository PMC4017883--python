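"""Event processing: ingestion, the 30-min filter, exclusions, incidence."""

import io

import numpy as np
import pandas as pd
import pytest

from trapeffort import (
    apply_exclusions,
    build_incidence,
    filter_independent,
    read_daily_matrix,
    read_photo_records,
    species_summary_from_counts,
    summarize_species,
    write_photo_records,
)
from trapeffort.events import UnclassifiedSpeciesError

from conftest import make_records


class TestReadPhotoRecords:
    def test_empty_file_with_header(self):
        records = read_photo_records(io.StringIO("site_id,species,timestamp\n"))
        assert records.empty and list(records.columns) == ["site_id", "species", "timestamp"]

    def test_bad_timestamp_names_the_file_row(self):
        text = (
            "site_id,species,timestamp\n"
            "S1,boar,2009-06-01T10:00:00\n"
            "S1,boar,2009-06-01T11:00:00\n"
            "S1,muntjac,2009-06-02T09:00:00\n"
            "S1,boar,not-a-time\n"
        )
        with pytest.raises(ValueError, match=r"row\(s\) \[5\]"):
            read_photo_records(io.StringIO(text))

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="required column"):
            read_photo_records(io.StringIO("site_id,when\nS1,2009-06-01\n"))

    def test_simulator_output_round_trips(self, full_sim, tmp_path):
        _, _, records, _ = full_sim
        path = tmp_path / "records.csv"
        write_photo_records(records, path)
        back = read_photo_records(path)
        expected = records.sort_values(
            ["site_id", "species", "timestamp"], kind="mergesort"
        ).reset_index(drop=True)
        pd.testing.assert_frame_equal(back, expected)


class TestReadDailyMatrix:
    def test_all_zero_table(self):
        matrix = read_daily_matrix(io.StringIO("a,b\n0,0\n0,0\n0,0\n0,0\n0,0\n"))
        assert matrix.n_units == 5
        assert (matrix.occurrence_counts() == 0).all()

    def test_single_row(self):
        matrix = read_daily_matrix(io.StringIO("a,b\n1,0\n"))
        assert matrix.n_units == 1
        assert matrix.occurrence_counts().tolist() == [1, 0]

    def test_value_above_camera_count_rejected(self):
        with pytest.raises(ValueError, match="exceeds the declared maximum 19"):
            read_daily_matrix(io.StringIO("a,b\n20,0\n"), max_cameras=19)


class TestIndependenceFilter:
    def test_single_photo_is_one_event(self):
        events = filter_independent(make_records([("S1", "boar", "2009-06-01T10:00:00")]))
        assert len(events) == 1 and events.loc[0, "n_photos"] == 1

    @pytest.mark.parametrize(
        "gap_minutes,n_events",
        [(29, 1), (30, 1), (31, 2)],
        ids=["29min-merged", "exactly-30min-merged", "31min-split"],
    )
    def test_interval_boundary(self, gap_minutes, n_events):
        """A gap of exactly the interval does not start a new event."""
        t0 = pd.Timestamp("2009-06-01T10:00:00")
        events = filter_independent(
            make_records(
                [
                    ("S1", "boar", str(t0)),
                    ("S1", "boar", str(t0 + pd.Timedelta(minutes=gap_minutes))),
                ]
            )
        )
        assert len(events) == n_events
        assert events["n_photos"].sum() == 2

    def test_rolling_gap_merges_long_bursts(self):
        """Photos each 20 min apart form one event however long the chain."""
        t0 = pd.Timestamp("2009-06-01T00:00:00")
        rows = [("S1", "boar", str(t0 + pd.Timedelta(minutes=20 * i))) for i in range(10)]
        events = filter_independent(make_records(rows))
        assert len(events) == 1 and events.loc[0, "n_photos"] == 10

    def test_order_insensitive(self, full_sim):
        _, _, records, _ = full_sim
        shuffled = records.sample(frac=1.0, random_state=0).reset_index(drop=True)
        pd.testing.assert_frame_equal(filter_independent(records), filter_independent(shuffled))

    def test_shorter_interval_never_merges_more(self, full_sim):
        _, _, records, _ = full_sim
        sub = records.head(500)
        n_prev = 0
        for interval in (120, 60, 30, 10, 1):
            n = len(filter_independent(sub, interval))
            assert n >= n_prev
            n_prev = n

    def test_streams_are_per_site_and_per_species(self):
        t0 = pd.Timestamp("2009-06-01T10:00:00")
        rows = [
            ("S1", "boar", str(t0)),
            ("S2", "boar", str(t0 + pd.Timedelta(minutes=5))),
            ("S1", "muntjac", str(t0 + pd.Timedelta(minutes=10))),
        ]
        assert len(filter_independent(make_records(rows))) == 3
        assert len(filter_independent(make_records(rows), per_site=False)) == 2

    def test_photo_count_conserved(self, full_sim):
        _, _, records, _ = full_sim
        events = filter_independent(records)
        assert events["n_photos"].sum() == len(records)

    def test_negative_interval_rejected(self):
        with pytest.raises(ValueError):
            filter_independent(make_records([("S1", "boar", "2009-06-01T10:00:00")]), -1)


class TestExclusions:
    def test_all_resident_is_identity(self):
        events = filter_independent(
            make_records(
                [
                    ("S1", "boar", "2009-06-01T10:00:00"),
                    ("S2", "muntjac", "2009-06-02T10:00:00"),
                ]
            )
        )
        kept, log = apply_exclusions(
            events, {"boar": "resident_terrestrial", "muntjac": "resident_terrestrial"}
        )
        pd.testing.assert_frame_equal(kept, events)
        assert log.empty

    def test_unclassified_species_is_a_hard_error(self):
        events = filter_independent(make_records([("S1", "boar", "2009-06-01T10:00:00")]))
        with pytest.raises(UnclassifiedSpeciesError, match="boar"):
            apply_exclusions(events, {"muntjac": "resident_terrestrial"})

    def test_removal_log_counts_events(self, full_processed):
        events, resident = full_processed["events"], full_processed["resident"]
        community = full_processed["community"]
        classification = {sp.name: sp.guild for sp in community}
        _, log = apply_exclusions(events, classification)
        removed = set(events["species"]) - set(resident["species"])
        assert set(log["species"]) == removed
        assert log["n_events"].sum() + len(resident) == len(events)
        assert set(log["guild"]) <= {"arboreal", "transient"}


class TestSpeciesSummary:
    def test_single_species_is_100_percent(self):
        summary = species_summary_from_counts({"boar": 5}, {"boar": 3}, resident=["boar"])
        assert summary.loc["boar", "p1"] == summary.loc["boar", "p2"] == 100.0

    def test_percentages_sum_to_100(self, full_processed):
        summary = full_processed["summary"]
        assert summary["p1"].sum() == pytest.approx(100.0)
        assert summary["p2"].dropna().sum() == pytest.approx(100.0)
        assert (summary["ip"] <= summary["rp"]).all()

    def test_zero_events_rejected(self):
        with pytest.raises(ValueError):
            species_summary_from_counts({"boar": 0}, {"boar": 0}, resident=["boar"])

    def test_ip_cannot_exceed_rp(self):
        with pytest.raises(ValueError):
            species_summary_from_counts({"boar": 2}, {"boar": 3}, resident=["boar"])


class TestBuildIncidence:
    def test_zero_days_are_retained(self):
        events = filter_independent(
            make_records(
                [
                    ("S1", "boar", "2009-06-01T10:00:00"),
                    ("S1", "boar", "2009-06-04T10:00:00"),
                ]
            )
        )
        span = (pd.Timestamp("2009-06-01"), pd.Timestamp("2009-06-05"))
        matrix = build_incidence(events, "day", span)
        assert matrix.n_units == 5
        assert (matrix.binarized().sum(axis=1) == 0).sum() == 3

    def test_day_count_is_distinct_sites(self):
        rows = [(f"S{i}", "boar", "2009-06-01T10:00:00") for i in (1, 2, 3)]
        rows.append(("S1", "boar", "2009-06-01T11:00:00"))
        events = filter_independent(make_records(rows))
        span = (pd.Timestamp("2009-06-01"), pd.Timestamp("2009-06-01"))
        matrix = build_incidence(events, "day", span)
        assert matrix.counts.iloc[0, 0] == 3

    def test_event_outside_span_rejected(self):
        events = filter_independent(make_records([("S1", "boar", "2009-06-09T10:00:00")]))
        with pytest.raises(ValueError, match="outside"):
            build_incidence(events, "day", (pd.Timestamp("2009-06-01"), pd.Timestamp("2009-06-05")))

    def test_site_units_count_events(self, full_processed):
        matrix = build_incidence(full_processed["resident"], "site")
        assert matrix.counts.to_numpy().sum() == len(full_processed["resident"])

    def test_two_path_consistency_with_pooled_matrix(self, full_processed):
        """The records-derived day matrix equals the pooled daily counts."""
        from conftest import SPAN

        matrix = full_processed["incidence"]
        pooled = full_processed["occupancy"].day_matrix()
        common = matrix.counts.columns
        assert (matrix.counts.to_numpy() == pooled[common].to_numpy()).all()
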