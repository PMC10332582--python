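"""Record ingestion, independence filtering, history construction and
survey summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from camtrapocc.survey import (DetectionHistory, build_history,
                               filter_independent, pool_guild, read_records,
                               read_stations, summarize_survey)
from camtrapocc.simulate import survey_fixture
from conftest import make_records


def _write_csvs(tmp_path, records, stations):
    rp, sp = tmp_path / "records.csv", tmp_path / "stations.csv"
    records.to_csv(rp, index=False)
    stations.to_csv(sp, index=False)
    return rp, sp


class TestReadRecords:
    def test_identity_parse(self, tmp_path, simple_stations, record_factory):
        rec = record_factory([("A", "tayra", "2021-01-02T10:00"),
                              ("B", "tayra", "2021-01-03T11:00"),
                              ("C", "puma", "2021-01-04T12:00")])
        rp, sp = _write_csvs(tmp_path, rec, simple_stations)
        out = read_records(rp, read_stations(sp))
        assert len(out) == 3
        assert out.attrs["n_dropped"] == 0

    def test_invalid_date_errors_with_row(self, tmp_path, simple_stations):
        rp, sp = _write_csvs(tmp_path, pd.DataFrame({
            "station_id": ["A"], "species": ["tayra"],
            "timestamp": ["2021-02-30T10:00"]}), simple_stations)
        with pytest.raises(ValueError, match="row"):
            read_records(rp, read_stations(sp))

    def test_unknown_station_errors_with_id(self, tmp_path, simple_stations,
                                            record_factory):
        rec = record_factory([("ZZ", "tayra", "2021-01-02T10:00")])
        rp, sp = _write_csvs(tmp_path, rec, simple_stations)
        with pytest.raises(ValueError, match="ZZ"):
            read_records(rp, read_stations(sp))

    def test_out_of_window_record_dropped_with_warning(self, tmp_path,
                                                       simple_stations,
                                                       record_factory):
        rec = record_factory([("A", "tayra", "2020-12-25T10:00"),
                              ("A", "tayra", "2021-01-05T10:00")])
        rp, sp = _write_csvs(tmp_path, rec, simple_stations)
        with pytest.warns(UserWarning, match="dropped 1"):
            out = read_records(rp, read_stations(sp))
        assert len(out) == 1
        assert out.attrs["n_dropped"] == 1


class TestPoolGuild:
    def test_relabel_and_identity(self, record_factory):
        rec = record_factory([("A", "puma", "2021-01-02T10:00"),
                              ("A", "dog", "2021-01-02T15:00"),
                              ("B", "tayra", "2021-01-03T10:00")])
        out = pool_guild(rec, {"puma": "killer", "dog": "killer"})
        assert list(out["species"]) == ["killer", "killer", "tayra"]
        assert len(out) == len(rec)

    def test_pool_then_filter_merges_same_day_guild_records(self, record_factory):
        rec = record_factory([("A", "puma", "2021-01-02T10:00"),
                              ("A", "dog", "2021-01-02T15:00")])
        pooled = filter_independent(pool_guild(rec, {"puma": "killer",
                                                     "dog": "killer"}))
        assert len(pooled) == 1
        assert pooled["species"].iloc[0] == "killer"


class TestFilterIndependent:
    def test_same_day_pooled_keeps_earliest(self, record_factory):
        rec = record_factory([("A", "tiger_cat", "2021-01-02T23:00"),
                              ("A", "tiger_cat", "2021-01-02T10:00")])
        out = filter_independent(rec)
        assert len(out) == 1
        assert out["timestamp"].iloc[0].hour == 10

    def test_consecutive_days_kept(self, record_factory):
        rec = record_factory([("A", "tiger_cat", "2021-01-02T10:00"),
                              ("A", "tiger_cat", "2021-01-03T10:00")])
        assert len(filter_independent(rec)) == 2

    def test_species_pooled_separately(self, record_factory):
        rec = record_factory([("A", "tiger_cat", "2021-01-02T10:00"),
                              ("A", "tayra", "2021-01-02T11:00")])
        assert len(filter_independent(rec)) == 2

    @given(st.lists(st.tuples(st.sampled_from(["A", "B"]),
                              st.sampled_from(["cat", "tayra"]),
                              st.integers(0, 9), st.integers(0, 23)),
                    max_size=30))
    def test_idempotent(self, rows):
        rec = make_records([
            (s, sp, f"2021-01-{d + 1:02d}T{h:02d}:00") for s, sp, d, h in rows])
        once = filter_independent(rec)
        twice = filter_independent(once)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True))


class TestBuildHistory:
    def test_130_day_deployment_gives_19_occasions(self, record_factory):
        stations = pd.DataFrame({
            "station_id": ["A"], "x": [0.0], "y": [0.0],
            "coord_system": ["planar"],
            "activation_date": pd.to_datetime(["2021-01-01"]),
            "retrieval_date": pd.to_datetime(["2021-05-10"]),  # 130 days
            "pir_delay_class": ["<=0.6s"], "block_id": ["R1"]})
        hist = build_history(make_records([("A", "cat", "2021-01-02T10:00")]),
                             stations, "cat")
        assert hist.n_occasions == 19
        assert hist.effort[0, -1] == 4          # 130 - 18*7
        assert hist.effort[0, :18].sum() == 126

    def test_detection_day_8_lands_in_second_occasion(self, simple_stations,
                                                      record_factory):
        rec = record_factory([("A", "cat", "2021-01-08T10:00")])
        hist = build_history(rec, simple_stations, "cat")
        assert hist.matrix[0, 1] == 1.0
        assert hist.matrix[0, 0] == 0.0

    @pytest.mark.parametrize("deploy_days", [7, 13, 29, 60])
    def test_single_record_block_arithmetic_exhaustive(self, deploy_days):
        """A record on day d always lands in occasion floor((d-1)/7)."""
        stations = pd.DataFrame({
            "station_id": ["A"], "x": [0.0], "y": [0.0],
            "coord_system": ["planar"],
            "activation_date": pd.to_datetime(["2021-01-01"]),
            "retrieval_date": pd.to_datetime(["2021-01-01"])
            + pd.Timedelta(days=deploy_days - 1),
            "pir_delay_class": ["<=0.6s"], "block_id": ["R1"]})
        for d in range(1, deploy_days + 1):
            ts = pd.Timestamp("2021-01-01") + pd.Timedelta(days=d - 1, hours=9)
            hist = build_history(make_records([("A", "cat", str(ts))]),
                                 stations, "cat")
            j = (d - 1) // 7
            assert hist.matrix[0, j] == 1.0
            assert np.nansum(hist.matrix) == 1.0

    def test_absent_species_warns_not_errors(self, simple_stations,
                                             record_factory):
        rec = record_factory([("A", "cat", "2021-01-02T10:00")])
        with pytest.warns(UserWarning, match="no records"):
            hist = build_history(rec, simple_stations, "ghost")
        assert np.nansum(hist.matrix) == 0

    def test_missing_iff_zero_effort(self, simple_stations, record_factory):
        rec = record_factory([("A", "cat", "2021-01-02T10:00")])
        hist = build_history(rec, simple_stations, "cat")
        assert np.array_equal(np.isnan(hist.matrix), hist.effort == 0)

    def test_theft_gap_is_missing_with_zero_effort(self, simple_stations,
                                                   record_factory):
        from camtrapocc.survey import apply_gaps
        hist = build_history(make_records([("A", "cat", "2021-01-02T10:00")]),
                             simple_stations, "cat")
        gapped = apply_gaps(hist, {"B": [1]})
        assert np.isnan(gapped.matrix[1, 1])
        assert gapped.effort[1, 1] == 0


class TestDetectionHistoryIO:
    def test_round_trip_preserves_matrix_and_effort(self, tmp_path):
        m = np.array([[1.0, 0.0, np.nan], [0.0, 1.0, 1.0]])
        e = np.array([[7, 7, 0], [7, 7, 3]])
        hist = DetectionHistory("cat", ["A", "B"], m, e)
        hp, ep = tmp_path / "h.csv", tmp_path / "e.csv"
        hist.to_csv(hp, ep)
        assert "NA" in hp.read_text()
        back = DetectionHistory.from_csv(hp, ep, species="cat")
        np.testing.assert_array_equal(back.matrix, m)
        np.testing.assert_array_equal(back.effort, e)


class TestSummarizeSurvey:
    def test_empty_history_set(self, simple_stations):
        s = summarize_survey({}, simple_stations)
        assert s.total_trap_nights == 0
        assert s.detections.empty

    def test_detection_counts_order_independent(self):
        records, stations = survey_fixture()
        hists = {sp: build_history(records, stations, sp)
                 for sp in ["tiger_cat", "tayra"]}
        s = summarize_survey(hists, stations, records)
        # occasion-level count can never exceed daily count or raw records
        for sp in hists:
            daily = s.daily_detections(sp)
            occ = s.occasion_detections(sp)
            raw = (records["species"] == sp).sum()
            assert occ <= daily <= raw

    def test_naive_occupancy_bounds(self):
        records, stations = survey_fixture()
        hists = {"tiger_cat": build_history(records, stations, "tiger_cat")}
        s = summarize_survey(hists, stations)
        naive = s.naive["naive_occupancy"].iloc[0]
        assert 0.0 <= naive <= 1.0
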