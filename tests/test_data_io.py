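"""Manifest parsing, frame-rate downsampling and per-pen accounting."""

import numpy as np
import pandas as pd
import pytest

from pentail import data_io
from pentail.data_io import (
    FrameTable,
    count_events,
    downsample_indices,
    load_manifest,
    save_manifest,
    summarize,
)
from pentail.errors import IntegrityError, ManifestFormatError

TOY_CSV = """pen_id,frame_index,biting,category
A,0,false,no_event
A,1,true,tail_biting
A,2,false,nursing
"""


def _write(tmp_path, text):
    path = tmp_path / "manifest.csv"
    path.write_text(text)
    return path


class TestLoadManifest:
    def test_toy_csv_counts(self, tmp_path):
        table = load_manifest(_write(tmp_path, TOY_CSV))
        assert len(table) == 3
        assert int(table.frames["biting"].sum()) == 1
        assert table.pens == ["A"]

    def test_missing_column_is_format_error(self, tmp_path):
        with pytest.raises(ManifestFormatError, match="biting"):
            load_manifest(_write(tmp_path, "pen_id,frame_index,category\nA,0,no_event\n"))

    def test_category_biting_mismatch_is_integrity_error(self, tmp_path):
        text = TOY_CSV.replace("A,1,true,tail_biting", "A,1,false,tail_biting")
        with pytest.raises(IntegrityError, match="disagree"):
            load_manifest(_write(tmp_path, text))

    def test_duplicate_frame_is_integrity_error(self, tmp_path):
        text = TOY_CSV + "A,2,false,no_event\n"
        with pytest.raises(IntegrityError, match="duplicate"):
            load_manifest(_write(tmp_path, text))

    def test_round_trip(self, tmp_path, small_data):
        _, table, _, _ = small_data
        save_manifest(table, tmp_path / "m.csv")
        back = load_manifest(tmp_path / "m.csv")
        pd.testing.assert_frame_equal(table.frames, back.frames)


class TestDownsampleIndices:
    def test_identity_rates(self):
        assert downsample_indices(10, 10, 5).tolist() == [0, 1, 2, 3, 4]

    def test_video_rate_to_ten_fps(self):
        # round(k * 59.94 / 10) for k = 0..9
        idx = downsample_indices(59.94, 10, 60)
        assert idx.tolist() == [0, 6, 12, 18, 24, 30, 36, 42, 48, 54]

    def test_count_for_longer_stream(self):
        idx = downsample_indices(59.94, 10, 599)
        assert len(idx) == 100
        assert idx.max() < 599

    @pytest.mark.parametrize("n", [1, 17, 300])
    def test_strictly_increasing_and_in_range(self, n):
        idx = downsample_indices(59.94, 10, n)
        assert np.all(np.diff(idx) > 0) if len(idx) > 1 else True
        assert np.all((idx >= 0) & (idx < n))

    def test_bad_rates_rejected(self):
        with pytest.raises(ValueError):
            downsample_indices(0, 10, 5)
        with pytest.raises(ValueError):
            downsample_indices(10, 20, 5)


def _table_from_biting(biting, pen="P"):
    n = len(biting)
    cats = ["tail_biting" if b else "no_event" for b in biting]
    return FrameTable(
        pd.DataFrame(
            {"pen_id": pen, "frame_index": range(n), "biting": biting, "category": cats}
        )
    )


class TestSummarize:
    def test_two_runs_of_biting(self):
        biting = [i in {5, 6, 7, 20} for i in range(25)]
        summary = summarize(_table_from_biting(biting))
        row = summary[summary["pen_id"] == "P"].iloc[0]
        assert row["n_biting"] == 4
        assert row["n_events"] == 2

    def test_all_negative_pen(self):
        summary = summarize(_table_from_biting([False] * 100))
        row = summary[summary["pen_id"] == "P"].iloc[0]
        assert row["n_non_biting"] == 100
        assert row["n_events"] == 0

    def test_empty_table_gives_empty_summary(self):
        table = FrameTable(
            pd.DataFrame(columns=["pen_id", "frame_index", "biting", "category"])
        )
        assert len(summarize(table)) == 0

    def test_matches_generator_event_log(self, small_data):
        _, table, _, event_log = small_data
        summary = summarize(table).set_index("pen_id")
        for pen, events in event_log.items():
            biting = [e for e in events if e["category"] == "tail_biting"]
            assert summary.loc[pen, "n_events"] == len(biting)
            assert summary.loc[pen, "n_biting"] == sum(e["n_frames"] for e in biting)

    def test_counts_partition_table(self, small_data):
        _, table, _, _ = small_data
        summary = summarize(table)
        per_pen = summary[summary["pen_id"] != "total"]
        assert (
            per_pen["n_biting"].sum()
            + per_pen["n_non_biting"].sum()
            + per_pen["n_excluded"].sum()
        ) == len(table)

    def test_event_count_equals_rising_edges(self, rng):
        biting = rng.random(500) < 0.1
        expected = int(np.sum(np.diff(np.concatenate([[0], biting.astype(int)])) == 1))
        assert count_events(biting) == expected


def test_feature_container_round_trip(tmp_path, small_data):
    _, _, features, _ = small_data
    data_io.save_features(features, tmp_path / "feats")
    back = data_io.load_features(tmp_path / "feats")
    assert set(back) == set(features)
    for pen in features:
        np.testing.assert_array_equal(back[pen], features[pen])
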