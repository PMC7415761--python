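"""Event containers, grid snapping, table I/O and dataset validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from canishow import (
    BehaviorEvent,
    EventLog,
    EventValidationError,
    FormatError,
    TrialContext,
    load_dataset,
    read_event_log,
    snap_to_grid,
    validate_dataset,
    write_event_log,
    write_metadata,
)
from canishow.io import events_to_frame, read_metadata

from helpers import dog, tiny_log


class TestSnapToGrid:
    @pytest.mark.parametrize("t,expected", [
        (1.03, 1.0),    # nearest multiple of 0.20
        (0.0, 0.0),     # grid point is fixed
        (0.50, 0.60),   # tie rounds half up
        (1.10, 1.20),
        (0.09, 0.0),
    ])
    def test_examples(self, t, expected):
        assert snap_to_grid(t) == pytest.approx(expected, abs=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            snap_to_grid(-0.1)

    def test_bad_resolution_rejected(self):
        with pytest.raises(ValueError):
            snap_to_grid(1.0, resolution=0.0)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.floats(min_value=0.0, max_value=1e4,
                     allow_nan=False, allow_infinity=False))
    def test_idempotent(self, t):
        once = snap_to_grid(t)
        assert snap_to_grid(once) == once


class TestBehaviorEvent:
    def test_box_code_requires_referent(self):
        with pytest.raises(EventValidationError):
            dog("gaze_box", 0.0, 1.0, referent=None)
        with pytest.raises(EventValidationError):
            dog("gaze_box", 0.0, 1.0, referent=5)

    def test_owner_directed_code_rejects_referent(self):
        with pytest.raises(EventValidationError):
            dog("gaze_owner", 0.0, 1.0, referent=2)

    def test_half_open_interval_needs_positive_extent(self):
        with pytest.raises(EventValidationError):
            dog("vocalize", 1.0, 1.0)

    def test_off_grid_time_rejected(self):
        with pytest.raises(EventValidationError, match="grid"):
            dog("vocalize", 1.03, 1.4)

    def test_unknown_code_rejected(self):
        with pytest.raises(EventValidationError):
            BehaviorEvent("dog", "wag_tail", None, 0.0, 0.2)
        with pytest.raises(EventValidationError):
            BehaviorEvent("owner", "gaze_box", 1, 0.0, 0.2)


class TestEventLogContainer:
    def test_events_kept_sorted_after_add(self):
        log = tiny_log([dog("gaze_owner", 5.0, 6.0)])
        log.add(dog("gaze_box", 1.0, 2.0, referent=2))
        assert [e.onset for e in log.events] == [1.0, 5.0]

    def test_retrieve_truncates_analyzable_window(self):
        log = tiny_log([
            dog("near_box", 0.0, 10.0, referent=2),
            BehaviorEvent("dog", "retrieve", None, 4.0, 4.2),
            dog("gaze_owner", 6.0, 7.0),
        ])
        kept = log.analyzable_events()
        assert [e.code for e in kept] == ["near_box"]
        assert kept[0].offset == 4.0  # clipped at the retrieve onset

    def test_choice_phase_lookup(self):
        ctx = TrialContext("p", 1, "far", 1, target_box=3,
                          choice_phase1=0, choice_phase2=3)
        assert ctx.choice(1) == 0
        assert ctx.choice(2) == 3


class TestTableIO:
    def _write_single_row(self, path):
        path.write_text(
            "pair,session,condition,trial,phase,actor,code,referent,onset,offset\n"
            "p01,1,close,1,1,dog,gaze_box,2,1.00,2.00\n")

    def test_single_row_identity(self, tmp_path):
        f = tmp_path / "events.csv"
        self._write_single_row(f)
        logs = read_event_log(f)
        assert len(logs) == 1
        (log,) = logs
        assert log.key == ("p01", 1, 1, 1)
        (e,) = log.events
        assert (e.code, e.referent, e.onset, e.offset) == ("gaze_box", 2, 1.0, 2.0)

    def test_empty_data_section_gives_empty_list(self, tmp_path):
        f = tmp_path / "events.csv"
        f.write_text(
            "pair,session,condition,trial,phase,actor,code,referent,onset,offset\n")
        assert read_event_log(f) == []

    def test_missing_column_is_format_error(self, tmp_path):
        f = tmp_path / "events.csv"
        f.write_text("pair,session\np01,1\n")
        with pytest.raises(FormatError, match="missing required column"):
            read_event_log(f)

    def test_off_grid_row_rejected_unless_snapped(self, tmp_path):
        f = tmp_path / "events.csv"
        f.write_text(
            "pair,session,condition,trial,phase,actor,code,referent,onset,offset\n"
            "p01,1,close,1,1,dog,gaze_box,2,1.03,2.00\n")
        with pytest.raises(EventValidationError, match="grid"):
            read_event_log(f)
        (log,) = read_event_log(f, snap=True)
        assert log.events[0].onset == 1.0

    def test_unknown_code_names_row(self, tmp_path):
        f = tmp_path / "events.csv"
        f.write_text(
            "pair,session,condition,trial,phase,actor,code,referent,onset,offset\n"
            "p01,1,close,1,1,dog,tail_wag,,1.00,2.00\n")
        with pytest.raises(EventValidationError, match="row 0"):
            read_event_log(f)

    def test_round_trip_bit_identical(self, tmp_path, default_dataset):
        logs, contexts, _ = default_dataset
        subset = logs[:12]
        ev, md = tmp_path / "ev.csv", tmp_path / "md.csv"
        write_event_log(subset, ev)
        write_metadata(contexts, md)
        back, _ = load_dataset(ev, md)
        assert events_to_frame(back).equals(events_to_frame(subset))
        # second serialization is byte-identical (stable ordering)
        ev2 = tmp_path / "ev2.csv"
        write_event_log(back, ev2)
        assert ev.read_bytes() == ev2.read_bytes()

    def test_xlsx_ingestion_normalizes_to_long_table(self, tmp_path, default_dataset):
        logs, contexts, _ = default_dataset
        subset = logs[:4]
        xl = tmp_path / "raw.xlsx"
        events_to_frame(subset).to_excel(xl, index=False)
        back = read_event_log(xl, contexts)
        assert events_to_frame(back).equals(events_to_frame(subset))

    def test_metadata_round_trip(self, tmp_path, default_dataset):
        _, contexts, _ = default_dataset
        md = tmp_path / "md.csv"
        write_metadata(contexts, md)
        back = read_metadata(md)
        assert back == contexts


class TestValidateDataset:
    def test_valid_synthetic_dataset_is_clean(self, default_dataset):
        logs, _, _ = default_dataset
        report = validate_dataset(logs)
        assert report.ok
        assert report.design_warnings == []

    def test_event_past_phase_duration_is_violation(self):
        log = tiny_log([dog("gaze_owner", 58.0, 61.0)], phase_duration=60.0)
        report = validate_dataset([log])
        assert len(report.violations) == 1
        assert "phase duration" in report.violations[0]

    def test_consecutive_target_box_design_warning(self):
        logs = []
        for trial, target in [(1, 2), (2, 3), (3, 3)]:
            ctx = TrialContext("p", 1, "close", trial, target_box=target,
                              choice_phase1=1, choice_phase2=1)
            logs.append(EventLog(context=ctx, phase=1, events=[]))
        report = validate_dataset(logs)
        assert report.ok  # warning, not error
        assert any("consecutive trials" in w for w in report.design_warnings)

    def test_overlapping_identical_state_events_flagged(self):
        log = tiny_log([
            dog("near_box", 0.0, 10.0, referent=2),
            dog("near_box", 5.0, 12.0, referent=2),
        ])
        report = validate_dataset([log])
        assert any("overlapping" in v for v in report.violations)
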