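"""Event model: table I/O, stream validation, day splitting, inclusion rule."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import stepday as sd
from stepday.events import (
    DAY_SECONDS,
    ActivityClass,
    Event,
    EventStream,
    EventTableError,
    ObservationDay,
    _split_event,
    select_valid_participants,
    split_into_days,
    validate_stream,
)

from .conftest import make_stream

A = ActivityClass


# -- strategies -------------------------------------------------------------

_activities = st.sampled_from(list(ActivityClass))


@st.composite
def valid_streams(draw, min_events=1, max_events=30):
    n = draw(st.integers(min_events, max_events))
    events = []
    cursor = 0.0
    for _ in range(n):
        act = draw(_activities)
        dur = draw(st.floats(0.5, 7200.0, allow_nan=False))
        strides = draw(st.integers(1, 200)) if act is A.STEPPING else 0
        events.append(Event(start=cursor, duration=dur, activity=act, strides=strides))
        cursor += dur
    return EventStream(origin="2017-03-06T00:00:00", participant_id="H1", events=events)


# -- event invariants -------------------------------------------------------


def test_event_rejects_invalid_fields():
    with pytest.raises(ValueError):
        Event(start=0, duration=0, activity=A.SEDENTARY)
    with pytest.raises(ValueError):
        Event(start=0, duration=10, activity=A.SEDENTARY, strides=3)
    with pytest.raises(ValueError):
        Event(start=0, duration=10, activity=A.STEPPING, strides=-1)


def test_steps_are_twice_strides():
    ev = Event(start=0, duration=30, activity=A.STEPPING, strides=25)
    assert ev.steps == 50


# -- validation -------------------------------------------------------------


def test_contiguous_stream_has_no_violations():
    stream = make_stream([(A.PRIMARY_LYING, 28800.0), (A.SEDENTARY, 43200.0),
                          (A.QUIET_STANDING, 14400.0)])
    assert validate_stream(stream) == []
    assert stream.total_duration == DAY_SECONDS


def test_gap_and_overlap_are_reported_with_index():
    stream = make_stream([(A.SEDENTARY, 100.0), (A.SEDENTARY, 100.0)])
    stream.events[1] = Event(start=102.0, duration=100.0, activity=A.SEDENTARY)
    (v,) = validate_stream(stream)
    assert (v.kind, v.index) == ("gap", 1)

    stream.events[1] = Event(start=95.0, duration=100.0, activity=A.SEDENTARY)
    kinds = {v.kind for v in validate_stream(stream)}
    assert "overlap" in kinds


def test_strides_on_nonstepping_violation():
    stream = make_stream([(A.SEDENTARY, 100.0)])
    object.__setattr__(stream.events[0], "strides", 5)
    (v,) = validate_stream(stream)
    assert v.kind == "strides_on_nonstepping"


# -- table I/O --------------------------------------------------------------


def test_read_three_row_file(tmp_path):
    path = tmp_path / "p.csv"
    path.write_text(
        "# origin=2017-03-06T00:00:00\n# participant=P1\n"
        "start_s,duration_s,activity,strides\n"
        "0.0,28800.0,primary_lying,0\n"
        "28800.0,43200.0,sedentary,0\n"
        "72000.0,14400.0,quiet_standing,0\n"
    )
    stream = sd.read_event_table(path)
    assert len(stream.events) == 3
    assert stream.total_duration == DAY_SECONDS
    assert stream.participant_id == "P1"


def test_read_rejects_gap_with_location(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text(
        "# origin=2017-03-06T00:00:00\n# participant=P1\n"
        "start_s,duration_s,activity,strides\n"
        "0.0,100.0,sedentary,0\n"
        "102.0,100.0,sedentary,0\n"
    )
    with pytest.raises(EventTableError, match="gap at index 1"):
        sd.read_event_table(path)


def test_read_rejects_malformed_row(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text(
        "# origin=2017-03-06T00:00:00\n# participant=P1\n"
        "start_s,duration_s,activity,strides\n"
        "0.0,100.0,sitting_hard,0\n"
    )
    with pytest.raises(EventTableError, match="bad.csv:4"):
        sd.read_event_table(path)


def test_write_empty_and_single_event_stream(tmp_path):
    empty = EventStream(origin="2017-03-06T00:00:00", participant_id="E", events=[])
    sd.write_event_table(empty, tmp_path / "e.csv")
    assert (tmp_path / "e.csv").read_text().count("\n") == 3  # headers only

    one = make_stream([(A.SEDENTARY, 50.0)])
    sd.write_event_table(one, tmp_path / "one.csv")
    back = sd.read_event_table(tmp_path / "one.csv")
    assert back.events == one.events


@settings(max_examples=40, deadline=None)
@given(stream=valid_streams())
def test_roundtrip_is_identity(stream, tmp_path_factory):
    path = tmp_path_factory.mktemp("rt") / "s.csv"
    sd.write_event_table(stream, path)
    back = sd.read_event_table(path)
    assert back.origin == stream.origin
    assert back.participant_id == stream.participant_id
    assert back.events == stream.events


# -- day splitting ----------------------------------------------------------


def test_exact_week_splits_into_seven_valid_days():
    spec = []
    for _ in range(7):
        spec += [(A.PRIMARY_LYING, 28800.0), (A.SEDENTARY, 43200.0),
                 (A.QUIET_STANDING, 14400.0)]
    days = split_into_days(make_stream(spec))
    assert len(days) == 7
    assert all(d.valid for d in days)
    assert [d.day_index for d in days] == list(range(7))


def test_partial_last_day_is_invalid():
    spec = [(A.SEDENTARY, DAY_SECONDS)] * 6 + [(A.SEDENTARY, DAY_SECONDS / 2)]
    days = split_into_days(make_stream(spec))
    assert sum(d.valid for d in days) == 6
    assert not days[-1].valid


def test_straddling_event_is_apportioned_proportionally():
    # 1000 s stepping with 80 strides, 40% before midnight
    spec = [
        (A.SEDENTARY, DAY_SECONDS - 400.0),
        (A.STEPPING, 1000.0, 80),
        (A.SEDENTARY, DAY_SECONDS - 600.0),
    ]
    days = split_into_days(make_stream(spec))
    first_frag = days[0].events[-1]
    second_frag = days[1].events[0]
    assert (first_frag.duration, first_frag.strides) == (400.0, 32)
    assert (second_frag.duration, second_frag.strides) == (600.0, 48)


def test_split_event_rounding_remainder_goes_to_earlier_fragment():
    ev = Event(start=0.0, duration=100.0, activity=A.STEPPING, strides=5)
    first, second = _split_event(ev, 50.0)
    assert (first.strides, second.strides) == (3, 2)


@settings(max_examples=40, deadline=None)
@given(stream=valid_streams(min_events=5, max_events=60))
def test_splitting_conserves_duration_and_strides(stream):
    days = split_into_days(stream)
    assert sum(d.coverage() for d in days) == pytest.approx(stream.total_duration)
    assert sum(e.strides for d in days for e in d.events) == stream.total_strides()
    for d in days:
        if d.valid:
            assert d.coverage() == pytest.approx(DAY_SECONDS, abs=1e-3)


def test_nonmidnight_boundary_shifts_day_starts():
    spec = [(A.SEDENTARY, DAY_SECONDS * 2)]
    days = split_into_days(make_stream(spec), boundary=4 * 3600.0)
    starts = [d.start for d in days]
    assert all((s - 4 * 3600.0) % DAY_SECONDS == 0 for s in starts)
    assert sum(d.valid for d in days) == 1  # only one fully covered window


# -- participant selection --------------------------------------------------


def _days(pid, n_valid, n_invalid=0):
    days = [
        ObservationDay(pid, i, i * DAY_SECONDS, events=[], valid=True)
        for i in range(n_valid)
    ]
    days += [
        ObservationDay(pid, n_valid + j, (n_valid + j) * DAY_SECONDS, valid=False)
        for j in range(n_invalid)
    ]
    return days


def test_selection_requires_enough_valid_days():
    pool = {"A": _days("A", 7), "B": _days("B", 6, 2), "C": _days("C", 9)}
    selected = select_valid_participants(pool, required_days=7)
    assert set(selected) == {"A", "C"}
    assert len(selected["C"]) == 7
    assert [d.day_index for d in selected["C"]] == list(range(7))


def test_selection_rejects_bad_required_days():
    with pytest.raises(ValueError):
        select_valid_participants({}, required_days=0)
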