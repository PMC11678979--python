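"""Shared fixtures: hand-built streams and session-scoped synthetic cohorts.

The cohorts are generated once per session because several test modules
measure different properties of the same simulated study conditions.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import stepday as sd
from stepday.events import DAY_SECONDS, ActivityClass, Event, EventStream

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

A = ActivityClass


def make_stream(spec, participant_id="T01", origin="2017-03-06T00:00:00"):
    """Build a contiguous stream from (activity, duration[, strides]) tuples."""
    events = []
    cursor = 0.0
    for item in spec:
        act, dur, *rest = item
        strides = rest[0] if rest else 0
        events.append(Event(start=cursor, duration=dur, activity=act, strides=strides))
        cursor += dur
    return EventStream(origin=origin, participant_id=participant_id, events=events)


def simple_day_spec(step_strides=0):
    """An 8 h lying / 8 h sedentary / 8 h upright day."""
    upright_dur = 8 * 3600.0
    if step_strides:
        return [
            (A.PRIMARY_LYING, 8 * 3600.0),
            (A.SEDENTARY, 8 * 3600.0),
            (A.QUIET_STANDING, upright_dur - 600.0),
            (A.STEPPING, 600.0, step_strides),
        ]
    return [
        (A.PRIMARY_LYING, 8 * 3600.0),
        (A.SEDENTARY, 8 * 3600.0),
        (A.QUIET_STANDING, upright_dur),
    ]


@pytest.fixture(scope="session")
def presets():
    return sd.level_presets()


@pytest.fixture(scope="session")
def active_cohort():
    """~500 days generated from the 'active' day profile (10k-12.5k steps)."""
    return sd.generate_cohort(
        72, 7, seed=11, level_mix={sd.ActivityLevel.ACTIVE: 1.0}
    )


@pytest.fixture(scope="session")
def active_cohort_summaries(active_cohort):
    out = []
    for stream in active_cohort.streams.values():
        out.extend(sd.analyse_stream(stream))
    return out


@pytest.fixture(scope="session")
def mixed_cohort():
    """A 143-participant week (1001 days) across the default level mix."""
    return sd.generate_cohort(143, 7, seed=5)


@pytest.fixture(scope="session")
def mixed_cohort_summaries(mixed_cohort):
    out = []
    for stream in mixed_cohort.streams.values():
        out.extend(sd.analyse_stream(stream))
    return out
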