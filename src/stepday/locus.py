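"""Time-in-bed detection and the primary locus.

The *primary locus* is the continuous period an individual spends at their
home location surrounding the overnight time-in-bed period.  Travel to and
from the locus shows up in the event stream as *transition events*:
continuous stepping longer than one minute, a period of seated transport, or
a period of cycling.  The locus for a night therefore runs from the end of
the last transition event before the bed period to the start of the first
transition event after it.

Time in bed itself is not directly observable from posture events; it is
approximated as the longest contiguous run of lying/sedentary events that
overlaps a configurable night window (default 21:00-09:00) and contains at
least one primary-lying event.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .events import (
    DAY_SECONDS,
    ActivityClass,
    Event,
    EventStream,
    ObservationDay,
)

#: default night window, seconds after a day's start: 21:00 to 09:00 next day
NIGHT_WINDOW = (21 * 3600.0, 33 * 3600.0)

#: strict threshold (s) above which continuous stepping indicates travel
TRANSITION_STEPPING_SECONDS = 60.0

_BED_CLASSES = frozenset(
    {ActivityClass.PRIMARY_LYING, ActivityClass.SECONDARY_LYING, ActivityClass.SEDENTARY}
)


class TransitionKind(str, enum.Enum):
    LONG_STEPPING = "long_stepping"
    SEATED_TRANSPORT = "seated_transport"
    CYCLING = "cycling"


@dataclass(frozen=True)
class TransitionEvent:
    """An event indicative of travel between two locations."""

    start: float
    duration: float
    kind: TransitionKind

    @property
    def end(self) -> float:
        return self.start + self.duration


@dataclass(frozen=True)
class Interval:
    start: float
    end: float

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    @property
    def duration(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class LocusInterval(Interval):
    """A primary-locus period; ``anchored`` when both bounds are transitions."""

    anchored: bool = True


class LocusUndefinedError(ValueError):
    """No bed period could be detected for the requested day."""


def find_transition_events(
    stream: EventStream,
    stepping_threshold: float = TRANSITION_STEPPING_SECONDS,
) -> list[TransitionEvent]:
    """All transition events of a (stride-merged) stream, in time order.

    A stepping bout qualifies only when strictly longer than
    ``stepping_threshold`` seconds; every seated-transport and cycling event
    qualifies.
    """
    out: list[TransitionEvent] = []
    for ev in stream.events:
        if ev.activity is ActivityClass.STEPPING and ev.duration > stepping_threshold:
            out.append(TransitionEvent(ev.start, ev.duration, TransitionKind.LONG_STEPPING))
        elif ev.activity is ActivityClass.SEATED_TRANSPORT:
            out.append(TransitionEvent(ev.start, ev.duration, TransitionKind.SEATED_TRANSPORT))
        elif ev.activity is ActivityClass.CYCLING:
            out.append(TransitionEvent(ev.start, ev.duration, TransitionKind.CYCLING))
    return out


def _lying_sedentary_runs(stream: EventStream) -> list[tuple[Interval, bool]]:
    """Maximal runs of lying/sedentary events, with a primary-lying flag."""
    runs: list[tuple[Interval, bool]] = []
    run_start: float | None = None
    run_end = 0.0
    has_primary = False
    for ev in stream.events:
        if ev.activity in _BED_CLASSES:
            if run_start is None:
                run_start = ev.start
                has_primary = False
            run_end = ev.end
            has_primary = has_primary or ev.activity is ActivityClass.PRIMARY_LYING
        elif run_start is not None:
            runs.append((Interval(run_start, run_end), has_primary))
            run_start = None
    if run_start is not None:
        runs.append((Interval(run_start, run_end), has_primary))
    return runs


def detect_time_in_bed(
    stream: EventStream,
    day: ObservationDay,
    night_window: tuple[float, float] = NIGHT_WINDOW,
) -> Interval | None:
    """The bed period for the night at the end of ``day``, or ``None``.

    Scans the whole (unsplit) stream so that blocks straddling the midnight
    day boundary are seen intact.  Returns the longest contiguous run of
    lying/sedentary events that overlaps the day's night window and contains
    at least one primary-lying event.
    """
    window = Interval(day.start + night_window[0], day.start + night_window[1])
    candidates = [
        iv
        for iv, has_primary in _lying_sedentary_runs(stream)
        if has_primary and iv.overlaps(window)
    ]
    if not candidates:
        return None
    return max(candidates, key=lambda iv: (iv.duration, -iv.start))


def primary_locus(
    stream: EventStream,
    bed: Interval,
    transitions: list[TransitionEvent] | None = None,
) -> LocusInterval:
    """Locus interval for the night whose bed period is ``bed``.

    The interval runs from the end of the last transition event before the
    bed period to the start of the first transition event after it; absent a
    bounding transition, the corresponding stream end is used and the
    interval is marked unanchored.  The bed period is always contained.
    """
    if bed is None:
        raise LocusUndefinedError("bed period is undefined; locus cannot be computed")
    if transitions is None:
        transitions = find_transition_events(stream)
    before = [t for t in transitions if t.end <= bed.start]
    after = [t for t in transitions if t.start >= bed.end]
    anchored = bool(before) and bool(after)
    start = before[-1].end if before else min(stream.start, bed.start)
    end = after[0].start if after else max(stream.end, bed.end)
    return LocusInterval(start=start, end=end, anchored=anchored)


def in_primary_locus(event: Event, locus: Interval) -> bool:
    """Membership by event midpoint, avoiding double counting at boundaries."""
    return locus.contains(event.midpoint)


def nightly_loci(
    stream: EventStream,
    days: list[ObservationDay],
    night_window: tuple[float, float] = NIGHT_WINDOW,
    stepping_threshold: float = TRANSITION_STEPPING_SECONDS,
) -> dict[int, LocusInterval]:
    """Locus interval per day index (night at the end of each day).

    Days whose bed period cannot be detected are omitted.  The night
    *preceding* the first day (a stream typically begins mid-sleep) is also
    probed and stored under index -1, so that the first morning's at-home
    time has a locus to belong to.
    """
    transitions = find_transition_events(stream, stepping_threshold)
    loci: dict[int, LocusInterval] = {}
    if days:
        before = ObservationDay(
            participant_id=days[0].participant_id,
            day_index=-1,
            start=days[0].start - DAY_SECONDS,
        )
        bed = detect_time_in_bed(stream, before, night_window)
        if bed is not None:
            loci[-1] = primary_locus(stream, bed, transitions)
    for day in days:
        if not day.valid:
            continue
        bed = detect_time_in_bed(stream, day, night_window)
        if bed is None:
            continue
        loci[day.day_index] = primary_locus(stream, bed, transitions)
    return loci


def loci_overlapping_day(
    day: ObservationDay, loci: dict[int, LocusInterval]
) -> list[LocusInterval]:
    """The locus intervals that intersect a day's 24 h window.

    A day's at-home time in the morning belongs to the locus anchored the
    previous evening, so both the preceding night's locus and the day's own
    are usually relevant.
    """
    window = Interval(day.start, day.end)
    seen: list[LocusInterval] = []
    for idx in sorted(loci):
        iv = loci[idx]
        if iv.overlaps(window) and iv not in seen:
            seen.append(iv)
    return seen


def in_any_locus(event: Event, loci: list[LocusInterval]) -> bool:
    return any(in_primary_locus(event, iv) for iv in loci)
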