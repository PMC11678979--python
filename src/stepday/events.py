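"""Domain types for activity-event streams and the event-table file format.

A thigh-worn monitor's export describes behaviour as a sequence of *events*:
each event is one continuous period of a single activity class (lying,
sitting, standing, a stride, ...) with a duration and, for stepping, a stride
count (one stride = two steps).  A valid stream tiles its observation window
exactly: consecutive events neither overlap nor leave gaps.

Times are stored as seconds from the stream origin (a wall-clock timestamp
kept in the stream header), double precision.  The on-disk dialect is plain
CSV with two ``#``-prefixed header lines::

    # origin=2017-03-06T00:00:00
    # participant=P0001
    start_s,duration_s,activity,strides
    0.0,28800.0,primary_lying,0
    ...
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: default contiguity tolerance, seconds
EPSILON = 1e-3

#: seconds in one observation day
DAY_SECONDS = 86_400.0


class ActivityClass(str, enum.Enum):
    """The seven monitor-derived activity classes."""

    PRIMARY_LYING = "primary_lying"
    SECONDARY_LYING = "secondary_lying"
    SEDENTARY = "sedentary"
    QUIET_STANDING = "quiet_standing"
    STEPPING = "stepping"
    SEATED_TRANSPORT = "seated_transport"
    CYCLING = "cycling"


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class Event:
    """One continuous period of a single activity class.

    Parameters
    ----------
    start : float
        Seconds from the stream origin.
    duration : float
        Event length in seconds, strictly positive.
    activity : ActivityClass
    strides : int
        Stride count; positive only for stepping events.  Each stride
        comprises two steps.
    """

    start: float
    duration: float
    activity: ActivityClass
    strides: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"event duration must be > 0, got {self.duration}")
        if self.strides < 0:
            raise ValueError("strides must be non-negative")
        if self.strides > 0 and self.activity is not ActivityClass.STEPPING:
            raise ValueError(
                f"strides > 0 on non-stepping event ({self.activity.value})"
            )

    @property
    def end(self) -> float:
        return self.start + self.duration

    @property
    def midpoint(self) -> float:
        return self.start + 0.5 * self.duration

    @property
    def steps(self) -> int:
        """Steps in the event: two per stride."""
        return 2 * self.strides


@dataclass(frozen=True)
class Participant:
    id: str
    sex: Sex = Sex.UNKNOWN


@dataclass
class EventStream:
    """A time-ordered, gap-free sequence of events for one participant."""

    origin: str
    participant_id: str
    events: list[Event] = field(default_factory=list)

    @property
    def start(self) -> float:
        return self.events[0].start if self.events else 0.0

    @property
    def end(self) -> float:
        return self.events[-1].end if self.events else 0.0

    @property
    def total_duration(self) -> float:
        return sum(e.duration for e in self.events)

    def total_strides(self) -> int:
        return sum(e.strides for e in self.events)


@dataclass
class ObservationDay:
    """A 24 h window of a stream, with events clipped to the window.

    ``start`` is in stream seconds; ``events`` are the (possibly split)
    events covering [start, start + 86400).  ``valid`` means the window is
    fully covered by events.
    """

    participant_id: str
    day_index: int
    start: float
    events: list[Event] = field(default_factory=list)
    valid: bool = True

    @property
    def end(self) -> float:
        return self.start + DAY_SECONDS

    def coverage(self) -> float:
        return sum(e.duration for e in self.events)


@dataclass(frozen=True)
class Violation:
    """A single stream-invariant violation (data, not an exception)."""

    kind: str
    index: int
    detail: str


class EventTableError(ValueError):
    """Malformed or invalid event-table file."""


# ---------------------------------------------------------------------------
# validation


def validate_stream(stream: EventStream, epsilon: float = EPSILON) -> list[Violation]:
    """Check stream invariants; return a list of violations (empty if valid).

    Checked per index i: sortedness, contiguity with the previous event
    (gap/overlap beyond ``epsilon``), positive duration, and stride counts
    confined to stepping events.
    """
    violations: list[Violation] = []
    prev_end: float | None = None
    prev_start = -math.inf
    for i, ev in enumerate(stream.events):
        if ev.start < prev_start:
            violations.append(Violation("unsorted", i, f"start {ev.start} before previous"))
        if prev_end is not None:
            delta = ev.start - prev_end
            if delta > epsilon:
                violations.append(Violation("gap", i, f"gap of {delta:.6g} s before event"))
            elif delta < -epsilon:
                violations.append(
                    Violation("overlap", i, f"overlap of {-delta:.6g} s with previous")
                )
        if ev.duration <= 0:
            violations.append(Violation("nonpositive_duration", i, f"{ev.duration}"))
        if ev.strides > 0 and ev.activity is not ActivityClass.STEPPING:
            violations.append(
                Violation("strides_on_nonstepping", i, ev.activity.value)
            )
        prev_end = ev.end
        prev_start = ev.start
    return violations


def _require_valid(stream: EventStream, epsilon: float = EPSILON) -> None:
    violations = validate_stream(stream, epsilon)
    if violations:
        v = violations[0]
        raise EventTableError(
            f"invalid stream for {stream.participant_id}: {v.kind} at index {v.index} ({v.detail});"
            f" {len(violations)} violation(s) total"
        )


# ---------------------------------------------------------------------------
# file I/O


def read_event_table(path: str | Path, epsilon: float = EPSILON) -> EventStream:
    """Read an event-table CSV into a validated :class:`EventStream`.

    Raises
    ------
    EventTableError
        On missing/malformed headers or rows, or on gap/overlap beyond
        ``epsilon`` (the error names the offending line or event index).
    """
    path = Path(path)
    header: dict[str, str] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" not in body:
                    raise EventTableError(f"{path}:{lineno}: malformed header line {line!r}")
                key, _, value = body.partition("=")
                header[key.strip()] = value.strip()
            else:
                data_lines.append((lineno, line))
    for key in ("origin", "participant"):
        if key not in header:
            raise EventTableError(f"{path}: missing '# {key}=' header line")
    if not data_lines or data_lines[0][1].split(",")[:4] != [
        "start_s",
        "duration_s",
        "activity",
        "strides",
    ]:
        raise EventTableError(f"{path}: missing column header 'start_s,duration_s,activity,strides'")

    events: list[Event] = []
    for lineno, line in data_lines[1:]:
        parts = line.split(",")
        if len(parts) != 4:
            raise EventTableError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
        try:
            ev = Event(
                start=float(parts[0]),
                duration=float(parts[1]),
                activity=ActivityClass(parts[2]),
                strides=int(parts[3]),
            )
        except (ValueError, KeyError) as exc:
            raise EventTableError(f"{path}:{lineno}: {exc}") from exc
        events.append(ev)
    events.sort(key=lambda e: e.start)
    stream = EventStream(origin=header["origin"], participant_id=header["participant"], events=events)
    _require_valid(stream, epsilon)
    return stream


def write_event_table(stream: EventStream, path: str | Path) -> None:
    """Write a stream to the event-table CSV dialect (re-readable, lossless)."""
    path = Path(path)
    lines = [
        f"# origin={stream.origin}",
        f"# participant={stream.participant_id}",
        "start_s,duration_s,activity,strides",
    ]
    for ev in stream.events:
        lines.append(
            f"{float(ev.start)!r},{float(ev.duration)!r},{ev.activity.value},{int(ev.strides)}"
        )
    path.write_text("\n".join(lines) + "\n")


def read_participants(path: str | Path) -> dict[str, Participant]:
    """Read the participant metadata CSV (``participant_id,sex``)."""
    df = pd.read_csv(path, dtype=str)
    out = {}
    for row in df.itertuples(index=False):
        out[row.participant_id] = Participant(id=row.participant_id, sex=Sex(row.sex))
    return out


def write_participants(participants: Iterable[Participant], path: str | Path) -> None:
    df = pd.DataFrame(
        [{"participant_id": p.id, "sex": p.sex.value} for p in participants]
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# day splitting and participant selection


def _split_event(ev: Event, at: float) -> tuple[Event, Event]:
    """Split one event at stream time ``at`` (strictly inside the event).

    Duration and strides are apportioned proportionally; stride counts are
    rounded to the nearest integer with the remainder (and the half-way
    case) going to the earlier fragment, so strides are conserved exactly.
    """
    frac = (at - ev.start) / ev.duration
    first_strides = int(math.floor(ev.strides * frac + 0.5))
    first = dataclasses.replace(
        ev, duration=at - ev.start, strides=first_strides
    )
    second = dataclasses.replace(
        ev, start=at, duration=ev.end - at, strides=ev.strides - first_strides
    )
    return first, second


def split_into_days(
    stream: EventStream,
    boundary: float = 0.0,
    epsilon: float = EPSILON,
) -> list[ObservationDay]:
    """Cut a stream into consecutive 24 h observation days.

    ``boundary`` is the clock time (seconds after the stream origin's
    midnight, i.e. after origin when the origin is itself a midnight) of the
    day boundary; the default 0.0 cuts at midnight.  Events straddling a
    boundary are split proportionally.  Only days with full 86 400 s
    coverage are marked valid.
    """
    _require_valid(stream, epsilon)
    if not stream.events:
        return []
    first_cut = boundary
    while first_cut > stream.start:
        first_cut -= DAY_SECONDS
    days: list[ObservationDay] = []
    day_start = first_cut
    pending = list(stream.events)
    i = 0
    day_events: list[Event] = []

    def flush(day_start: float, day_events: list[Event]) -> None:
        coverage = sum(e.duration for e in day_events)
        days.append(
            ObservationDay(
                participant_id=stream.participant_id,
                day_index=len(days),
                start=day_start,
                events=day_events,
                valid=bool(day_events)
                and abs(coverage - DAY_SECONDS) <= epsilon * max(1, len(day_events)),
            )
        )

    while i < len(pending):
        ev = pending[i]
        day_end = day_start + DAY_SECONDS
        if ev.end <= day_end + epsilon:
            day_events.append(ev)
            i += 1
        elif ev.start >= day_end - epsilon:
            flush(day_start, day_events)
            day_events = []
            day_start = day_end
        else:
            first, second = _split_event(ev, day_end)
            day_events.append(first)
            flush(day_start, day_events)
            day_events = []
            day_start = day_end
            pending[i] = second
    if day_events:
        flush(day_start, day_events)
    return days


def select_valid_participants(
    days_by_participant: Mapping[str, Sequence[ObservationDay]],
    required_days: int = 7,
) -> dict[str, list[ObservationDay]]:
    """Apply the valid-day inclusion rule.

    A participant is included iff it has at least ``required_days`` valid
    observation days; for each included participant exactly the earliest
    ``required_days`` valid days are retained.
    """
    if required_days < 1:
        raise ValueError("required_days must be >= 1")
    selected: dict[str, list[ObservationDay]] = {}
    for pid, days in days_by_participant.items():
        valid = sorted((d for d in days if d.valid), key=lambda d: d.start)
        if len(valid) >= required_days:
            selected[pid] = list(valid[:required_days])
    return selected
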