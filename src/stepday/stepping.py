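"""Stepping events and upright containers.

The monitor emits individual stride events (one stride = two steps).  Every
maximal run of contiguous stepping events is merged into a single *stepping
event* (a bout) characterised by duration, step count and cadence.  *Upright
containers* are maximal runs of upright-posture events (quiet standing,
stepping, cycling) uninterrupted by any sedentary or lying event; each
container carries its longest stepping bout, which later drives its
functional classification.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

from .events import (
    EPSILON,
    ActivityClass,
    Event,
    EventStream,
    ObservationDay,
)

#: activity classes whose primary posture is upright
UPRIGHT_CLASSES = frozenset(
    {ActivityClass.QUIET_STANDING, ActivityClass.STEPPING, ActivityClass.CYCLING}
)


@dataclass(frozen=True)
class SteppingEvent:
    """A maximal bout of continuous stepping."""

    start: float
    duration: float
    steps: int

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("stepping event duration must be > 0")

    @property
    def end(self) -> float:
        return self.start + self.duration

    @property
    def cadence(self) -> float:
        """Stepping intensity in steps per minute."""
        return cadence(self)


def cadence(event: SteppingEvent | Event) -> float:
    """steps x 60 / duration_seconds, in steps per minute."""
    if event.duration <= 0:
        raise ValueError("cadence undefined for zero-duration event")
    return event.steps * 60.0 / event.duration


def merge_strides(stream: EventStream, epsilon: float = EPSILON) -> EventStream:
    """Combine every maximal run of contiguous stepping events into one.

    Non-stepping events pass through untouched; total duration and stride
    counts are conserved.  Idempotent.
    """
    merged: list[Event] = []
    for ev in stream.events:
        if (
            merged
            and ev.activity is ActivityClass.STEPPING
            and merged[-1].activity is ActivityClass.STEPPING
            and abs(ev.start - merged[-1].end) <= epsilon
        ):
            prev = merged[-1]
            merged[-1] = dataclasses.replace(
                prev,
                duration=ev.end - prev.start,
                strides=prev.strides + ev.strides,
            )
        else:
            merged.append(ev)
    return EventStream(
        origin=stream.origin, participant_id=stream.participant_id, events=merged
    )


def as_stepping(event: Event) -> SteppingEvent:
    if event.activity is not ActivityClass.STEPPING:
        raise ValueError(f"not a stepping event: {event.activity.value}")
    return SteppingEvent(start=event.start, duration=event.duration, steps=event.steps)


@dataclass
class UprightContainer:
    """A maximal run of upright events between sedentary/lying interruptions."""

    start: float
    duration: float
    events: list[Event] = field(default_factory=list)

    @property
    def end(self) -> float:
        return self.start + self.duration

    @property
    def midpoint(self) -> float:
        return self.start + 0.5 * self.duration

    def stepping_bouts(self) -> list[SteppingEvent]:
        return [
            as_stepping(e) for e in self.events if e.activity is ActivityClass.STEPPING
        ]

    @property
    def n_steps(self) -> int:
        return sum(e.steps for e in self.events)

    @property
    def stepping_seconds(self) -> float:
        return sum(
            e.duration for e in self.events if e.activity is ActivityClass.STEPPING
        )

    @property
    def longest_stepping(self) -> float:
        """Duration (s) of the longest contained bout, 0.0 if none."""
        bout = longest_stepping_bout(self)
        return bout.duration if bout is not None else 0.0

    @property
    def longest_cadence(self) -> float:
        """Cadence of the longest contained bout, 0.0 if none."""
        bout = longest_stepping_bout(self)
        return bout.cadence if bout is not None else 0.0


def longest_stepping_bout(container: UprightContainer) -> SteppingEvent | None:
    """The maximum-duration bout in the container; ties go to the earliest."""
    bouts = container.stepping_bouts()
    if not bouts:
        return None
    return max(bouts, key=lambda b: (b.duration, -b.start))


def build_upright_containers(day: ObservationDay) -> list[UprightContainer]:
    """Group a day's events into maximal upright containers.

    Expects strides already merged.  Any sedentary or lying event (not only
    sedentary proper) breaks a container; every upright event belongs to
    exactly one container.
    """
    containers: list[UprightContainer] = []
    run: list[Event] = []
    for ev in day.events:
        if ev.activity in UPRIGHT_CLASSES:
            run.append(ev)
        elif run:
            containers.append(_close(run))
            run = []
    if run:
        containers.append(_close(run))
    return containers


def _close(run: list[Event]) -> UprightContainer:
    return UprightContainer(
        start=run[0].start, duration=run[-1].end - run[0].start, events=list(run)
    )
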