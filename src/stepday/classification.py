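"""Primary postures, day-level activity levels, and stepping-behaviour classes.

Three classifications sit on top of the event structure:

* every activity class collapses to one of three *primary postures*
  (lying, sedentary, upright);
* every observation day is classified into one of seven *activity levels*
  by its total step count (very inactive < 2500 steps ... very highly
  active >= 15 000 steps);
* every upright container is classified by the duration of its longest
  continuous stepping bout into a functional *behaviour class*: indoor-type
  (< 1 min; split into primary-locus vs other indoor stepping), community
  (1-10 min) or recreation (10 min +).  Community and recreation jointly
  form "outdoor" stepping.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .events import ActivityClass, ObservationDay
from .locus import Interval
from .stepping import UprightContainer


class PrimaryPosture(str, enum.Enum):
    LYING = "lying"
    SEDENTARY = "sedentary"
    UPRIGHT = "upright"


_POSTURE_MAP = {
    ActivityClass.PRIMARY_LYING: PrimaryPosture.LYING,
    ActivityClass.SECONDARY_LYING: PrimaryPosture.SEDENTARY,
    ActivityClass.SEDENTARY: PrimaryPosture.SEDENTARY,
    ActivityClass.SEATED_TRANSPORT: PrimaryPosture.SEDENTARY,
    ActivityClass.QUIET_STANDING: PrimaryPosture.UPRIGHT,
    ActivityClass.STEPPING: PrimaryPosture.UPRIGHT,
    ActivityClass.CYCLING: PrimaryPosture.UPRIGHT,
}


def posture_of(activity: ActivityClass) -> PrimaryPosture:
    """The fixed total mapping from activity class to primary posture."""
    try:
        return _POSTURE_MAP[activity]
    except KeyError:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown activity class: {activity!r}") from None


class ActivityLevel(enum.Enum):
    """Seven step-count-defined daily activity levels (ordered)."""

    VERY_INACTIVE = ("very_inactive", 0, 2500)
    INACTIVE = ("inactive", 2500, 5000)
    LOW_ACTIVE = ("low_active", 5000, 7500)
    SOMEWHAT_ACTIVE = ("somewhat_active", 7500, 10000)
    ACTIVE = ("active", 10000, 12500)
    HIGHLY_ACTIVE = ("highly_active", 12500, 15000)
    VERY_HIGHLY_ACTIVE = ("very_highly_active", 15000, None)

    def __init__(self, code: str, lo: int, hi: int | None):
        self.code = code
        self.lo = lo
        self.hi = hi

    @property
    def order(self) -> int:
        return list(type(self)).index(self)

    def __lt__(self, other: "ActivityLevel") -> bool:
        return self.order < other.order


def classify_day(steps: int) -> ActivityLevel:
    """Activity level whose half-open step interval [lo, hi) contains ``steps``."""
    if steps < 0:
        raise ValueError("steps must be non-negative")
    for level in ActivityLevel:
        if steps >= level.lo and (level.hi is None or steps < level.hi):
            return level
    raise AssertionError("intervals cover [0, inf)")  # pragma: no cover


def daily_step_count(day: ObservationDay) -> int:
    """Total steps over a day's stepping events (2 x strides)."""
    return sum(e.steps for e in day.events if e.activity is ActivityClass.STEPPING)


class BehaviourClass(str, enum.Enum):
    PRIMARY_LOCUS = "primary_locus_stepping"
    INDOOR = "indoor"
    COMMUNITY = "community"
    RECREATION = "recreation"


#: longest-bout duration bounds (s) for the functional classes
COMMUNITY_BOUT_SECONDS = 60.0
RECREATION_BOUT_SECONDS = 600.0


@dataclass(frozen=True)
class ContainerClass:
    behaviour: BehaviourClass
    locus_unknown: bool = False


def classify_container(
    container: UprightContainer,
    locus: Interval | None,
    community_bound: float = COMMUNITY_BOUT_SECONDS,
    recreation_bound: float = RECREATION_BOUT_SECONDS,
) -> ContainerClass:
    """Functional class of a container by its longest stepping bout.

    Containers whose longest bout is under a minute are indoor-type and are
    split by whether the container midpoint falls inside the primary locus.
    When the locus is unknown, indoor-type containers default to ``indoor``
    with ``locus_unknown`` set.  ``locus`` may be a single interval or a
    sequence of intervals (one per night overlapping the day).
    """
    longest = container.longest_stepping
    if longest >= recreation_bound:
        return ContainerClass(BehaviourClass.RECREATION)
    if longest >= community_bound:
        return ContainerClass(BehaviourClass.COMMUNITY)
    loci = _as_loci(locus)
    if loci is None:
        return ContainerClass(BehaviourClass.INDOOR, locus_unknown=True)
    if any(iv.contains(container.midpoint) for iv in loci):
        return ContainerClass(BehaviourClass.PRIMARY_LOCUS)
    return ContainerClass(BehaviourClass.INDOOR)


def _as_loci(locus) -> list[Interval] | None:
    if locus is None:
        return None
    if isinstance(locus, Interval):
        return [locus]
    loci = list(locus)
    return loci or None


def is_outdoor(behaviour: BehaviourClass) -> bool:
    """Outdoor = a continuous stepping bout longer than 1 min somewhere."""
    return behaviour in (BehaviourClass.COMMUNITY, BehaviourClass.RECREATION)
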