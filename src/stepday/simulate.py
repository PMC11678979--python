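"""Synthetic 24 h event-stream generator with known ground truth.

Real event exports from thigh-worn monitors are restricted-access, so every
pipeline stage is exercised against simulated cohorts instead.  A generated
day tiles 86 400 s exactly and reproduces the qualitative structure of a
free-living day: a nocturnal primary-lying block, a morning at home with
short bursts of household stepping, travel away from home (a long walk,
seated transport, or cycling - all of which read as transition events), a
daytime period away from home mixing short indoor stepping with longer
community bouts and occasional recreation walks (10 min +), travel home,
and an evening wind-down into bed.

Each activity level has a preset day profile.  Preset stepping-minute
compositions (primary-locus / indoor / outdoor) follow the reference
cohort's per-level means, and per-class cadence means are solved per level
so that the minute composition and the level's step-count band are jointly
satisfiable, with indoor-type cadences a fixed offset slower than outdoor
ones.  The generator records per-day ground truth (steps, class
composition, cadences, bed and travel times) so closure tests can compare
pipeline output against construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .classification import ActivityLevel, BehaviourClass
from .events import (
    DAY_SECONDS,
    ActivityClass,
    Event,
    EventStream,
    Participant,
    Sex,
    write_event_table,
    write_participants,
)

# ---------------------------------------------------------------------------
# preset constants

#: truncation bounds for bout cadences, steps/min
CADENCE_BOUNDS = (40.0, 160.0)
#: outdoor bouts are this much faster than indoor-type bouts, steps/min
OUTDOOR_CADENCE_OFFSET = 15.0
#: between-bout cadence SD, steps/min
CADENCE_SD = 8.0

#: per-level mean stepping minutes (primary locus, other indoor, outdoor)
#: that the presets emulate
LEVEL_STEPPING_MINUTES: dict[ActivityLevel, tuple[float, float, float]] = {
    ActivityLevel.VERY_INACTIVE: (16.8, 20.5, 2.7),
    ActivityLevel.INACTIVE: (23.2, 40.4, 14.5),
    ActivityLevel.LOW_ACTIVE: (22.0, 51.0, 33.1),
    ActivityLevel.SOMEWHAT_ACTIVE: (21.1, 56.1, 56.0),
    ActivityLevel.ACTIVE: (20.0, 58.4, 81.1),
    ActivityLevel.HIGHLY_ACTIVE: (18.6, 58.8, 107.3),
    ActivityLevel.VERY_HIGHLY_ACTIVE: (17.1, 53.7, 163.9),
}

#: per-level probability that a day contains recreation stepping
LEVEL_RECREATION_DAY_PROB: dict[ActivityLevel, float] = {
    ActivityLevel.VERY_INACTIVE: 0.001,
    ActivityLevel.INACTIVE: 0.019,
    ActivityLevel.LOW_ACTIVE: 0.084,
    ActivityLevel.SOMEWHAT_ACTIVE: 0.222,
    ActivityLevel.ACTIVE: 0.348,
    ActivityLevel.HIGHLY_ACTIVE: 0.468,
    ActivityLevel.VERY_HIGHLY_ACTIVE: 0.589,
}

#: per-level relative frequency of observation days (cohort mix default)
LEVEL_DAY_WEIGHTS: dict[ActivityLevel, float] = {
    ActivityLevel.VERY_INACTIVE: 869,
    ActivityLevel.INACTIVE: 3685,
    ActivityLevel.LOW_ACTIVE: 5974,
    ActivityLevel.SOMEWHAT_ACTIVE: 5517,
    ActivityLevel.ACTIVE: 3970,
    ActivityLevel.HIGHLY_ACTIVE: 2369,
    ActivityLevel.VERY_HIGHLY_ACTIVE: 2445,
}

# nominal day step target (mean, SD, truncation lo/hi) per level; targets are
# truncated inside the level's band so realised counts (within +-2% of
# target) stay in band
_LEVEL_TARGETS: dict[ActivityLevel, tuple[float, float, float, float]] = {
    ActivityLevel.VERY_INACTIVE: (2000, 250, 1200, 2425),
    ActivityLevel.INACTIVE: (3750, 450, 2600, 4850),
    ActivityLevel.LOW_ACTIVE: (6250, 450, 5150, 7275),
    ActivityLevel.SOMEWHAT_ACTIVE: (8750, 450, 7650, 9700),
    ActivityLevel.ACTIVE: (11250, 450, 10300, 12125),
    ActivityLevel.HIGHLY_ACTIVE: (13750, 450, 12875, 14550),
    ActivityLevel.VERY_HIGHLY_ACTIVE: (17500, 1400, 15500, 21000),
}


@dataclass(frozen=True)
class BoutParams:
    """Log-normal bout-duration parameters (s), clipped to [lo, hi]."""

    median: float
    sigma: float
    lo: float
    hi: float

    def draw(self, rng: np.random.Generator) -> float:
        return float(
            np.clip(rng.lognormal(math.log(self.median), self.sigma), self.lo, self.hi)
        )


#: short-bout containers at home or indoors stay well under the 60 s
#: community boundary so they never read as transitions
_BOUT_PARAMS: dict[BehaviourClass, BoutParams] = {
    BehaviourClass.PRIMARY_LOCUS: BoutParams(18.0, 0.5, 4.0, 55.0),
    BehaviourClass.INDOOR: BoutParams(25.0, 0.5, 5.0, 55.0),
    BehaviourClass.COMMUNITY: BoutParams(140.0, 0.5, 61.0, 590.0),
    BehaviourClass.RECREATION: BoutParams(900.0, 0.35, 605.0, 2400.0),
}

_STAND_PARAMS = BoutParams(20.0, 0.6, 3.0, 90.0)
_WALK_TRAVEL_PARAMS = BoutParams(300.0, 0.4, 90.0, 500.0)
_TRANSPORT_PARAMS = BoutParams(1200.0, 0.5, 300.0, 3600.0)
_CYCLE_PARAMS = BoutParams(900.0, 0.4, 300.0, 2700.0)

#: travel-mode probabilities (walk, seated transport, cycling)
_TRAVEL_MODE_P = (0.35, 0.50, 0.15)


@dataclass(frozen=True)
class ClockTime:
    """A clock time drawn per day: normal (mean, sd), clamped to [lo, hi] (s)."""

    mean: float
    sd: float
    lo: float
    hi: float

    def draw(self, rng: np.random.Generator) -> float:
        return float(np.clip(rng.normal(self.mean, self.sd), self.lo, self.hi))


_WAKE = ClockTime(7.0 * 3600, 1800, 5.0 * 3600, 9.0 * 3600)
_DEPARTURE = ClockTime(8.75 * 3600, 1800, 7.5 * 3600, 11.0 * 3600)
_RETURN = ClockTime(17.5 * 3600, 2700, 13.0 * 3600, 20.0 * 3600)
_BED = ClockTime(22.75 * 3600, 1800, 21.0 * 3600, 23.8 * 3600)


class GenerationError(RuntimeError):
    """The requested profile cannot be realised as a valid 24 h day."""


@dataclass(frozen=True)
class DayProfile:
    """Generator parameters for one day at one activity level."""

    level: ActivityLevel
    target_steps: float
    target_steps_sd: float
    target_bounds: tuple[float, float]
    behaviour_weights: dict[BehaviourClass, float]
    recreation_day_prob: float
    cadence_params: dict[BehaviourClass, tuple[float, float]]
    bout_duration_params: dict[BehaviourClass, BoutParams] = field(
        default_factory=lambda: dict(_BOUT_PARAMS)
    )
    wake: ClockTime = _WAKE
    departure: ClockTime = _DEPARTURE
    home_return: ClockTime = _RETURN
    bed_onset: ClockTime = _BED
    seed: int | None = None

    def __post_init__(self) -> None:
        total = sum(self.behaviour_weights.values())
        if abs(total - 1.0) > 1e-9 or any(
            w < 0 for w in self.behaviour_weights.values()
        ):
            raise ValueError("behaviour_weights must be non-negative and sum to 1")


def level_presets(
    cadence_offset: float = OUTDOOR_CADENCE_OFFSET,
    cadence_sd: float = CADENCE_SD,
    cadence_shift: float = 0.0,
) -> dict[ActivityLevel, DayProfile]:
    """One preset day profile per activity level.

    Per-class cadence means are solved from the level's stepping-minute
    composition (m_pl, m_in, m_out) and nominal step target S via
    ``S = (m_pl + m_in) * k_in + m_out * (k_in + offset)``, so the preset's
    expected minute composition equals the reference means while realised
    step counts land in the level's band.  ``cadence_shift`` adds a constant
    to every class mean (used to inject known sex differences).
    """
    lo, hi = CADENCE_BOUNDS
    presets: dict[ActivityLevel, DayProfile] = {}
    for level, (m_pl, m_in, m_out) in LEVEL_STEPPING_MINUTES.items():
        s_mean, s_sd, s_lo, s_hi = _LEVEL_TARGETS[level]
        total_min = m_pl + m_in + m_out
        k_in = max((s_mean - cadence_offset * m_out) / total_min, lo + 2.0)
        k_out = k_in + cadence_offset
        w_pl = m_pl * k_in / s_mean
        w_in = m_in * k_in / s_mean
        w_out = m_out * k_out / s_mean
        # renormalise the tiny residue from the cadence floor, if any
        norm = w_pl + w_in + w_out
        p_rec = LEVEL_RECREATION_DAY_PROB[level]
        # nominal unconditional recreation step share, for documentation of
        # the expected split of the outdoor budget
        rec_steps_nominal = (
            _BOUT_PARAMS[BehaviourClass.RECREATION].median
            * math.exp(_BOUT_PARAMS[BehaviourClass.RECREATION].sigma ** 2 / 2)
            * k_out
            / 60.0
        )
        w_rec = min(p_rec * rec_steps_nominal / s_mean, 0.9 * w_out / norm)
        presets[level] = DayProfile(
            level=level,
            target_steps=s_mean,
            target_steps_sd=s_sd,
            target_bounds=(s_lo, s_hi),
            behaviour_weights={
                BehaviourClass.PRIMARY_LOCUS: w_pl / norm,
                BehaviourClass.INDOOR: w_in / norm,
                BehaviourClass.COMMUNITY: w_out / norm - w_rec,
                BehaviourClass.RECREATION: w_rec,
            },
            recreation_day_prob=p_rec,
            cadence_params={
                BehaviourClass.PRIMARY_LOCUS: (k_in + cadence_shift, cadence_sd),
                BehaviourClass.INDOOR: (k_in + cadence_shift, cadence_sd),
                BehaviourClass.COMMUNITY: (k_out + cadence_shift, cadence_sd),
                BehaviourClass.RECREATION: (k_out + cadence_shift, cadence_sd),
            },
        )
    return presets


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class DayGroundTruth:
    """What the generator actually emitted for one day (realised, not nominal).

    ``wake``/``bed_onset`` are the lying-block boundaries and
    ``departure``/``return_end`` the travel transition anchors (first
    outbound transition start, last homebound transition end), all in
    absolute stream seconds taken from the emitted events, so the night-i
    locus is exactly ``[return_end(day i), departure(day i+1)]``.
    """

    participant_id: str
    day_index: int
    target_level: ActivityLevel
    target_steps: float
    steps: int
    class_steps: dict[BehaviourClass, int]
    class_minutes: dict[BehaviourClass, float]
    class_cadence: dict[BehaviourClass, float | None]
    wake: float
    bed_onset: float
    departure: float | None
    return_end: float | None
    travel_out: str | None
    travel_back: str | None
    has_recreation: bool

    def to_row(self) -> dict:
        row = {
            "participant_id": self.participant_id,
            "day_index": self.day_index,
            "target_level": self.target_level.code,
            "target_steps": self.target_steps,
            "true_steps": self.steps,
            "wake_s": self.wake,
            "bed_onset_s": self.bed_onset,
            "departure_s": self.departure,
            "return_end_s": self.return_end,
            "travel_out": self.travel_out,
            "travel_back": self.travel_back,
            "has_recreation": self.has_recreation,
        }
        for b in BehaviourClass:
            row[f"true_steps_{b.value}"] = self.class_steps[b]
            row[f"true_minutes_{b.value}"] = self.class_minutes[b]
            row[f"true_cadence_{b.value}"] = self.class_cadence[b]
        return row


# ---------------------------------------------------------------------------
# low-level helpers


def _tnorm(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    """Truncated-normal draw by rejection (falls back to clamping)."""
    for _ in range(64):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(min(max(mean, lo), hi))


@dataclass
class _Bout:
    duration: float
    strides: int

    @property
    def steps(self) -> int:
        return 2 * self.strides


class _StrideRounder:
    """Round raw (float) step counts to whole strides, conserving the total."""

    def __init__(self) -> None:
        self.carry = 0.0

    def strides(self, raw_steps: float) -> int:
        x = raw_steps + self.carry
        n = int(math.floor(x / 2.0 + 0.5))
        self.carry = x - 2 * n
        return n


def _draw_bouts(
    rng: np.random.Generator,
    budget: float,
    params: BoutParams,
    cadence: tuple[float, float],
    rounder: _StrideRounder,
) -> tuple[list[_Bout], float]:
    """Draw bouts totalling ``budget`` steps; return (bouts, unspent leftover).

    The final bout is fitted exactly to the remaining budget by adjusting
    its duration (and, if the class duration bounds bind, its cadence)
    within the legal cadence range; a remainder too small to realise at the
    class's minimum duration is returned as leftover.
    """
    lo_c, hi_c = CADENCE_BOUNDS
    bouts: list[_Bout] = []
    remaining = budget
    while remaining > 0.5:
        k = _tnorm(rng, cadence[0], cadence[1], lo_c, hi_c)
        d = params.draw(rng)
        raw = d * k / 60.0
        if raw < remaining - 0.5:
            n = rounder.strides(raw)
            if n > 0:
                bouts.append(_Bout(duration=d, strides=n))
            remaining -= raw
            continue
        # final fit
        d_fit = 60.0 * remaining / k
        if d_fit < params.lo:
            k_fit = 60.0 * remaining / params.lo
            if k_fit < lo_c:
                return bouts, remaining  # too small to realise in this class
            d_fit = params.lo
        elif d_fit > params.hi:
            # cap at the longest legal bout and keep drawing
            n = rounder.strides(params.hi * k / 60.0)
            if n > 0:
                bouts.append(_Bout(duration=params.hi, strides=n))
            remaining -= params.hi * k / 60.0
            continue
        n = rounder.strides(remaining)
        if n > 0:
            bouts.append(_Bout(duration=d_fit, strides=n))
        remaining = 0.0
    return bouts, max(remaining, 0.0)


# a container is a list of (activity, duration, strides) triples
_Seq = list[tuple[ActivityClass, float, int]]


def _container(rng: np.random.Generator, bouts: list[_Bout]) -> _Seq:
    """Wrap bouts in quiet standing: stand, bout, stand, bout, ..., stand."""
    seq: _Seq = [(ActivityClass.QUIET_STANDING, _STAND_PARAMS.draw(rng), 0)]
    for b in bouts:
        seq.append((ActivityClass.STEPPING, b.duration, b.strides))
        seq.append((ActivityClass.QUIET_STANDING, _STAND_PARAMS.draw(rng), 0))
    return seq


def _group_into_containers(
    rng: np.random.Generator, bouts: list[_Bout], max_per_container: int
) -> list[_Seq]:
    containers: list[_Seq] = []
    i = 0
    while i < len(bouts):
        n = int(rng.integers(1, max_per_container + 1))
        containers.append(_container(rng, bouts[i : i + n]))
        i += n
    return containers


def _seq_duration(seq: _Seq) -> float:
    return sum(d for _, d, _ in seq)


def _fill_segment(
    rng: np.random.Generator,
    length: float,
    containers: list[_Seq],
    lie_prob: float = 0.0,
) -> _Seq:
    """Tile a segment exactly: sedentary gaps interleaved with containers.

    Every container is flanked by sedentary time on both sides (so upright
    containers never merge across a segment fill).  With probability
    ``lie_prob`` a long gap carries a secondary-lying spell.
    """
    total_c = sum(_seq_duration(c) for c in containers)
    n_gaps = len(containers) + 1
    gap_total = length - total_c
    if gap_total < n_gaps * 1.0:
        raise GenerationError(
            f"segment of {length:.0f} s cannot hold {total_c:.0f} s of upright time"
        )
    weights = rng.exponential(1.0, size=n_gaps) + 0.05
    gaps = gap_total * weights / weights.sum()
    out: _Seq = []
    for i, gap in enumerate(gaps):
        if gap > 2400.0 and rng.random() < lie_prob:
            lie = min(gap * rng.uniform(0.3, 0.6), 5400.0)
            out.append((ActivityClass.SEDENTARY, gap - lie, 0))
            out.append((ActivityClass.SECONDARY_LYING, lie, 0))
        else:
            out.append((ActivityClass.SEDENTARY, gap, 0))
        if i < len(containers):
            out.extend(containers[i])
    # absorb float residue into the final gap
    residue = length - _seq_duration(out)
    act, d, s = out[-1]
    out[-1] = (act, d + residue, s)
    return out


# ---------------------------------------------------------------------------
# day generation


def generate_day(
    profile: DayProfile,
    rng: np.random.Generator | None = None,
    participant_id: str = "SYN",
    day_index: int = 0,
    origin: str = "2017-03-06T00:00:00",
) -> tuple[EventStream, DayGroundTruth]:
    """Generate one 24 h event stream plus its ground truth.

    Deterministic given ``profile.seed`` (or an explicit ``rng``).  Raises
    :class:`GenerationError` when the profile cannot fit in the day (for
    example a step target unachievable at the profile's cadences).
    """
    if rng is None:
        rng = np.random.default_rng(profile.seed)
    seq, truth, anchors = _build_day(profile, rng, participant_id, day_index)
    events = _seq_to_events(seq, offset=0.0)
    _realise_truth_times(truth, events, anchors)
    stream = EventStream(origin=origin, participant_id=participant_id, events=events)
    return stream, truth


def _realise_truth_times(
    truth: "DayGroundTruth", events: list[Event], anchors: tuple[int, int]
) -> None:
    """Overwrite intended clock times with the emitted event boundaries, in
    absolute stream seconds, so closure checks can demand exact equality."""
    i_out, i_back = anchors
    truth.wake = events[1].start
    truth.bed_onset = events[-1].start
    truth.departure = events[i_out].start
    truth.return_end = events[i_back].end


def _seq_to_events(seq: _Seq, offset: float) -> list[Event]:
    events = []
    cursor = offset
    for act, dur, strides in seq:
        events.append(Event(start=cursor, duration=dur, activity=act, strides=strides))
        cursor += dur
    return events


def _build_day(
    profile: DayProfile,
    rng: np.random.Generator,
    participant_id: str,
    day_index: int,
) -> tuple[_Seq, DayGroundTruth]:
    lo_t, hi_t = profile.target_bounds
    target = _tnorm(rng, profile.target_steps, profile.target_steps_sd, lo_t, hi_t)

    wake = profile.wake.draw(rng)
    bed_onset = profile.bed_onset.draw(rng)
    departure = min(profile.departure.draw(rng), bed_onset - 4 * 3600)
    departure = max(departure, wake + 1200)
    home_return = float(
        np.clip(profile.home_return.draw(rng), departure + 3600, bed_onset - 3600)
    )

    w = profile.behaviour_weights
    b_out = (w[BehaviourClass.COMMUNITY] + w[BehaviourClass.RECREATION]) * target
    b_in = w[BehaviourClass.INDOOR] * target
    b_pl = target - b_out - b_in

    cad = profile.cadence_params
    rounder = _StrideRounder()

    # --- travel legs -------------------------------------------------------
    def travel_leg() -> tuple[str, _Seq, float]:
        """Returns (mode, sequence, outdoor steps consumed)."""
        nonlocal b_out
        mode = ["walk", "seated_transport", "cycling"][
            int(rng.choice(3, p=_TRAVEL_MODE_P))
        ]
        if mode == "walk" and target > 0:
            k = _tnorm(rng, *cad[BehaviourClass.COMMUNITY], *CADENCE_BOUNDS)
            d = _WALK_TRAVEL_PARAMS.draw(rng)
            raw = d * k / 60.0
            if raw <= 0.5 * b_out:
                n = rounder.strides(raw)
                if n > 0:
                    b_out -= raw
                    return "walk", _container(rng, [_Bout(d, n)]), raw
            mode = "seated_transport"
        if mode == "cycling":
            return "cycling", [(ActivityClass.CYCLING, _CYCLE_PARAMS.draw(rng), 0)], 0.0
        return (
            "seated_transport",
            [(ActivityClass.SEATED_TRANSPORT, _TRANSPORT_PARAMS.draw(rng), 0)],
            0.0,
        )

    travel_out_mode, travel_out_seq, _ = travel_leg()
    travel_back_mode, travel_back_seq, _ = travel_leg()

    # --- recreation --------------------------------------------------------
    rec_params = profile.bout_duration_params[BehaviourClass.RECREATION]
    rec_bouts: list[_Bout] = []
    if rng.random() < profile.recreation_day_prob and b_out > 0:
        k = _tnorm(rng, *cad[BehaviourClass.RECREATION], *CADENCE_BOUNDS)
        d = rec_params.draw(rng)
        if d * k / 60.0 > 0.8 * b_out:
            d = 0.8 * b_out * 60.0 / k
        if d >= rec_params.lo:
            n = rounder.strides(d * k / 60.0)
            rec_bouts.append(_Bout(d, n))
            b_out -= d * k / 60.0

    # --- stepping budgets, cascading leftovers down-class ------------------
    com_bouts, leftover = _draw_bouts(
        rng, b_out, profile.bout_duration_params[BehaviourClass.COMMUNITY],
        cad[BehaviourClass.COMMUNITY], rounder,
    )
    in_bouts, leftover = _draw_bouts(
        rng, b_in + leftover, profile.bout_duration_params[BehaviourClass.INDOOR],
        cad[BehaviourClass.INDOOR], rounder,
    )
    pl_bouts, _ = _draw_bouts(
        rng, b_pl + leftover, profile.bout_duration_params[BehaviourClass.PRIMARY_LOCUS],
        cad[BehaviourClass.PRIMARY_LOCUS], rounder,
    )

    # --- containers --------------------------------------------------------
    pl_containers = _group_into_containers(rng, pl_bouts, 4)
    out_containers = (
        _group_into_containers(rng, in_bouts, 4)
        + _group_into_containers(rng, com_bouts, 2)
        + [_container(rng, [b]) for b in rec_bouts]
    )
    if target == 0 or not pl_containers:
        # a couple of standing-only spells so the day is not purely seated
        pl_containers = pl_containers + [_container(rng, []), _container(rng, [])]
    out_containers = [
        out_containers[j] for j in rng.permutation(len(out_containers))
    ]

    # --- segment placement -------------------------------------------------
    travel_out_len = _seq_duration(travel_out_seq)
    travel_back_len = _seq_duration(travel_back_seq)
    out_start = departure + travel_out_len
    out_end = home_return - travel_back_len
    out_needed = sum(_seq_duration(c) for c in out_containers)
    deficit = out_needed * 1.15 + 600 - (out_end - out_start)
    if deficit > 0:
        # widen the away-from-home window within its clamps
        shift = deficit / 2
        departure = max(wake + 1200, departure - shift)
        home_return = min(bed_onset - 3600, home_return + shift)
        out_start = departure + travel_out_len
        out_end = home_return - travel_back_len
        if out_needed * 1.1 + 300 > (out_end - out_start):
            raise GenerationError(
                f"step target {target:.0f} does not fit in the away-from-home window"
            )

    morning_len = departure - wake
    evening_len = bed_onset - home_return
    morning_containers: list[_Seq] = []
    evening_containers: list[_Seq] = []
    p_morning = morning_len / (morning_len + evening_len)
    for c in pl_containers:
        (morning_containers if rng.random() < p_morning else evening_containers).append(c)

    def rebalance(src: list[_Seq], dst: list[_Seq], cap: float) -> None:
        while src and sum(_seq_duration(c) for c in src) > cap:
            dst.append(src.pop())

    rebalance(morning_containers, evening_containers, 0.7 * morning_len)
    rebalance(evening_containers, morning_containers, 0.7 * evening_len)
    if sum(_seq_duration(c) for c in morning_containers) > 0.8 * morning_len:
        raise GenerationError("at-home stepping does not fit around the travel times")

    seq: _Seq = [(ActivityClass.PRIMARY_LYING, wake, 0)]
    seq += _fill_segment(rng, departure - wake, morning_containers)
    i_out_base = len(seq)
    seq += travel_out_seq
    seq += _fill_segment(rng, out_end - out_start, out_containers)
    i_back_base = len(seq)
    seq += travel_back_seq
    seq += _fill_segment(rng, bed_onset - home_return, evening_containers, lie_prob=0.25)
    seq.append((ActivityClass.PRIMARY_LYING, DAY_SECONDS - bed_onset, 0))

    def _qualifies(item: tuple[ActivityClass, float, int]) -> bool:
        act, d, _ = item
        return act in (ActivityClass.SEATED_TRANSPORT, ActivityClass.CYCLING) or (
            act is ActivityClass.STEPPING and d > 60.0
        )

    # anchor event indices: first transition of the outbound leg, last of the
    # homebound leg (walk bouts are flanked by standing, which never qualifies)
    i_out = next(
        (i_out_base + j for j, item in enumerate(travel_out_seq) if _qualifies(item)),
        i_out_base,
    )
    i_back = i_back_base
    for j, item in enumerate(travel_back_seq):
        if _qualifies(item):
            i_back = i_back_base + j

    # --- realised ground truth --------------------------------------------
    class_bouts: dict[BehaviourClass, list[_Bout]] = {
        BehaviourClass.PRIMARY_LOCUS: pl_bouts,
        BehaviourClass.INDOOR: in_bouts,
        BehaviourClass.COMMUNITY: list(com_bouts),
        BehaviourClass.RECREATION: rec_bouts,
    }
    # travel walks are community-class bouts; recover them from the legs
    for mode, leg in ((travel_out_mode, travel_out_seq), (travel_back_mode, travel_back_seq)):
        if mode == "walk":
            for act, d, s in leg:
                if act is ActivityClass.STEPPING:
                    class_bouts[BehaviourClass.COMMUNITY] = class_bouts[
                        BehaviourClass.COMMUNITY
                    ] + [_Bout(d, s)]

    class_steps = {b: sum(x.steps for x in bl) for b, bl in class_bouts.items()}
    class_minutes = {
        b: sum(x.duration for x in bl) / 60.0 for b, bl in class_bouts.items()
    }
    class_cadence: dict[BehaviourClass, float | None] = {}
    for b, bl in class_bouts.items():
        minutes = class_minutes[b]
        class_cadence[b] = (
            sum((x.steps / (x.duration / 60.0)) * (x.duration / 60.0) for x in bl)
            / minutes
            if minutes > 0
            else None
        )

    truth = DayGroundTruth(
        participant_id=participant_id,
        day_index=day_index,
        target_level=profile.level,
        target_steps=target,
        steps=sum(class_steps.values()),
        class_steps=class_steps,
        class_minutes=class_minutes,
        class_cadence=class_cadence,
        wake=wake,
        bed_onset=bed_onset,
        departure=departure,
        return_end=home_return,
        travel_out=travel_out_mode,
        travel_back=travel_back_mode,
        has_recreation=bool(rec_bouts),
    )
    return seq, truth, (i_out, i_back)


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class Cohort:
    """In-memory synthetic cohort: streams, metadata and ground truth."""

    streams: dict[str, EventStream]
    participants: dict[str, Participant]
    truths: list[DayGroundTruth]

    def manifest(self) -> pd.DataFrame:
        rows = []
        for t in self.truths:
            row = t.to_row()
            row["sex"] = self.participants[t.participant_id].sex.value
            rows.append(row)
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for pid, stream in self.streams.items():
            write_event_table(stream, out_dir / f"{pid}.csv")
        write_participants(self.participants.values(), out_dir / "participants.csv")
        self.manifest().to_csv(out_dir / "ground_truth.csv", index=False)


def generate_participant(
    pid: str,
    profiles: list[DayProfile],
    rng: np.random.Generator,
    origin: str = "2017-03-06T00:00:00",
) -> tuple[EventStream, list[DayGroundTruth]]:
    """Concatenate per-day generations into one multi-day stream.

    Contiguous primary-lying events across midnight boundaries are merged so
    nocturnal blocks straddle the boundary, as they would in a real export.
    """
    events: list[Event] = []
    truths: list[DayGroundTruth] = []
    for day_index, profile in enumerate(profiles):
        seq, truth, anchors = _build_day(profile, rng, pid, day_index)
        day_events = _seq_to_events(seq, offset=day_index * DAY_SECONDS)
        _realise_truth_times(truth, day_events, anchors)
        if (
            events
            and events[-1].activity is ActivityClass.PRIMARY_LYING
            and day_events[0].activity is ActivityClass.PRIMARY_LYING
        ):
            last = events.pop()
            day_events[0] = Event(
                start=last.start,
                duration=last.duration + day_events[0].duration,
                activity=ActivityClass.PRIMARY_LYING,
            )
        events.extend(day_events)
        truths.append(truth)
    return EventStream(origin=origin, participant_id=pid, events=events), truths


def _participant_day_levels(
    rng: np.random.Generator,
    n_days: int,
    level_mix: dict[ActivityLevel, float],
) -> list[ActivityLevel]:
    """Base level drawn from the mix; each day jitters one level up or down.

    This yields the observed pattern that most individuals span several
    activity levels over a week rather than sitting at a single one.
    """
    levels = list(ActivityLevel)
    p = np.array([level_mix.get(lv, 0.0) for lv in levels], dtype=float)
    p = p / p.sum()
    base = int(rng.choice(len(levels), p=p))
    out = []
    for _ in range(n_days):
        delta = int(rng.choice([-1, 0, 1], p=[0.25, 0.5, 0.25]))
        out.append(levels[int(np.clip(base + delta, 0, len(levels) - 1))])
    return out


def generate_cohort(
    n_participants: int,
    days_per_participant: int = 7,
    level_mix: dict[ActivityLevel, float] | None = None,
    seed: int = 0,
    male_cadence_shift: float = 0.0,
    presets: dict[ActivityLevel, DayProfile] | None = None,
    out_dir: str | Path | None = None,
    origin: str = "2017-03-06T00:00:00",
) -> Cohort:
    """Generate a reproducible synthetic cohort.

    Each participant gets an independent generator spawned from ``seed`` and
    its index, so cohorts are deterministic and participants independent.
    ``male_cadence_shift`` adds a known cadence offset (steps/min) to every
    bout of male participants, for power analyses of the sex comparisons.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    if level_mix is None:
        level_mix = dict(LEVEL_DAY_WEIGHTS)
    if presets is None:
        presets = level_presets()
    shifted = (
        level_presets(cadence_shift=male_cadence_shift)
        if male_cadence_shift
        else presets
    )
    streams: dict[str, EventStream] = {}
    participants: dict[str, Participant] = {}
    truths: list[DayGroundTruth] = []
    root = np.random.SeedSequence(seed)
    children = root.spawn(n_participants)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        pid = f"P{i:04d}"
        sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
        table = shifted if sex is Sex.MALE else presets
        day_levels = _participant_day_levels(rng, days_per_participant, level_mix)
        profiles = [table[lv] for lv in day_levels]
        stream, ptruths = generate_participant(pid, profiles, rng, origin=origin)
        streams[pid] = stream
        participants[pid] = Participant(id=pid, sex=sex)
        truths.extend(ptruths)
    cohort = Cohort(streams=streams, participants=participants, truths=truths)
    if out_dir is not None:
        cohort.write(out_dir)
    return cohort
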