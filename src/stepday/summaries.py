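"""Day-level summaries, per-level aggregates, and statistical comparisons.

A :class:`DailySummary` condenses one valid observation day: hours per
primary posture (summing to 24), hours inside the primary locus, stepping
minutes per behaviour class, total steps, and the cadence composition of
its stepping.  Aggregation by activity level yields the per-level means and
standard deviations, the share of stepping classed as outdoor, and the
proportion of days containing recreation stepping.  One-way ANOVAs compare
posture time across levels and Bonferroni-corrected Welch t-tests compare
cadence between sexes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classification import (
    ActivityLevel,
    BehaviourClass,
    PrimaryPosture,
    classify_container,
    classify_day,
    daily_step_count,
    posture_of,
)
from .events import EventStream, ObservationDay, Participant, Sex, split_into_days
from .locus import LocusInterval, in_any_locus, loci_overlapping_day, nightly_loci
from .stepping import UprightContainer, build_upright_containers, merge_strides

#: default cadence histogram bin width, steps per minute
CADENCE_BIN_WIDTH = 5.0


@dataclass(frozen=True)
class BoutRecord:
    """One stepping bout's contribution to the cadence composition."""

    behaviour: BehaviourClass
    cadence: float
    minutes: float


@dataclass
class DailySummary:
    participant_id: str
    day_index: int
    steps: int
    activity_level: ActivityLevel
    posture_hours: dict[PrimaryPosture, float]
    locus_hours: float
    stepping_minutes: dict[BehaviourClass, float]
    bouts: list[BoutRecord] = field(default_factory=list)
    locus_known: bool = True

    @property
    def total_stepping_minutes(self) -> float:
        return sum(self.stepping_minutes.values())

    def mean_cadence(self, behaviour: BehaviourClass) -> float | None:
        """Time-weighted mean cadence over the day's bouts of one class."""
        num = den = 0.0
        for b in self.bouts:
            if b.behaviour is behaviour:
                num += b.cadence * b.minutes
                den += b.minutes
        return num / den if den > 0 else None

    def cadence_histogram(
        self, bin_width: float = CADENCE_BIN_WIDTH
    ) -> dict[tuple[BehaviourClass, float], float]:
        """Stepping minutes per (behaviour, cadence-bin-lower-edge)."""
        hist: dict[tuple[BehaviourClass, float], float] = {}
        for b in self.bouts:
            lo = math.floor(b.cadence / bin_width) * bin_width
            key = (b.behaviour, lo)
            hist[key] = hist.get(key, 0.0) + b.minutes
        return hist


def summarise_day(
    day: ObservationDay,
    containers: list[UprightContainer] | None = None,
    loci: list[LocusInterval] | None = None,
) -> DailySummary:
    """Summarise one valid observation day.

    ``containers`` defaults to the containers built from the day's events
    (strides must already be merged); ``loci`` is the list of primary-locus
    intervals overlapping the day (empty/None when the bed period was
    undetectable, in which case indoor-type stepping cannot be split off as
    primary-locus stepping and ``locus_known`` is False).
    """
    if containers is None:
        containers = build_upright_containers(day)
    posture_seconds = {p: 0.0 for p in PrimaryPosture}
    locus_seconds = 0.0
    for ev in day.events:
        posture_seconds[posture_of(ev.activity)] += ev.duration
        if loci and in_any_locus(ev, loci):
            locus_seconds += ev.duration

    stepping_minutes = {b: 0.0 for b in BehaviourClass}
    bouts: list[BoutRecord] = []
    locus_known = bool(loci)
    for container in containers:
        cc = classify_container(container, loci)
        stepping_minutes[cc.behaviour] += container.stepping_seconds / 60.0
        for bout in container.stepping_bouts():
            bouts.append(
                BoutRecord(cc.behaviour, bout.cadence, bout.duration / 60.0)
            )

    steps = daily_step_count(day)
    return DailySummary(
        participant_id=day.participant_id,
        day_index=day.day_index,
        steps=steps,
        activity_level=classify_day(steps),
        posture_hours={p: s / 3600.0 for p, s in posture_seconds.items()},
        locus_hours=locus_seconds / 3600.0,
        stepping_minutes=stepping_minutes,
        bouts=bouts,
        locus_known=locus_known,
    )


def analyse_stream(
    stream: EventStream,
    boundary: float = 0.0,
    night_window: tuple[float, float] | None = None,
    stepping_threshold: float | None = None,
) -> list[DailySummary]:
    """Full per-day pipeline: merge strides, split days, detect loci, summarise.

    Only valid (fully covered) days are summarised.
    """
    merged = merge_strides(stream)
    days = split_into_days(merged, boundary=boundary)
    kwargs: dict = {}
    if night_window is not None:
        kwargs["night_window"] = night_window
    if stepping_threshold is not None:
        kwargs["stepping_threshold"] = stepping_threshold
    loci = nightly_loci(merged, days, **kwargs)
    out = []
    for day in days:
        if not day.valid:
            continue
        day_loci = loci_overlapping_day(day, loci)
        out.append(summarise_day(day, loci=day_loci))
    return out


# ---------------------------------------------------------------------------
# aggregation


@dataclass
class LevelAggregate:
    activity_level: ActivityLevel
    n_days: int
    means: dict[str, float]
    sds: dict[str, float]
    outdoor_pct: float
    recreation_day_pct: float


_QUANTITIES = (
    ["steps", "locus_hours"]
    + [f"hours_{p.value}" for p in PrimaryPosture]
    + [f"minutes_{b.value}" for b in BehaviourClass]
)


def _summary_row(s: DailySummary) -> dict[str, float]:
    row: dict[str, float] = {"steps": float(s.steps), "locus_hours": s.locus_hours}
    for p in PrimaryPosture:
        row[f"hours_{p.value}"] = s.posture_hours[p]
    for b in BehaviourClass:
        row[f"minutes_{b.value}"] = s.stepping_minutes[b]
    return row


def aggregate_by_level(summaries: list[DailySummary]) -> list[LevelAggregate]:
    """Per-level means/SDs, outdoor share and recreation-day proportion.

    ``outdoor_pct`` is 100 x outdoor / (indoor + outdoor) stepping minutes,
    where the indoor term excludes primary-locus stepping;
    ``recreation_day_pct`` is the percentage of the level's days containing
    at least one recreation container.
    """
    out: list[LevelAggregate] = []
    by_level: dict[ActivityLevel, list[DailySummary]] = {}
    for s in summaries:
        by_level.setdefault(s.activity_level, []).append(s)
    for level in ActivityLevel:
        group = by_level.get(level)
        if not group:
            continue
        frame = pd.DataFrame([_summary_row(s) for s in group])
        means = frame.mean().to_dict()
        sds = frame.std(ddof=1).fillna(0.0).to_dict()
        indoor = means[f"minutes_{BehaviourClass.INDOOR.value}"]
        outdoor = (
            means[f"minutes_{BehaviourClass.COMMUNITY.value}"]
            + means[f"minutes_{BehaviourClass.RECREATION.value}"]
        )
        denom = indoor + outdoor
        outdoor_pct = 100.0 * outdoor / denom if denom > 0 else 0.0
        rec_days = sum(
            1 for s in group if s.stepping_minutes[BehaviourClass.RECREATION] > 0
        )
        out.append(
            LevelAggregate(
                activity_level=level,
                n_days=len(group),
                means=means,
                sds=sds,
                outdoor_pct=outdoor_pct,
                recreation_day_pct=100.0 * rec_days / len(group),
            )
        )
    return out


def summaries_to_frame(summaries: list[DailySummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = {
            "participant_id": s.participant_id,
            "day_index": s.day_index,
            "activity_level": s.activity_level.code,
            "locus_known": s.locus_known,
        }
        row.update(_summary_row(s))
        rows.append(row)
    return pd.DataFrame(rows)


def aggregates_to_frame(aggregates: list[LevelAggregate]) -> pd.DataFrame:
    rows = []
    for a in aggregates:
        row: dict = {"activity_level": a.activity_level.code, "n_days": a.n_days}
        for q in _QUANTITIES:
            row[f"mean_{q}"] = a.means[q]
            row[f"sd_{q}"] = a.sds[q]
        row["outdoor_pct"] = a.outdoor_pct
        row["recreation_day_pct"] = a.recreation_day_pct
        rows.append(row)
    return pd.DataFrame(rows)


def cadence_distribution(
    summaries: list[DailySummary],
    level: ActivityLevel | None = None,
    behaviour: BehaviourClass | None = None,
    bin_width: float = CADENCE_BIN_WIDTH,
) -> pd.Series:
    """Histogram of stepping minutes by cadence bin for a (level, behaviour) cell.

    Bins are half-open ``[k*w, (k+1)*w)``; the returned series is indexed by
    the bin lower edge and its sum equals the cell's total stepping minutes.
    ``None`` selects all levels and/or behaviours.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    mass: dict[float, float] = {}
    for s in summaries:
        if level is not None and s.activity_level is not level:
            continue
        for b in s.bouts:
            if behaviour is not None and b.behaviour is not behaviour:
                continue
            lo = math.floor(b.cadence / bin_width) * bin_width
            mass[lo] = mass.get(lo, 0.0) + b.minutes
    return pd.Series(mass, dtype=float).sort_index()


# ---------------------------------------------------------------------------
# statistics


@dataclass(frozen=True)
class StatResult:
    statistic: float
    df: tuple[float, float] | float
    p_value: float
    corrected_alpha: float | None = None


def anova_across_levels(
    values: "np.ndarray | list[float]",
    levels: "list[ActivityLevel]",
) -> StatResult:
    """One-way ANOVA of a per-day quantity across activity levels.

    Day-level observations are treated as independent; degrees of freedom
    are (k - 1, N - k) for k groups and N observations.
    """
    values = np.asarray(values, dtype=float)
    groups = [
        values[np.array([lv is level for lv in levels])]
        for level in ActivityLevel
        if any(lv is level for lv in levels)
    ]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 levels with >= 2 observations each")
    f, p = stats.f_oneway(*groups)
    k = len(groups)
    n = sum(len(g) for g in groups)
    return StatResult(statistic=float(f), df=(k - 1, n - k), p_value=float(p))


@dataclass(frozen=True)
class SexCadenceResult:
    activity_level: ActivityLevel
    behaviour: BehaviourClass
    n_male: int
    n_female: int
    mean_difference: float  # male minus female, steps/min
    result: StatResult

    @property
    def significant(self) -> bool:
        return self.result.p_value < self.result.corrected_alpha


def sex_cadence_tests(
    summaries: list[DailySummary],
    participants: dict[str, Participant],
    behaviour: BehaviourClass,
    levels: list[ActivityLevel] | None = None,
    alpha: float = 0.05,
) -> list[SexCadenceResult]:
    """Welch t-tests for male-female cadence differences, per activity level.

    The unit of analysis is the day-level time-weighted mean cadence for the
    requested behaviour class.  The Bonferroni family is the set of cells
    actually tested in this invocation; cells with a single sex (or fewer
    than two days per sex) are skipped with a warning.
    """
    if levels is None:
        levels = [lv for lv in ActivityLevel]
    cells: list[tuple[ActivityLevel, np.ndarray, np.ndarray]] = []
    for level in levels:
        by_sex: dict[Sex, list[float]] = {Sex.MALE: [], Sex.FEMALE: []}
        for s in summaries:
            if s.activity_level is not level:
                continue
            participant = participants.get(s.participant_id)
            if participant is None or participant.sex is Sex.UNKNOWN:
                continue
            c = s.mean_cadence(behaviour)
            if c is not None:
                by_sex[participant.sex].append(c)
        male = np.asarray(by_sex[Sex.MALE])
        female = np.asarray(by_sex[Sex.FEMALE])
        if len(male) < 2 or len(female) < 2:
            if len(male) + len(female) > 0:
                warnings.warn(
                    f"skipping sex comparison for {level.code}/{behaviour.value}: "
                    f"n_male={len(male)}, n_female={len(female)}",
                    stacklevel=2,
                )
            continue
        cells.append((level, male, female))
    if not cells:
        return []
    corrected = alpha / len(cells)
    out = []
    for level, male, female in cells:
        t, p = stats.ttest_ind(male, female, equal_var=False)
        # Welch-Satterthwaite degrees of freedom
        vm, vf = male.var(ddof=1) / len(male), female.var(ddof=1) / len(female)
        df = (vm + vf) ** 2 / (
            vm**2 / (len(male) - 1) + vf**2 / (len(female) - 1)
        )
        out.append(
            SexCadenceResult(
                activity_level=level,
                behaviour=behaviour,
                n_male=len(male),
                n_female=len(female),
                mean_difference=float(male.mean() - female.mean()),
                result=StatResult(
                    statistic=float(t),
                    df=float(df),
                    p_value=float(p),
                    corrected_alpha=corrected,
                ),
            )
        )
    return out
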