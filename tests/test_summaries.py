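"""Daily summaries, level aggregates, cadence histograms, and statistics."""

from __future__ import annotations

import numpy as np
import pytest

import stepday as sd
from stepday.classification import ActivityLevel, BehaviourClass, PrimaryPosture
from stepday.events import ActivityClass, ObservationDay, Participant, Sex
from stepday.locus import Interval, LocusInterval
from stepday.summaries import (
    BoutRecord,
    DailySummary,
    aggregate_by_level,
    anova_across_levels,
    cadence_distribution,
    sex_cadence_tests,
    summarise_day,
)

from .conftest import make_stream, simple_day_spec

A = ActivityClass


def _day(spec):
    stream = make_stream(spec)
    return ObservationDay("T", 0, 0.0, events=list(stream.events), valid=True)


def _summary(level_steps, minutes, pid="P", day=0, rec=0.0, bouts=()):
    sm = {b: 0.0 for b in BehaviourClass}
    sm.update(minutes)
    sm[BehaviourClass.RECREATION] = sm.get(BehaviourClass.RECREATION, 0.0) + rec
    return DailySummary(
        participant_id=pid,
        day_index=day,
        steps=level_steps,
        activity_level=sd.classify_day(level_steps),
        posture_hours={p: 8.0 for p in PrimaryPosture},
        locus_hours=12.0,
        stepping_minutes=sm,
        bouts=list(bouts),
    )


# -- summarise_day ----------------------------------------------------------


def test_equal_thirds_day_gives_eight_hour_postures():
    s = summarise_day(_day(simple_day_spec()))
    assert s.posture_hours[PrimaryPosture.LYING] == pytest.approx(8.0)
    assert s.posture_hours[PrimaryPosture.SEDENTARY] == pytest.approx(8.0)
    assert s.posture_hours[PrimaryPosture.UPRIGHT] == pytest.approx(8.0)
    assert sum(s.posture_hours.values()) == pytest.approx(24.0)


def test_single_recreation_bout_day():
    day = _day([
        (A.PRIMARY_LYING, 8 * 3600.0),
        (A.SEDENTARY, 8 * 3600.0),
        (A.QUIET_STANDING, 8 * 3600.0 - 720.0),
        (A.STEPPING, 720.0, 600),   # 12 min, 1200 steps
    ])
    s = summarise_day(day, loci=[LocusInterval(0.0, 3600.0, anchored=False)])
    assert s.stepping_minutes[BehaviourClass.RECREATION] == pytest.approx(12.0)
    assert s.steps == 1200
    assert s.activity_level is ActivityLevel.VERY_INACTIVE


def test_posture_hours_always_sum_to_24(mixed_cohort_summaries):
    for s in mixed_cohort_summaries:
        assert sum(s.posture_hours.values()) == pytest.approx(24.0, abs=1e-6)


def test_locus_hours_counted_when_loci_known(active_cohort_summaries):
    known = [s for s in active_cohort_summaries if s.locus_known]
    assert known, "expected detectable bed periods"
    # overnight at home alone exceeds ~8 h for these profiles
    assert np.mean([s.locus_hours for s in known]) > 8.0


# -- aggregation ------------------------------------------------------------


def test_outdoor_percentage_excludes_primary_locus_stepping():
    days = [
        _summary(3000, {
            BehaviourClass.PRIMARY_LOCUS: 23.2,
            BehaviourClass.INDOOR: 40.4,
            BehaviourClass.COMMUNITY: 14.5,
        })
        for _ in range(4)
    ]
    (agg,) = aggregate_by_level(days)
    assert agg.outdoor_pct == pytest.approx(100 * 14.5 / (40.4 + 14.5), abs=0.05)


def test_outdoor_percentage_zero_without_outdoor_stepping():
    days = [_summary(3000, {BehaviourClass.INDOOR: 30.0})]
    (agg,) = aggregate_by_level(days)
    assert agg.outdoor_pct == 0.0


def test_recreation_day_percentage_counts_days_with_recreation():
    days = [
        _summary(3000, {BehaviourClass.INDOOR: 30.0}, day=0, rec=12.0),
        _summary(3000, {BehaviourClass.INDOOR: 30.0}, day=1),
    ]
    (agg,) = aggregate_by_level(days)
    assert agg.recreation_day_pct == pytest.approx(50.0)


def test_aggregate_groups_by_level_and_counts_days():
    days = [_summary(1000, {}), _summary(1200, {}), _summary(9000, {})]
    aggs = aggregate_by_level(days)
    assert [a.activity_level for a in aggs] == [
        ActivityLevel.VERY_INACTIVE, ActivityLevel.SOMEWHAT_ACTIVE,
    ]
    assert [a.n_days for a in aggs] == [2, 1]


def test_empty_input_gives_empty_aggregate():
    assert aggregate_by_level([]) == []


# -- cadence distribution ---------------------------------------------------


def test_single_bout_mass_in_one_bin():
    days = [_summary(3000, {}, bouts=[BoutRecord(BehaviourClass.COMMUNITY, 100.0, 10.0)])]
    hist = cadence_distribution(days, behaviour=BehaviourClass.COMMUNITY, bin_width=5.0)
    assert dict(hist) == {100.0: 10.0}


def test_empty_selection_gives_empty_histogram():
    days = [_summary(3000, {})]
    hist = cadence_distribution(days, behaviour=BehaviourClass.RECREATION)
    assert len(hist) == 0


def test_histogram_mass_equals_stepping_minutes(mixed_cohort_summaries):
    sample = mixed_cohort_summaries[:200]
    for behaviour in BehaviourClass:
        hist = cadence_distribution(sample, behaviour=behaviour)
        total = sum(s.stepping_minutes[behaviour] for s in sample)
        assert hist.sum() == pytest.approx(total, abs=1e-9)


def test_bin_width_must_be_positive():
    with pytest.raises(ValueError):
        cadence_distribution([], bin_width=0.0)


# -- ANOVA ------------------------------------------------------------------


def _anova_oracle(groups):
    """Textbook between/within sum-of-squares computation."""
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b = len(groups) - 1
    df_w = len(allv) - len(groups)
    return (ss_between / df_b) / (ss_within / df_w)


def test_anova_matches_sum_of_squares_oracle():
    rng = np.random.default_rng(3)
    levels_pool = list(ActivityLevel)[:4]
    values, levels = [], []
    for i, lv in enumerate(levels_pool):
        g = rng.normal(loc=5 + i, scale=1.2, size=250)
        values.extend(g)
        levels.extend([lv] * len(g))
    res = anova_across_levels(values, levels)
    groups = [
        np.array([v for v, l in zip(values, levels) if l is lv])
        for lv in levels_pool
    ]
    assert res.statistic == pytest.approx(_anova_oracle(groups), rel=1e-9)
    assert res.df == (3, 996)


def test_anova_degrees_of_freedom_track_group_sizes():
    rng = np.random.default_rng(0)
    sizes = dict(zip(list(ActivityLevel), [10, 20, 30, 40, 50, 60, 70]))
    values, levels = [], []
    for lv, n in sizes.items():
        values.extend(rng.normal(size=n))
        levels.extend([lv] * n)
    res = anova_across_levels(values, levels)
    assert res.df == (6, 280 - 7)


def test_identical_groups_give_zero_f():
    values = [1.0, 2.0, 3.0] * 2
    levels = [ActivityLevel.ACTIVE] * 3 + [ActivityLevel.INACTIVE] * 3
    res = anova_across_levels(values, levels)
    assert res.statistic == pytest.approx(0.0, abs=1e-12)


def test_anova_rejects_degenerate_grouping():
    with pytest.raises(ValueError):
        anova_across_levels([1.0, 2.0], [ActivityLevel.ACTIVE, ActivityLevel.ACTIVE])


# -- sex comparisons --------------------------------------------------------


def _sex_fixture(shift=0.0, n=50, seed=0):
    rng = np.random.default_rng(seed)
    summaries, participants = [], {}
    for i in range(2 * n):
        pid = f"P{i}"
        sex = Sex.MALE if i < n else Sex.FEMALE
        participants[pid] = Participant(pid, sex)
        cadence = rng.normal(100.0 + (shift if sex is Sex.MALE else 0.0), 3.0)
        summaries.append(
            _summary(
                11000, {BehaviourClass.COMMUNITY: 30.0}, pid=pid,
                bouts=[BoutRecord(BehaviourClass.COMMUNITY, cadence, 30.0)],
            )
        )
    return summaries, participants


def test_identical_sex_samples_are_not_significant():
    summaries, participants = _sex_fixture(shift=0.0)
    # force literally identical samples: mirror male cadences onto females
    for i in range(50):
        summaries[50 + i].bouts = list(summaries[i].bouts)
    (res,) = sex_cadence_tests(summaries, participants, BehaviourClass.COMMUNITY)
    assert res.result.statistic == pytest.approx(0.0, abs=1e-12)
    assert not res.significant


def test_known_shift_is_detected_after_correction():
    summaries, participants = _sex_fixture(shift=3.0, n=200, seed=1)
    (res,) = sex_cadence_tests(summaries, participants, BehaviourClass.COMMUNITY)
    assert res.significant
    assert res.mean_difference == pytest.approx(3.0, abs=1.0)


def test_bonferroni_family_is_cells_tested():
    rng = np.random.default_rng(2)
    summaries, participants = [], {}
    i = 0
    for steps in (1000, 3000, 6000, 8000, 11000, 13000, 16000):
        for sex in (Sex.MALE, Sex.FEMALE):
            for _ in range(3):
                pid = f"P{i}"; i += 1
                participants[pid] = Participant(pid, sex)
                summaries.append(_summary(
                    steps, {BehaviourClass.INDOOR: 20.0}, pid=pid,
                    bouts=[BoutRecord(BehaviourClass.INDOOR, rng.normal(95, 3), 20.0)],
                ))
    results = sex_cadence_tests(summaries, participants, BehaviourClass.INDOOR)
    assert len(results) == 7
    assert all(r.result.corrected_alpha == pytest.approx(0.05 / 7) for r in results)


def test_single_sex_cell_is_skipped_with_warning():
    summaries, participants = _sex_fixture(n=3)
    for pid in list(participants):
        if participants[pid].sex is Sex.FEMALE:
            participants[pid] = Participant(pid, Sex.UNKNOWN)
    with pytest.warns(UserWarning, match="skipping sex comparison"):
        results = sex_cadence_tests(summaries, participants, BehaviourClass.COMMUNITY)
    assert results == []
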