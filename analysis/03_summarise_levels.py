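"""Aggregate day summaries by activity level and run the statistics.

Produces the per-level breakdowns (posture hours, stepping minutes per
behaviour class, outdoor share, recreation-day share), the cadence
histograms, the one-way ANOVAs of posture time across levels, and the
Bonferroni-corrected Welch t-tests for sex differences in cadence.
Outputs: ``results/level_aggregates.csv``, ``results/cadence_histograms.csv``
and ``results/stats.json``.
"""

import json
from pathlib import Path

import pandas as pd

import stepday as sd
from stepday.classification import ActivityLevel, BehaviourClass, PrimaryPosture
from stepday.cli import _frame_to_summaries
from stepday.summaries import (
    aggregate_by_level,
    aggregates_to_frame,
    anova_across_levels,
    cadence_distribution,
    sex_cadence_tests,
)

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"


def main() -> None:
    frame = pd.read_csv(RESULTS / "day_summaries.csv")
    bouts = pd.read_csv(SCRATCH / "day_summaries.bouts.csv")
    summaries = _frame_to_summaries(frame, bouts)
    participants = sd.read_participants(SCRATCH / "cohort" / "participants.csv")

    aggregates = aggregate_by_level(summaries)
    agg_frame = aggregates_to_frame(aggregates)
    agg_frame.to_csv(RESULTS / "level_aggregates.csv", index=False)
    cols = ["activity_level", "n_days", "mean_steps", "outdoor_pct",
            "recreation_day_pct"]
    print(agg_frame[cols].round(1).to_string(index=False))

    stats_out: dict = {"anova": {}, "sex_cadence": []}
    testable = {
        a.activity_level for a in aggregates if a.n_days >= 2
    }
    subset = [s for s in summaries if s.activity_level in testable]
    levels = [s.activity_level for s in subset]
    for posture in PrimaryPosture:
        r = anova_across_levels([s.posture_hours[posture] for s in subset], levels)
        stats_out["anova"][f"hours_{posture.value}"] = {
            "F": r.statistic, "df": list(r.df), "p": r.p_value,
        }
        print(f"ANOVA {posture.value} hours: F({r.df[0]},{r.df[1]}) = "
              f"{r.statistic:.1f}, p = {r.p_value:.3g}")

    for behaviour in BehaviourClass:
        for res in sex_cadence_tests(summaries, participants, behaviour):
            stats_out["sex_cadence"].append({
                "activity_level": res.activity_level.code,
                "behaviour": behaviour.value,
                "t": res.result.statistic,
                "p": res.result.p_value,
                "corrected_alpha": res.result.corrected_alpha,
                "mean_difference": res.mean_difference,
                "significant": res.significant,
            })

    rows = []
    for level in ActivityLevel:
        for behaviour in BehaviourClass:
            hist = cadence_distribution(summaries, level=level, behaviour=behaviour)
            rows.extend(
                {"activity_level": level.code, "behaviour": behaviour.value,
                 "bin_lo": lo, "bin_hi": lo + 5.0, "minutes": minutes}
                for lo, minutes in hist.items()
            )
    pd.DataFrame(rows).to_csv(RESULTS / "cadence_histograms.csv", index=False)
    (RESULTS / "stats.json").write_text(json.dumps(stats_out, indent=2))
    n_sig = sum(r["significant"] for r in stats_out["sex_cadence"])
    print(f"sex-cadence comparisons: {len(stats_out['sex_cadence'])} cells, "
          f"{n_sig} significant after Bonferroni correction")


if __name__ == "__main__":
    main()
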