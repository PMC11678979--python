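# Methods

## The event model

A monitored day is represented as a gap-free, time-ordered sequence of
events, each a continuous period of one of seven activity classes
(primary lying, secondary lying, sedentary, quiet standing, stepping,
seated transport, cycling). Times are seconds from the stream origin,
double precision; stride counts attach only to stepping events and one
stride is two steps. Contiguity is enforced at a tolerance ε = 0.001 s:
larger gaps or overlaps are validity violations, reported as data rather
than exceptions so a caller can triage a whole cohort.

Streams are cut into 24 h observation days at a configurable clock
boundary (default midnight relative to the stream origin; the boundary
convention is not observable from the data itself, so midnight is the
assumed convention). Events straddling a boundary are split
proportionally; stride counts are rounded to the nearest integer with the
half-way case and the residual going to the earlier fragment, which makes
splitting conserve both total duration and total strides exactly. Only
days with full 86 400 s coverage count as valid, and a participant enters
the analysis only with at least seven valid days (the earliest seven are
retained), so that every included participant contributes equally.
Non-wear and signal cleaning are assumed resolved upstream by the device
software; the event classes are taken as given.

## Stepping structure

Adjacent stride/stepping events merge into maximal stepping bouts;
merging is idempotent and conserves duration and strides. Cadence is
steps × 60 / duration (steps/min). Upright containers are maximal runs of
upright-posture events. Two reading choices here were genuinely open:

- *Interruptions.* Lying events break containers exactly as sedentary
  events do — a mid-container lying spell is physically a break in
  uprightness even though the container definition mentions only
  sedentary interruptions.
- *Cycling* maps to the upright posture and therefore lives inside
  containers, but contributes no steps and is never a stepping bout.

The longest bout of a container (ties broken to the earliest start)
drives its functional class. No bridging of short standing gaps is
applied when measuring "continuous" stepping; the stream tolerance ε is
the only contiguity allowance.

## Time in bed and the primary locus

Time in bed is not directly observable from posture events. The heuristic
used: the longest contiguous run of lying/sedentary events that overlaps
a configurable night window (default 21:00–09:00, expressed relative to
each day) and contains at least one primary-lying event. This is the
minimal rule consistent with a home period "surrounding" the overnight
block; night-shift schedules would need a shifted window.

Transition events are continuous stepping strictly longer than 60 s, any
seated-transport event, and any cycling event. The primary locus for a
night runs from the end of the last transition before the bed period to
the start of the first transition after it; missing bounding transitions
fall back to the stream ends and mark the interval unanchored. The night
preceding the first observation day is probed as well (streams typically
begin mid-sleep), so the first morning's at-home time belongs to a locus.
Membership of an event (or container) in the locus is decided by its
midpoint, which prevents double counting of straddling events. Day-level
summaries accept every locus overlapping the day, because a day's morning
at-home time belongs to the locus anchored the previous evening.

## Classification

Primary postures: lying ← primary lying; sedentary ← sedentary, secondary
lying, seated transport; upright ← quiet standing, stepping, cycling.
Activity levels are half-open step-count bands
[0, 2500), [2500, 5000), …, [15 000, ∞); the 12 500 boundary is resolved
half-open into the higher band. Containers classify by longest bout:
[0, 60) s indoor-type (split into primary-locus vs other indoor stepping
by locus membership), [60, 600) s community, [600, ∞) s recreation. The
bout-class boundary (≥ 60 s) and the transition threshold (> 60 s) are
configured independently: the former is a band edge, the latter a strict
exceedance, and a container whose longest bout is exactly 60 s is
community without being a travel marker. Stepping inside the locus that
sits in a community or recreation container is not primary-locus
stepping: classification is per container, by its longest bout.

## Summaries and statistics

Per-day summaries carry posture hours (an exact partition of 24 h),
locus hours, stepping minutes per behaviour class (an exact partition of
stepping time), total steps, and per-bout records (behaviour, cadence,
minutes) from which cadence histograms (half-open bins, default
5 steps/min width) and time-weighted mean cadences are computed on
demand. Aggregation is across days, not participants — the day is the
unit of analysis throughout. The outdoor share is
100 × outdoor / (indoor + outdoor) stepping minutes with primary-locus
stepping excluded from the denominator; the recreation-day share is the
percentage of a level's days containing at least one recreation
container.

One-way ANOVA (scipy `f_oneway`) treats day-level observations as
independent, giving df = (k − 1, N − k); within-person clustering is
deliberately ignored to match the day-level design. Sex comparisons use
Welch's unequal-variance t-test on day-level time-weighted mean cadences,
with a Bonferroni family equal to the set of level × behaviour cells
actually tested in one invocation; cells with data but fewer than two
days of either sex are skipped with a warning.

## The synthetic generator

The generator emulates the structure of a free-living day, not any real
cohort's parameter values. A day tiles 86 400 s exactly: lying until
wake, a morning at home (short stepping bursts padded with standing,
separated by sedentary gaps), an outbound travel leg, a daytime
away-from-home segment mixing indoor-type containers with community
bouts and occasional recreation walks, a homebound leg, an evening at
home (with occasional secondary-lying spells), and lying from bed onset.
Travel legs draw walk (35 %), seated transport (50 %) or cycling (15 %);
every leg realises a transition event, and at-home bouts stay under 60 s
so the locus anchors are exactly the travel transitions.

Per activity level the preset day profile fixes: a step target
(truncated-normal, truncated inside the level's band so realised counts
stay in band), a stepping-minute composition (primary locus / indoor /
outdoor) taken from the reference per-level means, a recreation-day
probability, log-normal bout durations clipped to the class bounds
(medians 18/25/140/900 s), and normal cadences truncated to
[40, 160] steps/min with SD 8. Because the reference minute compositions
and the step bands jointly imply low whole-day average cadences, per-class
cadence means are solved per level from
S = (m_pl + m_in)·k_in + m_out·(k_in + Δ) with a fixed indoor→outdoor
offset Δ = 15 steps/min; this keeps indoor stepping slower than outdoor
at every level while hitting both the minute composition and the step
band. The very-inactive step target sits at 2000 (upper part of its
band): the 40 steps/min cadence floor would otherwise make that level's
stepping-minute composition unreachable.

Bout drawing consumes a per-class step budget; the final bout of each
class is fitted exactly (adjusting duration, then cadence within the
legal range), tiny unrealisable remainders cascade to the next class
down, and stride rounding carries a running remainder so realised steps
match the day target to well under 1 %. On recreation days one ≥ 10 min
bout is carved from the outdoor budget when it fits; at low activity
levels the outdoor budget often cannot hold a full 10-min bout, so
realised recreation-day rates sit slightly below the nominal
probability there — ground truth records what was actually emitted.
Ground truth times (wake, bed onset, travel anchors) are read back from
the emitted events, so closure tests can demand bitwise equality of
detected locus boundaries.

Cohorts draw one generator per participant from a seed sequence
(master seed × participant index), a base activity level per participant
from a configurable mix (default proportional to the reference cohort's
day distribution), and a ±1-level per-day jitter so most participants
span several levels over a week. An optional constant cadence shift for
male participants injects a known sex effect for power checks.

### What passing tests do and do not show

The generator reproduces the qualitative structure the pipeline exploits
(event tiling, nocturnal blocks, travel-bounded home periods, distinct
indoor/outdoor cadence regimes). It does not model posture-transition
microstructure, non-wear, irregular sleep, multi-residence days or
night-shift schedules; closure results demonstrate internal correctness
of the pipeline, not fidelity of any particular cohort's parameter
estimates.

## Numerical choices and problem sizes

ε = 0.001 s contiguity; event membership by midpoint; ties in longest
bouts to the earliest; half-open intervals everywhere (a 12 500-step day
is highly active, a 600 s bout is recreation). Statistical checks in the
test suite run on simulated batches of ~500–1000 days (which already
bound Monte-Carlo error on the recovered compositions well below the
3-SE acceptance margin), and oracle comparisons on instances up to 1000
observations at 1e-9 relative tolerance.

## Known limitations

- The time-in-bed rule is a heuristic; the upstream device software's
  internal home-detection rule may differ.
- Day-one mornings have a locus only when the stream starts mid-sleep
  (it does for generated cohorts); streams starting mid-day would leave
  the first morning unassigned.
- ANOVA ignores within-person correlation by design (day-level unit of
  analysis); a mixed model would be the natural extension.
- The seven-day retention rule keeps the earliest valid days; no
  weighting is applied for excluded participants.
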