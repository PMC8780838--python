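# Methods

This note documents the models and procedures implemented in
`sensorgraphs`, the defaults and why they were chosen, what the synthetic
data generator does and does not emulate, and the numerical conventions.

## The sensor-graph activity statistic

**Event model.** The observable is a chronological log of PIR firings, one
sensor id and timestamp per row, second precision. PIR hardware enforces an
8 s cool-down per sensor; validation flags (but by default keeps) any pair
of same-sensor events closer than 8 s, since the cool-down describes the
hardware, not a data-cleaning rule. Sensors are mapped to rooms at load
time, so several sensors in one room (including a redundant sensor)
collapse onto a single vertex; room granularity is the reference behaviour.

**Daily graphs.** Days are cut at civil midnight in a configurable zone
(UTC default). Each day is processed independently: pairs spanning midnight
do not form transitions, which keeps every daily matrix computable from
that day's events alone. Every consecutive event pair within a day adds 1
to the ordered room pair, with no maximum time gap (a configurable gap
option exists but defaults off, since dwell times of hours are normal).
Same-room pairs accumulate on the diagonal. An unmasked day of m events
therefore has total mass m − 1 — a conservation law used as a property test.

**Masking.** Ordered room pairs not directly reachable in the flat are
zeroed in every daily matrix *before any aggregation*, and the removed mass
is reported. Masking is deliberately a hard zero rather than a re-routing:
impossible pairs are evidence of a second person or a glitch, and the
method's only defence against visitor contamination is to discard that
mass.

**Baseline.** The baseline B is the entrywise mean of the first k = 7
valid days (present, not excluded). One week is the natural cycle of
domestic routines and is consistent with baselines whose cells are
multiples of 1/7; k is configurable.

**Weights and the pd statistic.** W carries 1 on the diagonal and 1.5 off
it, up-weighting room transitions, which are rarer but more informative
about mobility than within-room motion. The day statistic is
`pd = Σ W∘(B − D) / Σ W∘B`, a signed fraction rendered in percent. The
orientation follows the difference B − D: pd > 0 means *less* activity than
baseline, pd = 1 a fully silent day, pd < 0 a day more active than
baseline. Subtract-then-weight and weight-then-subtract are algebraically
identical; the implementation subtracts first. The baseline week itself is
excluded from the series.

## Filtering

Participants are excluded for death, a change in living situation, or a
mobility-compromising incident (each flagged with an onset date). Days
inside declared absence intervals (vacation, short-term care,
hospitalization) are removed from the series; the declared intervals are
authoritative. A low-event-count detector (default threshold 10 events/day)
only *suggests* candidate absence days, because a very quiet day is also
compatible with genuine inactivity. Participant- and day-level filtering
commute, which is property-tested.

The cohort bias check compares each metric-scale characteristic between two
groups with an unpaired two-sample Mann–Whitney rank test (the cohorts are
independent samples, so a paired signed-rank test would not apply) and
reports a same/different verdict at a configurable α, default 0.01.

## Trends and the group comparison

Per-series trends are ordinary least squares on (days since first valid
day, value). Group trends pool all points of a group's participants into a
single fit — the simplest aggregation consistent with unequal day counts;
per-participant fit averaging is available as an option. The fitted line is
evaluated on the common window [0, w), w being the shortest participant
span, and "fitted change" is slope × window.

The two groups' fitted lines are compared with a Wilcoxon signed-rank test
paired by day index: W is the positive-rank sum (average ranks on ties), and
for more than 25 informative pairs z and p come from the normal
approximation with continuity and tie correction. All-zero differences
yield the degenerate convention p = 1, flagged as such. Two caveats are
deliberate: applying a paired test to two fitted straight lines makes the
pairs fully dependent, so the procedure is reproduced as a descriptive
device without endorsing its inferential validity; and the package reports
both the slope and the total fitted change, which differ by the window
factor.

Assessment series (SPPB points, TUG seconds) are reported relative to their
first value; the clinical orientation is preserved (SPPB up = better, TUG
down = better), not flipped.

## The synthetic cohort generator

**What it emulates.** A lone resident in a 5-room flat (hallway hub;
bedroom–bathroom never directly connected, so an impossible pair always
exists) moves by a semi-Markov process: log-normal dwell per room
(means 25/10/18/40/3 min for bedroom/bathroom/kitchen/living room/hallway,
log-SD 0.6), uniform choice among adjacent rooms, sleep in the bedroom
between jittered bed (22:30) and wake (06:30) times, with a shortest-path
walk home at bedtime so consecutive rooms are always connected. Sensors
fire on room entry and then by a renewal process with gaps of 8 s plus an
exponential wait (daytime re-trigger rate 0.5/min, night 0.04/min), which
makes cool-down violations impossible by construction; dwell times are
clipped at 8 s so re-entries cannot violate it either. Timestamps are
rounded to whole seconds, which cannot shrink a ≥ 8 s gap below 8 s
(rounding is monotone and commutes with +8). This yields roughly 500–700
events per present day. Since real PIR re-fire behaviour under sustained
presence varies, an `entry_only` emission mode is provided as well.

**Injected structure.** Activity change multiplies both the movement rate
(dwell shortens) and the re-trigger rate by `max(0, 1 + slope·day)`; pd
responds linearly to such uniform scaling, so a participant with activity
slope s is expected to show a pd slope of ≈ −s (the renewal cool-down
introduces a small saturation nonlinearity, a few percent over a 30 %
decline). The reference cohort is 9 intervention participants at
−0.0001/day and 6 controls at −0.001/day over 311 days (one baseline week
plus a ten-month follow-up), log-normal (σ = 0.35) per-participant rate
heterogeneity, about 1.5 absence spells of mean 5 days each (≈ 7–8 absent
days per participant), one visitor event per day on average in uniformly
random rooms (which also occurs on absence days — relatives in the flat),
and monthly assessments: SPPB drifting by +0.16/+0.06 points and TUG by
−0.10/−0.08 s per group over the study with test-retest noise of 0.7
points / 0.8 s. All draws descend from one master seed via spawned child
streams, so datasets are byte-reproducible.

**What it does not emulate** — and hence what passing recovery tests do not
show about real data: day-of-week and seasonal routine structure, sensor
dropouts and base-station outages, geometric PIR coverage (overlapping
fields of view, missed detections), correlated multi-day behavioural
changes such as illness, deliberate sensor tampering, and visitors whose
movement is itself topologically coherent. Recovery results demonstrate
that the pipeline extracts what the generator injects, not that real flats
satisfy the generator's assumptions.

With monthly assessments and realistic test-retest noise, the injected
sub-point SPPB/TUG drifts are below the resolution of ~10 visits per
participant; the pipeline reports the fitted assessment changes without
claiming they recover the injected values — unlike the pd slopes, whose
recovery is tested across master seeds.

## Numerical conventions and degenerate inputs

* pd is stored as a signed fraction; only rendering multiplies by 100.
* An all-zero weighted baseline raises a degenerate-baseline error rather
  than returning an infinity.
* Trend fits require ≥ 2 points with ≥ 2 distinct abscissae; collinear
  input is recovered exactly, and the implementation agrees with the
  closed-form normal equations to 1e−10.
* Ties in the signed-rank test get average ranks; zero differences are
  dropped (and their count reduces the effective n).
* Matrix CSVs round-trip exactly (shortest-repr floats, labels preserved);
  the worked-example identities hold to 1e−9.
* The acceptance script and the test suite run the reference cohort at its
  full size (15 participants × 311 days); recovery tests across 20 master
  seeds take a few minutes in total.

## Known limitations

* Pooled group fits weight participants by their number of valid days.
* The signed-rank comparison of two fitted lines is descriptive, not
  confirmatory (fully dependent pairs; see above).
* Absence detection from event counts alone cannot distinguish absence
  from immobility; only declared intervals are filtered.
* The pd statistic conflates *where* activity happens only through the
  diagonal/off-diagonal weight split; it is not a graph distance and
  carries no spatial semantics beyond that.
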