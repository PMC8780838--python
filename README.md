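# sensorgraphs

Monitoring how the *real-life* mobility of older adults changes over months
is hard: supervised assessments such as the Short Physical Performance
Battery (SPPB) and the Timed Up and Go (TUG) measure what a person *can* do
in a test situation (capacity), not what they actually *do* at home
(performance). `sensorgraphs` implements a privacy-preserving alternative
for single-resident flats instrumented with PIR motion sensors: daily
activity is summarised as a weighted directed graph of room transitions and
compared, day by day, against the resident's own baseline week.

## The statistic

Rooms are vertices; each consecutive pair of sensor events adds 1 to the
directed edge between the corresponding rooms, so within-room motion
accumulates on the diagonal of the adjacency matrix and room changes off it.
Transitions that are physically impossible in the flat (e.g. bedroom to
bathroom without passing the hallway) are fixed to weight 0 — they can only
be caused by visitors or glitches. With the baseline matrix **B** (entrywise
mean of the first seven valid days), the daily matrix **D**, and a weight
matrix **W** with 1 on the diagonal and 1.5 elsewhere (transitions are rarer
but more informative than within-room motion):

```
diff(B, D) = Σᵢⱼ wᵢⱼ (bᵢⱼ − dᵢⱼ)          pd = diff(B, D) / Σᵢⱼ wᵢⱼ bᵢⱼ
```

`pd` is the per-day performance surrogate: 0 for a day like the baseline,
+100 % for a day with no activity, negative for a day *more* active than
baseline. Per-group progress is summarised by ordinary least squares over
the pooled `(day, pd)` points, and the two groups' fitted activity lines are
compared with a Wilcoxon signed-rank test paired by day index.

Because real in-home monitoring data of this kind cannot be shared, the
package includes a first-class synthetic cohort generator
(`sensorgraphs.simulate`): a semi-Markov resident moves between connected
rooms with room-specific dwell times, sensors fire on entry and by a renewal
process that respects the 8 s PIR cool-down, and group-level activity
trends, absence spells and visitor contamination are injected with full
ground truth for recovery testing.

## Worked example

The package bundles a five-room example flat (bedroom, bathroom, kitchen,
living room, hallway) with a baseline-week matrix and one day's matrix:

```python
from sensorgraphs.examples import five_room_example
from sensorgraphs.difference import make_weight_matrix, percent_difference

ex = five_room_example()
W = make_weight_matrix(5)                      # 1 on-diagonal, 1.5 off
r = percent_difference(ex.baseline, ex.day, W)
print(f"diff = {r.raw:.2f}, pd = {r.pd * 100:.2f} %")
```

```
diff = -21.10, pd = -1.89 %
```

The weighted mass of the day exceeds the baseline week's by 21.10, i.e. this
day was 1.89 % *more* active than the resident's baseline.

A full synthetic study from the shell:

```sh
sensorgraphs simulate --seed 1 --out dataset/
sensorgraphs all --in dataset/ --out results/
```

This simulates 15 participants (9 intervention with a near-flat injected
activity trend, 6 controls declining by 0.1 % of their activity per day)
over 311 days, builds every daily graph, filters absences, fits the group
trends and writes `results/trend_report.csv`, `results/comparison.json` and
a reproducibility manifest. With seed 1 the recovered pooled pd slopes are
+0.0092 %/day (intervention) vs +0.0980 %/day (control) — a fitted change
of +2.8 vs +29.8 percentage points over the common 304-day window (pd grows
as activity declines), the injected factor-10 difference — and the
signed-rank comparison of the fitted lines rejects equality at α = 0.01
(z = −14.96, p ≈ 10⁻⁵⁰).

## Layout

| module | contents |
| --- | --- |
| `sensorgraphs.events` | event-log/topology/assessment types and I/O, validation, day segmentation |
| `sensorgraphs.graphs` | daily adjacency matrices, edge updates, impossible-transition masking |
| `sensorgraphs.difference` | baseline averaging, weight matrix, `diff`/`pd`, difference series |
| `sensorgraphs.preprocess` | exclusion criteria, absence filtering, cohort bias check |
| `sensorgraphs.trends` | least-squares trends, group pooling, signed-rank comparison |
| `sensorgraphs.simulate` | topology/resident/cohort generators with ground truth |
| `sensorgraphs.pipeline` / `cli` | end-to-end orchestration and the `sensorgraphs` command |

See `docs/methods.md` for the model assumptions, parameter choices and
known limitations.
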