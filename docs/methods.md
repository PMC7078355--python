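# Methods

## The scoring model

The engine implements the Hygiene Performance Rating arithmetic exactly as
the scheme defines it. Every (chapter, control point) cell of the protocol
crosstabulation yields an observation score *s* ∈ {0, 1, 2, 3} and weights
*e* ∈ {1, 2} (economic) and *h* ∈ {1, 3, 6, 12} (hygienic):

* weighted result W = s·e·h, with W = 0 whenever s ∈ {0, 1};
* theoretical maximum M = 3·e·h, with M = 0 whenever s = 0.

Setting both W and M to zero for s = 0 is what makes the scheme robust to
protocol/line mismatch: a control point that does not exist on a given line
(rodding is the canonical example) simply drops out of every sum. The engine
treats this as *not applicable*, never as 0 % — a chapter whose ΣM is zero is
reported as `n/a`.

Percentages are always pooled raw sums, `100 − ΣW/ΣM·100`, at single-cell,
chapter and total level. The total is **not** the mean of chapter
percentages; chapters with more and heavier control points weigh more. A
dedicated test constructs an audit where the two disagree (pooled 96.0 %
versus averaged 50.0 %) and asserts the pooled value.

## Rounding and grade bands

Band edges are printed at one-decimal resolution (85.1/85.0, …), so
percentages are rounded to one decimal before band comparison. The rounding
mode — half away from zero, implemented with `decimal` quantization rather
than binary-float `round` — is a design choice: the scheme does not state
one, and banker's rounding would make 85.05 fall out of grade A. Raw
unrounded percentages are kept in the report for transparency. Band
membership is evaluated on integer tenths, so no float-comparison fuzz can
move a total across an edge.

The band table is configuration (CSV: `label,total_min,total_max,
chapter_min`), with the bundled default reproducing the published values.
A loaded table must partition [0, 100] exactly at one-decimal resolution.

The published scheme attaches chapter floors to A (no chapter < 60.0 %) and
B (no chapter < 50.0 %) but does not say what happens when the total sits in
A's range while a chapter is below the floor. The engine demotes to the
first worse band, scanning downward, whose floor holds (C and D have none,
so the cascade always terminates); the report records both the band the
total alone selects and the demotion flag. Only applicable chapters
(ΣM > 0) are checked against floors. This cascade is a declared engine
choice, not published intent.

## Aggregation rules

* **Behavioural / structural points** register the worst spot score of the
  day (`max`), never the average. Spot-level zeros are ignored: 0 is a
  cell-level "not observed" state, not a judgement. An empty spot list
  yields 0.
* **Frequency points** map an error percentage through ordered
  (upper-bound, score) bands; the first band whose bound covers the
  frequency wins, and a frequency above every bound falls into the last
  (worst) band. The real-world thresholds are not published; every band in
  this package is synthetic configuration carried in the protocol file. The
  worked example's skin-contamination bands (≤0.5 → 1, ≤2 → 2, else 3) are
  chosen so the recorded 3 % maps to score 3, consistent with the example,
  without claiming the thresholds used in practice.
* **Measurement points** score 1 inside a closed acceptable range, 2 within
  a configured margin outside it, 3 beyond the margin (or anywhere outside
  the range when no margin is configured). The bundled start-up temperature
  range 82–100 °C with an 8 °C margin is likewise synthetic, consistent
  with the worked example's 87.0 °C scoring 1. Units must match exactly.

## File formats

Protocols are UTF-8 sectioned delimited text (`[protocol]`, `[catalog]`,
`[chapters]`), tab- or comma-delimited with the delimiter auto-detected from
the catalog header row. Fields are single-line; csv quoting covers embedded
delimiters and quotes. A writer option emits comma decimal separators for
locale-compatible export (tab delimiter only, to keep numbers unambiguous),
and all numeric readers tolerate comma decimals. Audits are JSON with one
record per observation. Round-trip fidelity (write → parse → identical
object, field-exact) is property-tested over generated protocols, including
the comma-delimited and comma-decimal variants.

## The synthetic audit generator

`random_audit` exists so every pipeline stage is testable without real audit
data. For each crosstabulation pair it decides observation with probability
`coverage`, draws an intended score from the quality level's distribution,
and synthesises evidence of the right kind that reduces back to exactly that
score (spot lists whose maximum is the target; a frequency inside the
target's band; a measurement inside the corresponding region of the range).
Everything derives from one `numpy` generator seeded by the scenario, so the
same seed and scenario give byte-identical audit files.

Declared score distributions P(1, 2, 3):

| quality   | P(1) | P(2) | P(3) |
|-----------|------|------|------|
| excellent | 0.97 | 0.03 | 0.00 |
| mixed     | 0.55 | 0.35 | 0.10 |
| poor      | 0.10 | 0.30 | 0.60 |

"Excellent" draws no score 3 at all: with hygienic weights up to 12, a
single "not acceptable" finding can push a small chapter below the grade-B
floor and cascade the grade to C, which contradicts what an excellent line
means in this scheme (grade A or B). Even so, rare clusters of score-2
findings can breach a chapter floor, so the A/B rate for excellent audits is
high but not certain (measured ≥ 99 % over 100-seed windows). The generator
models cells as independent; real audits correlate deviations within an
operator or a position, exhibit day-time drift, and attach photographic
evidence — none of which is emulated. Passing tests therefore demonstrate
the correctness of the scoring pipeline, not the realism of any particular
audit.

The bundled sheep-line template carries the twelve standard chapters with a
representative catalog of 27 control points (69 crosstabulation cells). A
production protocol is several times larger; the loader is size-agnostic and
property tests exercise arbitrary generated protocols.

## Problem sizes and numerical choices

All arithmetic is exact integer arithmetic until the final percentage; the
only floating-point step is the division, immediately quantized to one
decimal through `decimal`. Property suites run 200 generated cases per
invariant and the simulation checks use 100–200 seeds, which keeps the full
test suite under a minute on one CPU. Degenerate inputs are explicit errors:
an audit whose total ΣM is zero raises (there is nothing to score), scores
or weights outside their domains raise, and a frequency point without bands
or a measurement point without a range is a configuration error rather than
a silent default.

## Known limitations

* The cascade rule for floor-demoted grades, the frequency bands, the
  measurement margins and the report layout are engine choices where the
  published scheme is silent; all are configuration or documented constants.
* Benchmarking compares audits of the identical protocol only; no attempt
  is made to align chapters across different protocol revisions.
* Photo/video evidence is out of scope; comments may carry references.
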