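# hpraudit

A scoring engine for **Hygiene Performance Rating (HPR)** audits of slaughter
lines. HPR is a systematic, visual auditing scheme for slaughter hygiene: a
trained assessor walks the line for a full slaughter day and judges every
relevant control point — operator behaviour, start-up temperatures, error
frequencies, facilities — on a three-point scale. The engine turns those
observations into weighted percentages, a per-position hygiene profile, an
A–D grade, and benchmark tables across repeated audits. It is written for
veterinary public-health and food-safety practitioners who want the scoring
arithmetic reproducible, scriptable and auditable, independent of any
spreadsheet or web front end.

## The model

A **protocol** is an ordered list of *chapters* (positions along the line,
e.g. Bleeding, Skinning, Evisceration, plus management/premises) crossed with
a catalog of *control points* (auditable questions). The same question may
apply at several positions, so the binding is a many-to-many
crosstabulation. Each control point carries a hygienic weight
*h* ∈ {1, 3, 6, 12} (hygienic impact and risk) and an economic weight
*e* ∈ {1, 2}, where 2 means the deviation is a cheap quick-fix — the scheme
deliberately punishes harder what is easy to fix.

Observations score *s* ∈ {1, 2, 3} (acceptable / potential for improvement /
not acceptable); 0 marks an unobserved or not-applicable point. Per cell:

    weighted result      W = s·e·h   (forced to 0 when s ∈ {0, 1})
    theoretical maximum  M = 3·e·h   (forced to 0 when s = 0)

Scores are deductions from perfect hygiene, pooled over raw sums (never
averaged over chapters):

    single  % = 100 − (W/M)·100
    chapter % = 100 − (ΣW/ΣM)·100          over the chapter's cells
    total   % = 100 − (ΣW/ΣM)·100          over all cells

The total maps to a grade: **A** 85.1–100.0 % (no chapter below 60.0 %),
**B** 70.1–85.0 % (no chapter below 50.0 %), **C** 55.1–70.0 %,
**D** 0–55.0 %. Percentages are rounded half away from zero to one decimal
before band comparison; when a chapter floor fails, the grade cascades to the
best lower band whose floor holds, and the report flags the demotion.

Aggregation during the audit day follows the scheme's field rules: for
behaviours the **worst deviation observed** is registered, not the average;
error-rate indicators (punctured intestines, fleece remnants, skin-to-carcass
contamination) record a **frequency** mapped to a score through configured
bands; start-up **measurements** (disinfection-tool temperatures) are checked
against an acceptable range.

## Worked example

The bundled single-chapter example audits the *skinning* position with seven
control points (two of them unobserved):

```python
import hpraudit as h

protocol, audit = h.table2_audit()
report = h.build_report(audit, protocol)
print(f"total = {report.total}%  grade = {report.grade}")
for d in report.deviations:
    print(f"  score {d.score}  W={d.weighted_result:<3} {d.question}")
```

prints

```
total = 37.0%  grade = D
  score 3  W=72  Visible contaminations from skin onto carcass
  score 3  W=18  Are sinks situated expediently in accordance with the work flow?
  score 2  W=12  All working positions are facilitated with hand wash
```

The five observed cells sum to ΣW = 102 against ΣM = 162, so the chapter
(and total) score is 100 − 102/162·100 = 37.0 % — deep in grade D, with the
deviation list led by the heaviest finding (visible skin-to-carcass
contamination at 3 % frequency, W = 72). Unobserved cells contribute nothing
to either sum.

The same pipeline is available from the shell:

```sh
hpr simulate --out demo --seed 42 --quality mixed
hpr score --protocol demo/protocol.tsv --audit demo/audit.json --out demo/report
# total=70.1% grade=C
```

`hpr score` writes `report.json` and the per-chapter `profile.tsv`;
`hpr report` adds a Markdown rendering and the profile bar chart; `hpr
validate` checks protocol/audit files; `hpr benchmark` lines up repeated
audits chronologically with per-chapter deltas.

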