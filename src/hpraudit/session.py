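"""Audit session: raw observations and their reduction to cell scores.

During an audit day the assessor walks the line from start-up to the end of
slaughtering and records evidence per (chapter, control point) cell.  The
evidence depends on the control point's kind:

* behavioural / structural — repeated spot judgements; the **worst deviation
  observed is registered**, not the average (``max`` of the spot scores);
* frequency — an error percentage (e.g. punctured intestines, carcasses with
  fleece remnants), mapped to a score through the point's frequency bands;
* measurement — a value with a unit (e.g. start-up water temperature in the
  knife disinfection tool), checked against the point's acceptable range.

Cells with no recorded evidence score 0 ("not observed"), which removes them
from both the weighted result and the theoretical maximum, so control points
that do not apply on a given line barely influence the result.

Audit files are JSON: a metadata block plus one record per observation.  The
reader tolerates comma decimal separators in measurement values.
"""

from __future__ import annotations

import datetime as _dt
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import scoring
from .errors import ConfigurationError, DomainError, ValidationError
from .protocol import ControlPoint, MeasurementRule, Protocol


@dataclass
class Observation:
    """One recorded judgement for a (chapter, control point) cell.

    Exactly one evidence field should be populated, matching the control
    point's kind; an observation with no evidence marks the cell as
    deliberately not observed (final score 0).
    """

    chapter_index: int
    control_id: str
    raw_scores: list[int] | None = None
    frequency_percent: float | None = None
    measurement: tuple[float, str] | None = None
    comment: str = ""

    def evidence_fields(self) -> list[str]:
        present = []
        if self.raw_scores is not None:
            present.append("raw_scores")
        if self.frequency_percent is not None:
            present.append("frequency_percent")
        if self.measurement is not None:
            present.append("measurement")
        return present


@dataclass
class Audit:
    """A dated assessment of one slaughter line against a protocol."""

    protocol_name: str
    abattoir: str
    line: str
    date: _dt.date
    assessor: str
    observations: list[Observation] = field(default_factory=list)

    @property
    def identifier(self) -> str:
        return f"{self.abattoir}/{self.line}/{self.date.isoformat()}"

    def observation_map(self) -> dict[tuple[int, str], Observation]:
        out: dict[tuple[int, str], Observation] = {}
        for obs in self.observations:
            key = (obs.chapter_index, obs.control_id)
            if key in out:
                raise ValidationError(
                    f"duplicate observation for chapter {key[0]}, control {key[1]!r}"
                )
            out[key] = obs
        return out


def aggregate_behavioural(raw_scores: Sequence[int]) -> int:
    """Worst-deviation rule: the final score is the worst spot score of the day.

    Zeros inside the list are ignored (0 is a cell-level state, not a spot
    judgement); an empty list means the point was never observed → 0.
    """
    spots = [s for s in raw_scores if s != 0]
    if not spots:
        return 0
    if any(s not in (1, 2, 3) for s in spots):
        raise DomainError(f"spot scores must be in {{1,2,3}}, got {list(raw_scores)}")
    return max(spots)


def aggregate_frequency(
    frequency_percent: float, bands: Sequence[tuple[float, int]] | None
) -> int:
    """Map an error frequency to the score of the first band covering it.

    Bands are (upper-bound %, score) pairs with strictly increasing bounds; a
    frequency above every bound falls into the last (worst) band.
    """
    if not bands:
        raise ConfigurationError("frequency-kind control point has no frequency bands")
    if not 0.0 <= frequency_percent <= 100.0:
        raise DomainError(f"frequency {frequency_percent} outside [0, 100]")
    for bound, score in bands:
        if frequency_percent <= bound:
            return score
    return bands[-1][1]


def score_measurement(
    measurement: tuple[float, str], rule: MeasurementRule | None
) -> int:
    """Score a measured value against its acceptable range (closed interval).

    Inside the range → 1; within the configured margin outside it → 2; beyond
    the margin (or outside the range when no margin is configured) → 3.
    """
    if rule is None:
        raise ConfigurationError("measurement-kind control point has no acceptable range")
    value, unit = measurement
    if unit != rule.unit:
        raise DomainError(f"measurement unit {unit!r} does not match range unit {rule.unit!r}")
    if rule.minimum <= value <= rule.maximum:
        return 1
    if rule.margin is not None and (
        rule.minimum - rule.margin <= value <= rule.maximum + rule.margin
    ):
        return 2
    return 3


def finalize_score(observation: Observation, control_point: ControlPoint) -> int:
    """Reduce an observation's evidence to the cell's final score 0–3."""
    fields = observation.evidence_fields()
    if len(fields) > 1:
        raise ValidationError(
            f"observation for {observation.control_id!r} carries several evidence "
            f"fields: {fields}"
        )
    if not fields:
        return 0
    kind = control_point.kind
    if kind in ("behavioural", "structural"):
        if fields != ["raw_scores"]:
            raise ValidationError(
                f"{kind} control {control_point.id!r} needs raw_scores, got {fields[0]}"
            )
        return aggregate_behavioural(observation.raw_scores or [])
    if kind == "frequency":
        if fields != ["frequency_percent"]:
            raise ValidationError(
                f"frequency control {control_point.id!r} needs frequency_percent, got {fields[0]}"
            )
        return aggregate_frequency(
            observation.frequency_percent, control_point.frequency_bands
        )
    if kind == "measurement":
        if fields != ["measurement"]:
            raise ValidationError(
                f"measurement control {control_point.id!r} needs measurement, got {fields[0]}"
            )
        return score_measurement(observation.measurement, control_point.acceptable_range)
    raise ValidationError(f"unknown control point kind {kind!r}")


def build_cells(audit: Audit, protocol: Protocol) -> list[scoring.ScoredCell]:
    """Join observations to the protocol crosstabulation, one cell per pair.

    Every crosstabulation pair yields exactly one cell, in protocol order;
    pairs without an observation score 0 and drop out of both sums.  Weights
    resolve per-cell override first, then the catalog entry.
    """
    obs_map = audit.observation_map()
    valid_pairs = {(ch.index, cid) for ch, cid in protocol.pairs()}
    for key in obs_map:
        if key not in valid_pairs:
            raise ValidationError(
                f"observation for chapter {key[0]}, control {key[1]!r} has no "
                "matching crosstabulation pair in the protocol"
            )
    cells: list[scoring.ScoredCell] = []
    for chapter, control_id in protocol.pairs():
        cp = protocol.catalog[control_id]
        h, e = protocol.weights_for(chapter, control_id)
        obs = obs_map.get((chapter.index, control_id))
        s = finalize_score(obs, cp) if obs is not None else 0
        cells.append(scoring.score_cell(chapter.index, control_id, s, e, h))
    return cells


# ---------------------------------------------------------------------------
# audit file I/O (JSON)


def _measurement_from_json(obj) -> tuple[float, str]:
    value = obj["value"]
    if isinstance(value, str):
        value = float(value.strip().replace(",", "."))
    return (float(value), str(obj["unit"]))


def parse_audit(text: str) -> Audit:
    doc = json.loads(text)
    try:
        observations = []
        for rec in doc.get("observations", []):
            meas = rec.get("measurement")
            observations.append(
                Observation(
                    chapter_index=int(rec["chapter"]),
                    control_id=str(rec["control"]),
                    raw_scores=[int(s) for s in rec["raw_scores"]]
                    if rec.get("raw_scores") is not None
                    else None,
                    frequency_percent=float(rec["frequency_percent"])
                    if rec.get("frequency_percent") is not None
                    else None,
                    measurement=_measurement_from_json(meas) if meas is not None else None,
                    comment=str(rec.get("comment", "")),
                )
            )
        return Audit(
            protocol_name=str(doc["protocol"]),
            abattoir=str(doc["abattoir"]),
            line=str(doc.get("line", "")),
            date=_dt.date.fromisoformat(doc["date"]),
            assessor=str(doc.get("assessor", "")),
            observations=observations,
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValidationError(f"malformed audit file: {exc}") from exc


def load_audit(path: str | os.PathLike) -> Audit:
    return parse_audit(Path(path).read_text(encoding="utf-8"))


def write_audit(audit: Audit, path: str | os.PathLike | None = None) -> str:
    doc = {
        "protocol": audit.protocol_name,
        "abattoir": audit.abattoir,
        "line": audit.line,
        "date": audit.date.isoformat(),
        "assessor": audit.assessor,
        "observations": [],
    }
    for obs in audit.observations:
        rec: dict = {"chapter": obs.chapter_index, "control": obs.control_id}
        if obs.raw_scores is not None:
            rec["raw_scores"] = list(obs.raw_scores)
        if obs.frequency_percent is not None:
            rec["frequency_percent"] = obs.frequency_percent
        if obs.measurement is not None:
            rec["measurement"] = {"value": obs.measurement[0], "unit": obs.measurement[1]}
        if obs.comment:
            rec["comment"] = obs.comment
        doc["observations"].append(rec)
    text = json.dumps(doc, ensure_ascii=False, indent=2) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text
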