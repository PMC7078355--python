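"""Protocol data model: control points, chapters and their crosstabulation.

A Hygiene Performance Rating (HPR) protocol describes what an auditor looks
at on a slaughter line.  It has two layers:

* a **catalog** of control points — single auditable questions, each with a
  hygienic weight (1, 3, 6 or 12, reflecting hygienic impact and risk) and an
  economic weight (1 = fixing the deviation needs a considerable investment,
  2 = a cheap quick-fix exists, which is punished harder);
* an ordered list of **chapters** — positions along the slaughter line (plus
  management/premises categories) — each referencing the control points that
  apply at that position.

The same question is typically relevant at several positions, so chapters and
control points form a many-to-many *crosstabulation*; control points carry a
stable short ``id`` to act as the join key.  Weights live on the catalog entry
but may be overridden per (chapter, control point) cell.

The on-disk format is UTF-8 sectioned delimited text (tab or comma,
auto-detected from the header row)::

    [protocol]
    key<TAB>value            # name, species
    [catalog]
    id  question  kind  hygienic_weight  economic_weight  frequency_bands  acceptable_range
    [chapters]
    index  name  control_ids  weight_overrides

``frequency_bands`` encodes ordered (upper-bound %, score) pairs as
``bound:score`` joined by ``;`` (e.g. ``0.5:1;2:2;100:3``); ``acceptable_range``
encodes ``min..max[~margin] unit`` (e.g. ``82..100~8 °C``).  ``control_ids``
is ``;``-separated; ``weight_overrides`` holds ``id:h:e`` triples.
"""

from __future__ import annotations

import csv
import io
import os
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .errors import ProtocolParseError, ValidationError

ALLOWED_HYGIENIC_WEIGHTS = (1, 3, 6, 12)
ALLOWED_ECONOMIC_WEIGHTS = (1, 2)
KINDS = ("behavioural", "frequency", "measurement", "structural")

CATALOG_COLUMNS = (
    "id",
    "question",
    "kind",
    "hygienic_weight",
    "economic_weight",
    "frequency_bands",
    "acceptable_range",
)
CHAPTER_COLUMNS = ("index", "name", "control_ids", "weight_overrides")

_SECTION_RE = re.compile(r"^\[(\w+)\]\s*$")
_RANGE_RE = re.compile(
    r"^\s*(?P<min>[-\d.,]+)\.\.(?P<max>[-\d.,]+)(?:~(?P<margin>[\d.,]+))?\s+(?P<unit>.+?)\s*$"
)


def _parse_float(text: str) -> float:
    """Parse a decimal number, tolerating a comma decimal separator."""
    return float(text.strip().replace(",", "."))


def _fmt_num(x: float, decimal: str = "point") -> str:
    s = format(x, "g")
    if decimal == "comma":
        s = s.replace(".", ",")
    return s


@dataclass
class MeasurementRule:
    """Acceptable range for a measured value, with optional grace margin.

    Values inside [minimum, maximum] score 1 (acceptable); values within
    ``margin`` outside the range score 2 (potential for improvement); values
    further out — or any out-of-range value when no margin is configured —
    score 3 (not acceptable).
    """

    minimum: float
    maximum: float
    unit: str
    margin: float | None = None

    def encode(self, decimal: str = "point") -> str:
        core = f"{_fmt_num(self.minimum, decimal)}..{_fmt_num(self.maximum, decimal)}"
        if self.margin is not None:
            core += f"~{_fmt_num(self.margin, decimal)}"
        return f"{core} {self.unit}"

    @classmethod
    def decode(cls, text: str) -> "MeasurementRule":
        m = _RANGE_RE.match(text)
        if m is None:
            raise ProtocolParseError(f"cannot parse acceptable_range {text!r}")
        margin = m.group("margin")
        return cls(
            minimum=_parse_float(m.group("min")),
            maximum=_parse_float(m.group("max")),
            unit=m.group("unit"),
            margin=_parse_float(margin) if margin else None,
        )


@dataclass
class ControlPoint:
    """One auditable question with its weights and observation kind.

    ``kind`` selects the aggregation rule applied during an audit:
    behavioural/structural points record spot scores (worst deviation wins),
    frequency points record an error percentage mapped through
    ``frequency_bands``, measurement points record a value checked against
    ``acceptable_range``.
    """

    id: str
    question: str
    kind: str
    hygienic_weight: int
    economic_weight: int
    frequency_bands: tuple[tuple[float, int], ...] | None = None
    acceptable_range: MeasurementRule | None = None


@dataclass
class Chapter:
    """A position on the slaughter line and the control points applying there."""

    index: int
    name: str
    control_ids: list[str]
    #: per-cell (hygienic, economic) weight overrides, keyed by control id
    weight_overrides: dict[str, tuple[int, int]] = field(default_factory=dict)


@dataclass
class Protocol:
    """Ordered chapters plus the control-point catalog they draw from."""

    name: str
    species: str
    chapters: list[Chapter]
    catalog: dict[str, ControlPoint]

    def pairs(self) -> Iterator[tuple[Chapter, str]]:
        """Iterate the crosstabulation cells in protocol order."""
        for chapter in self.chapters:
            for control_id in chapter.control_ids:
                yield chapter, control_id

    def n_pairs(self) -> int:
        return sum(len(c.control_ids) for c in self.chapters)

    def weights_for(self, chapter: Chapter, control_id: str) -> tuple[int, int]:
        """Resolve (hygienic, economic) weights: cell override, else catalog."""
        if control_id in chapter.weight_overrides:
            return chapter.weight_overrides[control_id]
        cp = self.catalog[control_id]
        return cp.hygienic_weight, cp.economic_weight


@dataclass(frozen=True)
class Finding:
    """One validation finding: the violated invariant and the offending element."""

    invariant: str
    element: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - formatting only
        return f"{self.invariant} [{self.element}]: {self.message}"


def validate_protocol(protocol: Protocol) -> list[Finding]:
    """Check every structural invariant; an empty list means the protocol is valid.

    Findings are returned rather than raised so broken protocols can be
    inspected; :func:`load_protocol` turns a non-empty result into an error.
    """
    findings: list[Finding] = []

    for cp in protocol.catalog.values():
        if cp.kind not in KINDS:
            findings.append(
                Finding("control-point kind", cp.id, f"kind {cp.kind!r} not one of {KINDS}")
            )
        if cp.hygienic_weight not in ALLOWED_HYGIENIC_WEIGHTS:
            findings.append(
                Finding(
                    "hygienic weight",
                    cp.id,
                    f"hygienic_weight {cp.hygienic_weight} not in {ALLOWED_HYGIENIC_WEIGHTS}",
                )
            )
        if cp.economic_weight not in ALLOWED_ECONOMIC_WEIGHTS:
            findings.append(
                Finding(
                    "economic weight",
                    cp.id,
                    f"economic_weight {cp.economic_weight} not in {ALLOWED_ECONOMIC_WEIGHTS}",
                )
            )
        if cp.frequency_bands is not None:
            bounds = [b for b, _ in cp.frequency_bands]
            if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
                findings.append(
                    Finding(
                        "frequency bands order",
                        cp.id,
                        "upper bounds must be strictly increasing",
                    )
                )
            if any(score not in (1, 2, 3) for _, score in cp.frequency_bands):
                findings.append(
                    Finding("frequency band scores", cp.id, "band scores must be in {1,2,3}")
                )
        if cp.kind == "frequency" and not cp.frequency_bands:
            findings.append(
                Finding("frequency bands missing", cp.id, "frequency kind requires bands")
            )
        if cp.kind == "measurement" and cp.acceptable_range is None:
            findings.append(
                Finding("acceptable range missing", cp.id, "measurement kind requires a range")
            )
        if cp.acceptable_range is not None:
            rng = cp.acceptable_range
            if rng.minimum > rng.maximum:
                findings.append(
                    Finding("acceptable range order", cp.id, "range minimum exceeds maximum")
                )

    indices = [c.index for c in protocol.chapters]
    if len(set(indices)) != len(indices):
        dupes = sorted({i for i in indices if indices.count(i) > 1})
        findings.append(
            Finding("chapter index uniqueness", str(dupes), "duplicate chapter index")
        )
    elif indices != list(range(1, len(indices) + 1)):
        findings.append(
            Finding(
                "chapter index contiguity",
                str(indices),
                "chapter indices must run 1..n in order",
            )
        )

    referenced: set[str] = set()
    for chapter in protocol.chapters:
        label = f"chapter {chapter.index}"
        if not chapter.control_ids:
            findings.append(Finding("chapter non-empty", label, "no control points listed"))
        seen: set[str] = set()
        for cid in chapter.control_ids:
            if cid in seen:
                findings.append(
                    Finding("duplicate control in chapter", f"{label}/{cid}", "listed twice")
                )
            seen.add(cid)
            referenced.add(cid)
            if cid not in protocol.catalog:
                findings.append(
                    Finding("dangling control id", f"{label}/{cid}", "not in catalog")
                )
        for cid, (h, e) in chapter.weight_overrides.items():
            if cid not in chapter.control_ids:
                findings.append(
                    Finding(
                        "override target", f"{label}/{cid}", "override for control not in chapter"
                    )
                )
            if h not in ALLOWED_HYGIENIC_WEIGHTS or e not in ALLOWED_ECONOMIC_WEIGHTS:
                findings.append(
                    Finding(
                        "override weights",
                        f"{label}/{cid}",
                        f"override ({h},{e}) outside allowed weight sets",
                    )
                )

    for cid in protocol.catalog:
        if cid not in referenced:
            findings.append(
                Finding("orphan control point", cid, "catalog entry referenced by no chapter")
            )

    return findings


# ---------------------------------------------------------------------------
# serialization


def _encode_bands(bands: tuple[tuple[float, int], ...] | None, decimal: str) -> str:
    if not bands:
        return ""
    return ";".join(f"{_fmt_num(b, decimal)}:{s}" for b, s in bands)


def _decode_bands(text: str) -> tuple[tuple[float, int], ...] | None:
    text = text.strip()
    if not text:
        return None
    out = []
    for part in text.split(";"):
        bound, _, score = part.rpartition(":")
        if not bound:
            raise ProtocolParseError(f"cannot parse frequency band {part!r}")
        out.append((_parse_float(bound), int(score)))
    return tuple(out)


def write_protocol(
    protocol: Protocol,
    path: str | os.PathLike | None = None,
    *,
    delimiter: str = "\t",
    decimal: str = "point",
) -> str:
    """Serialize a protocol to the sectioned delimited-text format.

    ``decimal="comma"`` emits comma decimal separators for locale-compatible
    export; it requires the tab delimiter so numbers stay unambiguous.
    Returns the text; also writes it to ``path`` when given.
    """
    if decimal not in ("point", "comma"):
        raise ValueError(f"decimal must be 'point' or 'comma', got {decimal!r}")
    if decimal == "comma" and delimiter == ",":
        raise ValueError("comma-decimal export requires the tab delimiter")
    buf = io.StringIO()
    w = csv.writer(buf, delimiter=delimiter, lineterminator="\n")
    buf.write("[protocol]\n")
    w.writerow(["name", protocol.name])
    w.writerow(["species", protocol.species])
    buf.write("[catalog]\n")
    w.writerow(CATALOG_COLUMNS)
    for cp in protocol.catalog.values():
        w.writerow(
            [
                cp.id,
                cp.question,
                cp.kind,
                cp.hygienic_weight,
                cp.economic_weight,
                _encode_bands(cp.frequency_bands, decimal),
                cp.acceptable_range.encode(decimal) if cp.acceptable_range else "",
            ]
        )
    buf.write("[chapters]\n")
    w.writerow(CHAPTER_COLUMNS)
    for ch in protocol.chapters:
        overrides = ";".join(
            f"{cid}:{h}:{e}" for cid, (h, e) in ch.weight_overrides.items()
        )
        w.writerow([ch.index, ch.name, ";".join(ch.control_ids), overrides])
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def _split_sections(lines: Iterable[str]) -> dict[str, list[tuple[int, str]]]:
    sections: dict[str, list[tuple[int, str]]] = {}
    current: list[tuple[int, str]] | None = None
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n").rstrip("\r")
        m = _SECTION_RE.match(line)
        if m:
            name = m.group(1)
            if name in sections:
                raise ProtocolParseError(f"line {lineno}: duplicate section [{name}]")
            current = sections.setdefault(name, [])
            continue
        if not line.strip():
            continue
        if current is None:
            raise ProtocolParseError(f"line {lineno}: content before first section header")
        current.append((lineno, line))
    return sections


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def _read_rows(
    section: list[tuple[int, str]], columns: tuple[str, ...], what: str, delim: str
) -> list[tuple[int, list[str]]]:
    if not section:
        raise ProtocolParseError(f"section [{what}] is empty")
    header_lineno, header_line = section[0]
    header = next(csv.reader([header_line], delimiter=delim))
    if [h.strip() for h in header] != list(columns):
        raise ProtocolParseError(
            f"line {header_lineno}: [{what}] header must be {list(columns)}, got {header}"
        )
    rows = []
    for lineno, line in section[1:]:
        fields = next(csv.reader([line], delimiter=delim))
        if len(fields) != len(columns):
            raise ProtocolParseError(
                f"line {lineno}: expected {len(columns)} fields in [{what}] row, got {len(fields)}"
            )
        rows.append((lineno, fields))
    return rows


def parse_protocol(text: str) -> Protocol:
    """Parse protocol-file content; raises on malformed rows or invalid structure."""
    # split on \n only: csv-quoted fields may contain exotic line-break chars
    sections = _split_sections(text.split("\n"))
    for required in ("catalog", "chapters"):
        if required not in sections:
            raise ProtocolParseError(f"missing required section [{required}]")
    if not sections["catalog"]:
        raise ProtocolParseError("section [catalog] is empty")
    # the delimiter is detected once, from the catalog header row
    delim = _detect_delimiter(sections["catalog"][0][1])

    meta = {"name": "", "species": ""}
    for lineno, line in sections.get("protocol", []):
        fields = next(csv.reader([line], delimiter=delim))
        if len(fields) != 2:
            raise ProtocolParseError(f"line {lineno}: [protocol] rows are key/value pairs")
        meta[fields[0].strip()] = fields[1]

    catalog: dict[str, ControlPoint] = {}
    for lineno, fields in _read_rows(sections["catalog"], CATALOG_COLUMNS, "catalog", delim):
        cid, question, kind, hw, ew, bands, arange = fields
        cid = cid.strip()
        if cid in catalog:
            raise ProtocolParseError(f"line {lineno}: duplicate catalog id {cid!r}")
        try:
            hygienic = int(hw)
            economic = int(ew)
        except ValueError as exc:
            raise ProtocolParseError(f"line {lineno}: non-integer weight for {cid!r}") from exc
        try:
            freq_bands = _decode_bands(bands)
            rule = MeasurementRule.decode(arange) if arange.strip() else None
        except ProtocolParseError as exc:
            raise ProtocolParseError(f"line {lineno}: {exc}") from exc
        catalog[cid] = ControlPoint(
            id=cid,
            question=question,
            kind=kind.strip(),
            hygienic_weight=hygienic,
            economic_weight=economic,
            frequency_bands=freq_bands,
            acceptable_range=rule,
        )

    chapters: list[Chapter] = []
    for lineno, fields in _read_rows(sections["chapters"], CHAPTER_COLUMNS, "chapters", delim):
        idx, name, control_ids, overrides = fields
        try:
            index = int(idx)
        except ValueError as exc:
            raise ProtocolParseError(f"line {lineno}: non-integer chapter index {idx!r}") from exc
        ids = [c.strip() for c in control_ids.split(";") if c.strip()]
        ovr: dict[str, tuple[int, int]] = {}
        for triple in overrides.split(";"):
            triple = triple.strip()
            if not triple:
                continue
            parts = triple.split(":")
            if len(parts) != 3:
                raise ProtocolParseError(
                    f"line {lineno}: weight override {triple!r} is not id:h:e"
                )
            try:
                ovr[parts[0]] = (int(parts[1]), int(parts[2]))
            except ValueError as exc:
                raise ProtocolParseError(
                    f"line {lineno}: non-integer weights in override {triple!r}"
                ) from exc
        chapters.append(Chapter(index=index, name=name, control_ids=ids, weight_overrides=ovr))

    protocol = Protocol(
        name=meta["name"], species=meta["species"], chapters=chapters, catalog=catalog
    )
    findings = validate_protocol(protocol)
    if findings:
        raise ValidationError(
            "invalid protocol:\n" + "\n".join(str(f) for f in findings)
        )
    return protocol


def load_protocol(source: str | os.PathLike) -> Protocol:
    """Load a protocol from a file path or from in-memory file content."""
    if isinstance(source, os.PathLike):
        return parse_protocol(Path(source).read_text(encoding="utf-8"))
    if "\n" not in source and Path(source).exists():
        return parse_protocol(Path(source).read_text(encoding="utf-8"))
    return parse_protocol(source)
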