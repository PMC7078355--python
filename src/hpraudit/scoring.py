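"""Weighted scoring arithmetic and A–D grade assignment.

Every observed control point gets a score *s* in {1, 2, 3} (1 acceptable,
2 potential for improvement, 3 not acceptable); 0 marks a point that was not
observed or does not apply on this line.  With economic weight *e* and
hygienic weight *h*:

* weighted result  W = s·e·h, forced to 0 when s is 0 or 1;
* theoretical maximum  M = 3·e·h, forced to 0 when s = 0.

Percentages are deductions from perfect hygiene: a single score is
100 − (W/M)·100, a chapter score sums W and M over the chapter's cells, and
the total score pools W and M over *all* cells (it is not a mean of chapter
percentages).  Because an unobserved point contributes nothing to either sum,
irrelevant operations (e.g. rodding on a line without it) influence the result
only marginally.

The total maps to a grade A–D; the top two bands additionally require every
applicable chapter to stay above a floor (A: no chapter below 60.0%, B: none
below 50.0%).  Band edges are read at one-decimal resolution, so percentages
are rounded half away from zero to one decimal before comparison.
"""

from __future__ import annotations

import csv
import io
import os
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .errors import DomainError, EmptyAuditError, ProtocolParseError, ValidationError

VALID_SCORES = (0, 1, 2, 3)
_OBSERVATION_MEANING = {0: "not observed", 1: "acceptable", 2: "potential for improvement", 3: "not acceptable"}


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (decimal semantics)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def _tenths(x: float) -> int:
    """A one-decimal percentage as an exact integer count of tenths."""
    return int(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP).scaleb(1))


def _check_domain(s: int, e: int, h: int) -> None:
    if s not in VALID_SCORES:
        raise DomainError(f"observation score {s} not in {VALID_SCORES}")
    if e not in (1, 2):
        raise DomainError(f"economic weight {e} not in (1, 2)")
    if h not in (1, 3, 6, 12):
        raise DomainError(f"hygienic weight {h} not in (1, 3, 6, 12)")


def weighted_result(s: int, e: int, h: int) -> int:
    """W = s·e·h for s in {2,3}; 0 for s in {0,1} (acceptable costs nothing)."""
    _check_domain(s, e, h)
    return 0 if s in (0, 1) else s * e * h


def theoretical_max(s: int, e: int, h: int) -> int:
    """M = 3·e·h for any observed point; 0 when the point was not observed."""
    _check_domain(s, e, h)
    return 0 if s == 0 else 3 * e * h


@dataclass(frozen=True)
class ScoredCell:
    """One (chapter, control point) cell with its weighted contribution."""

    chapter_index: int
    control_id: str
    observation_score: int
    weighted_result: int
    theoretical_max: int


def score_cell(chapter_index: int, control_id: str, s: int, e: int, h: int) -> ScoredCell:
    return ScoredCell(
        chapter_index=chapter_index,
        control_id=control_id,
        observation_score=s,
        weighted_result=weighted_result(s, e, h),
        theoretical_max=theoretical_max(s, e, h),
    )


def _percent(w: int, m: int) -> float:
    return round_half_up(100.0 - (w / m) * 100.0, 1)


def single_score_percent(cell: ScoredCell) -> float | None:
    """100 − (W/M)·100 for one cell; None (not applicable) when M = 0."""
    if cell.theoretical_max == 0:
        return None
    return _percent(cell.weighted_result, cell.theoretical_max)


def chapter_score(cells: Sequence[ScoredCell]) -> float | None:
    """Pooled percentage over one chapter's cells; None when nothing applies."""
    indices = {c.chapter_index for c in cells}
    if len(indices) > 1:
        raise DomainError(f"cells span several chapters: {sorted(indices)}")
    w = sum(c.weighted_result for c in cells)
    m = sum(c.theoretical_max for c in cells)
    if m == 0:
        return None
    return _percent(w, m)


def total_score(cells: Iterable[ScoredCell]) -> float:
    """Pooled percentage over all cells of an audit (not a mean of chapters)."""
    cells = list(cells)
    w = sum(c.weighted_result for c in cells)
    m = sum(c.theoretical_max for c in cells)
    if m == 0:
        raise EmptyAuditError("no observed control points (total theoretical maximum is 0)")
    return _percent(w, m)


# ---------------------------------------------------------------------------
# grade bands


@dataclass(frozen=True)
class GradeBand:
    label: str
    total_min: float
    total_max: float
    chapter_min: float | None = None

    def contains_total(self, total: float) -> bool:
        return _tenths(self.total_min) <= _tenths(total) <= _tenths(self.total_max)

    def chapters_ok(self, chapter_scores: Iterable[float | None]) -> bool:
        if self.chapter_min is None:
            return True
        floor = _tenths(self.chapter_min)
        return all(_tenths(s) >= floor for s in chapter_scores if s is not None)


@dataclass(frozen=True)
class GradeBands:
    """Ordered grade bands, best first; must partition [0, 100] in tenths."""

    bands: tuple[GradeBand, ...]

    def __post_init__(self) -> None:
        ordered = sorted(self.bands, key=lambda b: -_tenths(b.total_max))
        object.__setattr__(self, "bands", tuple(ordered))
        if not self.bands:
            raise ValidationError("grade band table is empty")
        if _tenths(self.bands[0].total_max) != 1000 or _tenths(self.bands[-1].total_min) != 0:
            raise ValidationError("grade bands must cover 0.0–100.0")
        for upper, lower in zip(self.bands, self.bands[1:]):
            if _tenths(lower.total_max) != _tenths(upper.total_min) - 1:
                raise ValidationError(
                    f"bands {upper.label}/{lower.label} do not abut at one-decimal resolution"
                )

    def band_for_total(self, total: float) -> GradeBand:
        for band in self.bands:
            if band.contains_total(total):
                return band
        raise DomainError(f"total {total} outside 0–100")

    @classmethod
    def default(cls) -> "GradeBands":
        """The bundled band table: A 85.1–100.0 (chapters ≥ 60.0), B 70.1–85.0
        (chapters ≥ 50.0), C 55.1–70.0, D 0.0–55.0."""
        with resources.files("hpraudit").joinpath("data/grade_bands.csv").open(
            "r", encoding="utf-8"
        ) as fh:
            return parse_bands(fh.read())


def parse_bands(text: str) -> GradeBands:
    """Parse a band configuration file: CSV ``label,total_min,total_max,chapter_min``."""
    rows = list(csv.reader(io.StringIO(text)))
    rows = [r for r in rows if r and any(f.strip() for f in r)]
    if not rows or [c.strip() for c in rows[0]] != ["label", "total_min", "total_max", "chapter_min"]:
        raise ProtocolParseError("band file header must be label,total_min,total_max,chapter_min")
    bands = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != 4:
            raise ProtocolParseError(f"line {lineno}: band rows need 4 fields")
        label, tmin, tmax, cmin = (f.strip() for f in row)
        try:
            bands.append(
                GradeBand(
                    label=label,
                    total_min=float(tmin.replace(",", ".")),
                    total_max=float(tmax.replace(",", ".")),
                    chapter_min=float(cmin.replace(",", ".")) if cmin else None,
                )
            )
        except ValueError as exc:
            raise ProtocolParseError(f"line {lineno}: non-numeric band edge") from exc
    return GradeBands(tuple(bands))


def load_bands(path: str | os.PathLike) -> GradeBands:
    return parse_bands(Path(path).read_text(encoding="utf-8"))


def write_bands(bands: GradeBands, path: str | os.PathLike | None = None) -> str:
    buf = io.StringIO()
    w = csv.writer(buf, lineterminator="\n")
    w.writerow(["label", "total_min", "total_max", "chapter_min"])
    for b in bands.bands:
        w.writerow(
            [b.label, format(b.total_min, "g"), format(b.total_max, "g"),
             "" if b.chapter_min is None else format(b.chapter_min, "g")]
        )
    text = buf.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


@dataclass(frozen=True)
class GradeAssignment:
    """Outcome of grading: final label, the band the total alone selects, and
    whether a chapter floor demoted the grade."""

    label: str
    band_by_total: str
    demoted: bool
    failed_chapters: tuple[int, ...] = ()


def grade_assignment(
    total: float,
    chapter_scores: Sequence[float | None],
    bands: GradeBands | None = None,
) -> GradeAssignment:
    """Assign a grade with the chapter-floor cascade.

    The band containing the (one-decimal) total is selected first.  If its
    chapter floor fails for any applicable chapter, the grade cascades to the
    next worse band whose floor holds; not-applicable chapters are ignored.
    """
    bands = bands or GradeBands.default()
    primary = bands.band_for_total(total)
    start = bands.bands.index(primary)
    for offset, band in enumerate(bands.bands[start:]):
        if band.chapters_ok(chapter_scores):
            failed = ()
            if offset > 0 and primary.chapter_min is not None:
                floor = _tenths(primary.chapter_min)
                failed = tuple(
                    i + 1
                    for i, s in enumerate(chapter_scores)
                    if s is not None and _tenths(s) < floor
                )
            return GradeAssignment(
                label=band.label,
                band_by_total=primary.label,
                demoted=offset > 0,
                failed_chapters=failed,
            )
    # the last band has no floor in any sane configuration; guard anyway
    return GradeAssignment(
        label=bands.bands[-1].label, band_by_total=primary.label, demoted=True
    )


def assign_grade(
    total: float,
    chapter_scores: Sequence[float | None],
    bands: GradeBands | None = None,
) -> str:
    """Grade label only; see :func:`grade_assignment` for the demotion detail."""
    return grade_assignment(total, chapter_scores, bands).label
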