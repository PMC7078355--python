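"""Feedback artifacts: score report, per-chapter profile, benchmarking.

The score report carries what the feedback meeting needs: the chapter score
profile (where on the line improvement is most needed), the pooled total, the
grade, and every deviation (score 2 or 3) with its comment, worst first.
Benchmarking lines up several audits of the same line chronologically and
shows per-chapter deltas between consecutive audits, but the emphasis stays
on the direct observations and comments, not the league table.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import scoring, session
from .errors import ValidationError
from .protocol import Protocol
from .scoring import GradeBands, ScoredCell

NOT_APPLICABLE = "n/a"


@dataclass
class ChapterResult:
    index: int
    name: str
    weighted_sum: int
    max_sum: int
    percent: float | None          # one-decimal, None = not applicable
    percent_raw: float | None      # unrounded, for transparency


@dataclass
class Deviation:
    chapter_index: int
    chapter_name: str
    control_id: str
    question: str
    score: int
    weighted_result: int
    comment: str


@dataclass
class ScoreReport:
    """Per-chapter percentages, pooled total, grade and flagged deviations."""

    protocol_name: str
    audit_id: str
    date: str
    chapters: list[ChapterResult]
    total: float
    total_raw: float
    grade: str
    grade_by_total: str
    demoted: bool
    deviations: list[Deviation] = field(default_factory=list)

    def chapter_percents(self) -> list[float | None]:
        return [c.percent for c in self.chapters]

    def to_dict(self) -> dict:
        return {
            "protocol": self.protocol_name,
            "audit": self.audit_id,
            "date": self.date,
            "total_percent": self.total,
            "total_percent_raw": self.total_raw,
            "grade": self.grade,
            "grade_by_total": self.grade_by_total,
            "demoted_by_chapter_floor": self.demoted,
            "chapters": [
                {
                    "index": c.index,
                    "name": c.name,
                    "weighted_sum": c.weighted_sum,
                    "theoretical_max_sum": c.max_sum,
                    "percent": c.percent,
                    "percent_raw": c.percent_raw,
                }
                for c in self.chapters
            ],
            "deviations": [
                {
                    "chapter": d.chapter_index,
                    "chapter_name": d.chapter_name,
                    "control": d.control_id,
                    "question": d.question,
                    "score": d.score,
                    "weighted_result": d.weighted_result,
                    "comment": d.comment,
                }
                for d in self.deviations
            ],
        }


def build_report(
    audit: session.Audit,
    protocol: Protocol,
    bands: GradeBands | None = None,
) -> ScoreReport:
    """Score an audit end to end and assemble the feedback report.

    Chapter and total percentages come straight from the scoring module (no
    re-derivation); deviations are all cells scoring 2 or 3, sorted by
    weighted result descending so the worst finding leads.
    """
    bands = bands or GradeBands.default()
    cells = session.build_cells(audit, protocol)
    by_chapter: dict[int, list[ScoredCell]] = {}
    for cell in cells:
        by_chapter.setdefault(cell.chapter_index, []).append(cell)

    chapters: list[ChapterResult] = []
    for chapter in protocol.chapters:
        chapter_cells = by_chapter.get(chapter.index, [])
        w = sum(c.weighted_result for c in chapter_cells)
        m = sum(c.theoretical_max for c in chapter_cells)
        pct = scoring.chapter_score(chapter_cells) if chapter_cells else None
        chapters.append(
            ChapterResult(
                index=chapter.index,
                name=chapter.name,
                weighted_sum=w,
                max_sum=m,
                percent=pct,
                percent_raw=None if m == 0 else 100.0 - (w / m) * 100.0,
            )
        )

    total = scoring.total_score(cells)
    w_all = sum(c.weighted_result for c in cells)
    m_all = sum(c.theoretical_max for c in cells)
    assignment = scoring.grade_assignment(total, [c.percent for c in chapters], bands)

    obs_map = audit.observation_map()
    chapter_names = {c.index: c.name for c in protocol.chapters}
    deviations = []
    for cell in cells:
        if cell.observation_score >= 2:
            obs = obs_map.get((cell.chapter_index, cell.control_id))
            deviations.append(
                Deviation(
                    chapter_index=cell.chapter_index,
                    chapter_name=chapter_names[cell.chapter_index],
                    control_id=cell.control_id,
                    question=protocol.catalog[cell.control_id].question,
                    score=cell.observation_score,
                    weighted_result=cell.weighted_result,
                    comment=obs.comment if obs else "",
                )
            )
    deviations.sort(key=lambda d: -d.weighted_result)

    return ScoreReport(
        protocol_name=protocol.name,
        audit_id=audit.identifier,
        date=audit.date.isoformat(),
        chapters=chapters,
        total=total,
        total_raw=100.0 - (w_all / m_all) * 100.0,
        grade=assignment.label,
        grade_by_total=assignment.band_by_total,
        demoted=assignment.demoted,
        deviations=deviations,
    )


def write_report(report: ScoreReport, path: str | os.PathLike | None = None) -> str:
    text = json.dumps(report.to_dict(), ensure_ascii=False, indent=2) + "\n"
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def render_markdown(report: ScoreReport) -> str:
    """Human-readable rendering of a score report (Markdown)."""
    lines = [
        f"# Hygiene Performance Rating — {report.audit_id}",
        "",
        f"Protocol: {report.protocol_name}  ",
        f"Date: {report.date}  ",
        f"**Total score: {report.total:.1f}%  Grade: {report.grade}**",
    ]
    if report.demoted:
        lines.append(
            f"(demoted from {report.grade_by_total} because a chapter fell below "
            "the band's chapter floor)"
        )
    lines += ["", "## Chapter profile", "", "| Chapter | Position | Score |", "|---|---|---|"]
    for c in report.chapters:
        score = NOT_APPLICABLE if c.percent is None else f"{c.percent:.1f}%"
        lines.append(f"| {c.index} | {c.name} | {score} |")
    lines += ["", "## Deviations (worst first)", ""]
    if not report.deviations:
        lines.append("No deviations: every observed control point was acceptable.")
    for d in report.deviations:
        comment = f" — {d.comment}" if d.comment else ""
        lines.append(
            f"- [{d.chapter_index}. {d.chapter_name}] {d.question} "
            f"(score {d.score}, weighted result {d.weighted_result}){comment}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# per-chapter profile export (bar-profile analogue)


def profile_frame(report: ScoreReport) -> pd.DataFrame:
    """Chapter-indexed profile table; not-applicable chapters carry 'n/a'."""
    return pd.DataFrame(
        {
            "chapter": [c.index for c in report.chapters],
            "name": [c.name for c in report.chapters],
            "score_percent": [
                NOT_APPLICABLE if c.percent is None else f"{c.percent:.1f}"
                for c in report.chapters
            ],
        }
    )


def export_profile(report: ScoreReport, path: str | os.PathLike | None = None) -> str:
    """Write the chapter profile as tab-delimited text; returns the text."""
    text = profile_frame(report).to_csv(sep="\t", index=False)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def read_profile(text_or_path: str | os.PathLike) -> list[tuple[int, str, float | None]]:
    """Re-parse an exported profile into (chapter, name, percent) rows."""
    if isinstance(text_or_path, os.PathLike):
        text = Path(text_or_path).read_text(encoding="utf-8")
    else:
        text = text_or_path
    rows = []
    for line in text.strip().splitlines()[1:]:
        chapter, name, score = line.split("\t")
        rows.append((int(chapter), name, None if score == NOT_APPLICABLE else float(score)))
    return rows


def plot_profile(report: ScoreReport, path: str | os.PathLike | None = None, ax=None):
    """Bar chart of the chapter profile: chapters on x, 0–100 % on y."""
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    indices = [c.index for c in report.chapters]
    values = [0.0 if c.percent is None else c.percent for c in report.chapters]
    labels = [
        NOT_APPLICABLE if c.percent is None else f"{c.percent:.0f}" for c in report.chapters
    ]
    bars = ax.bar(indices, values, color="#3b6ea5")
    ax.bar_label(bars, labels=labels, fontsize=8)
    ax.set_xticks(indices)
    ax.set_ylim(0, 105)
    ax.set_xlabel("Chapter (position on the slaughter line)")
    ax.set_ylabel("Score (%)")
    ax.set_title(f"{report.audit_id} — total {report.total:.1f}% (grade {report.grade})")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


# ---------------------------------------------------------------------------
# benchmarking across stored audits


@dataclass
class BenchmarkTable:
    """Chronological comparison of several audits of the same protocol."""

    protocol_name: str
    frame: pd.DataFrame    # one row per audit: id, date, chapter_*, total, grade
    deltas: pd.DataFrame   # per-chapter change vs the previous audit


def benchmark(
    audits: Sequence[session.Audit],
    protocol: Protocol,
    bands: GradeBands | None = None,
) -> BenchmarkTable:
    """Score each audit and line the results up chronologically.

    All audits must reference the same protocol; deltas are computed on the
    rounded percentages readers see, between consecutive audits.
    """
    if not audits:
        raise ValidationError("benchmark needs at least one audit")
    names = {a.protocol_name for a in audits}
    if len(names) > 1 or names != {protocol.name}:
        raise ValidationError(
            f"audits reference mixed protocols {sorted(names)}; expected {protocol.name!r}"
        )
    bands = bands or GradeBands.default()
    reports = [build_report(a, protocol, bands) for a in audits]
    order = sorted(range(len(audits)), key=lambda i: (audits[i].date, audits[i].identifier))

    chapter_cols = [f"chapter_{c.index}" for c in protocol.chapters]
    rows, delta_rows = [], []
    prev: ScoreReport | None = None
    for i in order:
        rep = reports[i]
        row = {"audit": rep.audit_id, "date": rep.date}
        for c in rep.chapters:
            row[f"chapter_{c.index}"] = c.percent
        row["total"] = rep.total
        row["grade"] = rep.grade
        rows.append(row)
        if prev is not None:
            drow = {"audit": rep.audit_id, "date": rep.date}
            for c, p in zip(rep.chapters, prev.chapters):
                drow[f"chapter_{c.index}"] = (
                    None
                    if c.percent is None or p.percent is None
                    else round(c.percent - p.percent, 1)
                )
            drow["total"] = round(rep.total - prev.total, 1)
            delta_rows.append(drow)
        prev = rep

    frame = pd.DataFrame(rows, columns=["audit", "date", *chapter_cols, "total", "grade"])
    deltas = pd.DataFrame(delta_rows, columns=["audit", "date", *chapter_cols, "total"])
    return BenchmarkTable(protocol_name=protocol.name, frame=frame, deltas=deltas)
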