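import dataclasses
import datetime

import pytest

import hpraudit as h
from hpraudit.errors import ValidationError
from hpraudit.protocol import Chapter, ControlPoint, Protocol


def _mini_protocol():
    catalog = {
        cid: ControlPoint(id=cid, question=f"Q {cid}?", kind="behavioural",
                          hygienic_weight=6, economic_weight=1)
        for cid in ("a", "b", "c")
    }
    chapters = [
        Chapter(index=1, name="First", control_ids=["a", "b"]),
        Chapter(index=2, name="Second", control_ids=["c"]),
    ]
    return Protocol(name="Mini", species="sheep", chapters=chapters, catalog=catalog)


def _audit(protocol, scores, date=datetime.date(2021, 5, 1)):
    observations = [
        h.Observation(ch.index, cid, raw_scores=[score], comment=f"spot {score}")
        for (ch, cid), score in zip(protocol.pairs(), scores)
    ]
    return h.Audit(protocol_name=protocol.name, abattoir="Abattoir", line="L1",
                   date=date, assessor="A", observations=observations)


def test_report_matches_scoring_module_exactly(table2):
    protocol, audit = table2
    report = h.build_report(audit, protocol)
    cells = h.build_cells(audit, protocol)
    assert report.total == h.total_score(cells)
    assert report.chapter_percents() == [h.chapter_score(cells)]
    assert report.grade == h.assign_grade(report.total, report.chapter_percents())
    assert report.chapters[0].weighted_sum == 102
    assert report.chapters[0].max_sum == 162


def test_worked_example_deviations_worst_first(table2):
    protocol, audit = table2
    report = h.build_report(audit, protocol)
    assert [d.weighted_result for d in report.deviations] == [72, 18, 12]
    assert report.deviations[0].question == "Visible contaminations from skin onto carcass"
    assert "hand wash" in report.deviations[2].comment.lower()
    cells = h.build_cells(audit, protocol)
    assert len(report.deviations) == sum(1 for c in cells if c.observation_score >= 2)


def test_all_acceptable_audit_grades_a_with_no_deviations():
    protocol = _mini_protocol()
    report = h.build_report(_audit(protocol, [1, 1, 1]), protocol)
    assert (report.total, report.grade, report.deviations) == (100.0, "A", [])
    assert report.demoted is False


def test_unobserved_chapter_is_not_applicable_never_zero():
    protocol = _mini_protocol()
    report = h.build_report(_audit(protocol, [1, 2, 0]), protocol)
    assert report.chapters[1].percent is None
    frame = h.profile_frame(report)
    assert list(frame["score_percent"]) == ["66.7", "n/a"]


def test_profile_export_round_trips_exactly(tmp_path, sheep):
    audit = h.random_audit(sheep, h.AuditScenario(seed=5, quality="mixed", coverage=0.8))
    report = h.build_report(audit, sheep)
    path = tmp_path / "profile.tsv"
    h.export_profile(report, path)
    rows = h.read_profile(path)
    assert len(rows) == 12
    assert [r[2] for r in rows] == report.chapter_percents()


def test_plot_profile_writes_image(tmp_path, table2):
    protocol, audit = table2
    report = h.build_report(audit, protocol)
    path = tmp_path / "profile.png"
    h.plot_profile(report, path)
    assert path.stat().st_size > 0


def test_render_markdown_carries_total_grade_and_comments(table2):
    protocol, audit = table2
    text = h.render_markdown(h.build_report(audit, protocol))
    assert "37.0%" in text and "Grade: D" in text
    assert "Frequency 3%" in text


def test_report_json_round_trip_values(tmp_path, table2):
    protocol, audit = table2
    report = h.build_report(audit, protocol)
    import json

    doc = json.loads(h.write_report(report, tmp_path / "report.json"))
    assert doc["total_percent"] == 37.0
    assert doc["grade"] == "D"
    assert doc["chapters"][0]["theoretical_max_sum"] == 162


def test_benchmark_identical_audits_have_zero_deltas():
    protocol = _mini_protocol()
    a1 = _audit(protocol, [1, 2, 3], date=datetime.date(2021, 1, 1))
    a2 = _audit(protocol, [1, 2, 3], date=datetime.date(2021, 6, 1))
    table = h.benchmark([a2, a1], protocol)  # deliberately out of order
    assert list(table.frame["date"]) == ["2021-01-01", "2021-06-01"]  # chronological
    assert list(table.deltas["chapter_1"]) == [0.0]
    assert list(table.deltas["total"]) == [0.0]


def test_benchmark_single_audit_has_empty_deltas():
    protocol = _mini_protocol()
    table = h.benchmark([_audit(protocol, [1, 2, 3])], protocol)
    assert len(table.frame) == 1 and len(table.deltas) == 0


def test_benchmark_flags_improvement_in_the_right_chapter():
    protocol = _mini_protocol()
    before = _audit(protocol, [1, 3, 2], date=datetime.date(2021, 1, 1))
    after = _audit(protocol, [1, 1, 2], date=datetime.date(2021, 6, 1))
    table = h.benchmark([before, after], protocol)
    # chapter 1 improved (a "3" became a "1"), chapter 2 unchanged
    d = table.deltas.iloc[0]
    assert d["chapter_1"] > 0 and d["chapter_2"] == 0.0 and d["total"] > 0
    # oracle: recompute both chapter-1 percentages from raw sums
    assert d["chapter_1"] == pytest.approx(
        (100 - 0 / 36 * 100) - (100 - 18 / 36 * 100)
    )


def test_benchmark_rejects_mixed_protocols():
    protocol = _mini_protocol()
    alien = dataclasses.replace(_audit(protocol, [1, 1, 1]), protocol_name="Other")
    with pytest.raises(ValidationError, match="mixed"):
        h.benchmark([_audit(protocol, [1, 1, 1]), alien], protocol)
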