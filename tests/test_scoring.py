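import itertools

import pytest

import hpraudit as h
from hpraudit.errors import DomainError, EmptyAuditError, ProtocolParseError, ValidationError
from hpraudit.scoring import GradeBand, GradeBands, round_half_up


@pytest.mark.parametrize(
    "s, e, hw, expected_w, expected_m",
    [
        (2, 1, 6, 12, 18),   # hand-wash cell of the worked example
        (1, 2, 6, 0, 36),    # acceptable observation: W forced to 0, M kept
        (3, 2, 12, 72, 72),  # worst case: W equals M
        (0, 2, 6, 0, 0),     # not observed: both sums untouched
        (0, 1, 6, 0, 0),
    ],
)
def test_weighted_result_and_theoretical_max(s, e, hw, expected_w, expected_m):
    assert h.weighted_result(s, e, hw) == expected_w
    assert h.theoretical_max(s, e, hw) == expected_m


def test_rule_arithmetic_brute_force_all_combinations():
    """Exhaustive agreement with a literal restatement of the scoring rules."""
    for s, e, hw in itertools.product(range(4), (1, 2), (1, 3, 6, 12)):
        w_oracle = s * e * hw
        m_oracle = 3 * e * hw
        if s == 0:
            w_oracle = m_oracle = 0
        if s == 1:
            w_oracle = 0
        assert h.weighted_result(s, e, hw) == w_oracle
        assert h.theoretical_max(s, e, hw) == m_oracle
        assert w_oracle <= m_oracle
        assert w_oracle % (e * hw) == 0 and m_oracle % (e * hw) == 0


@pytest.mark.parametrize("bad", [(4, 1, 6), (-1, 1, 6), (2, 3, 6), (2, 1, 5)])
def test_out_of_domain_inputs_rejected(bad):
    with pytest.raises(DomainError):
        h.weighted_result(*bad)
    with pytest.raises(DomainError):
        h.theoretical_max(*bad)


def test_single_score_percent():
    assert h.single_score_percent(h.score_cell(1, "x", 1, 2, 12)) == 100.0
    assert h.single_score_percent(h.score_cell(1, "x", 3, 1, 3)) == 0.0
    assert h.single_score_percent(h.score_cell(1, "x", 2, 1, 6)) == 33.3
    assert h.single_score_percent(h.score_cell(1, "x", 0, 1, 6)) is None


def test_chapter_score_on_worked_example_cells(table2):
    protocol, audit = table2
    cells = h.build_cells(audit, protocol)
    assert h.chapter_score(cells) == 37.0
    assert h.total_score(cells) == 37.0


def test_chapter_score_degenerate_cases():
    all_ones = [h.score_cell(2, f"c{i}", 1, 1, 6) for i in range(3)]
    assert h.chapter_score(all_ones) == 100.0
    all_zero = [h.score_cell(2, f"c{i}", 0, 2, 12) for i in range(3)]
    assert h.chapter_score(all_zero) is None
    with pytest.raises(DomainError):
        h.chapter_score([h.score_cell(1, "a", 1, 1, 1), h.score_cell(2, "b", 1, 1, 1)])


def test_total_score_empty_audit_is_an_error():
    with pytest.raises(EmptyAuditError):
        h.total_score([h.score_cell(1, "a", 0, 1, 6)])


def test_total_pools_cells_rather_than_averaging_chapters():
    # chapter 1 scores 0%, chapter 2 scores 100%; the pooled total is not 50%
    cells = [h.score_cell(1, "a", 3, 1, 1), h.score_cell(2, "b", 1, 2, 12)]
    assert h.chapter_score(cells[:1]) == 0.0
    assert h.chapter_score(cells[1:]) == 100.0
    assert h.total_score(cells) == round_half_up(100 - 3 / 75 * 100, 1) == 96.0


@pytest.mark.parametrize(
    "x, expected",
    [(37.037, 37.0), (33.333, 33.3), (85.05, 85.1), (0.04, 0.0), (99.95, 100.0)],
)
def test_rounding_is_half_away_from_zero_at_one_decimal(x, expected):
    assert round_half_up(x) == expected


@pytest.mark.parametrize(
    "total, expected",
    [(85.1, "A"), (85.0, "B"), (70.1, "B"), (70.0, "C"), (55.1, "C"), (55.0, "D"), (0.0, "D")],
)
def test_grade_band_boundaries(total, expected):
    chapters = [100.0, 100.0, 60.0]  # no chapter below any floor
    assert h.assign_grade(total, chapters) == expected


def test_grade_cascade_on_chapter_floor():
    # total in A's range but one chapter below 60 → demoted to B (floor 50 holds)
    a = h.grade_assignment(90.0, [100.0, 55.0])
    assert (a.label, a.band_by_total, a.demoted) == ("B", "A", True)
    assert a.failed_chapters == (2,)
    # chapter below 50 fails B's floor as well → C (no floor)
    assert h.assign_grade(90.0, [100.0, 40.0]) == "C"
    # not-applicable chapters cannot fail a floor
    assert h.assign_grade(90.0, [None, 100.0]) == "A"
    # inside the band and floors hold → no demotion
    assert h.grade_assignment(100.0, [100.0, 100.0]).demoted is False


def test_default_bands_reproduce_the_published_table():
    bands = GradeBands.default()
    assert [(b.label, b.total_min, b.total_max, b.chapter_min) for b in bands.bands] == [
        ("A", 85.1, 100.0, 60.0),
        ("B", 70.1, 85.0, 50.0),
        ("C", 55.1, 70.0, None),
        ("D", 0.0, 55.0, None),
    ]


def test_bands_partition_unit_interval_at_one_decimal():
    bands = GradeBands.default()
    for tenth in range(0, 1001):
        total = tenth / 10
        containing = [b for b in bands.bands if b.contains_total(total)]
        assert len(containing) == 1, total


def test_band_file_round_trip_and_validation(tmp_path):
    bands = GradeBands.default()
    path = tmp_path / "bands.csv"
    h.write_bands(bands, path)
    assert h.load_bands(path) == bands
    with pytest.raises(ValidationError, match="abut"):
        GradeBands(
            (
                GradeBand("A", 90.0, 100.0),
                GradeBand("B", 0.0, 85.0),
            )
        )
    with pytest.raises(ProtocolParseError):
        h.parse_bands("not,a,band,file\n")
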