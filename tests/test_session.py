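import datetime

import pytest

import hpraudit as h
from hpraudit.errors import ConfigurationError, DomainError, ValidationError
from hpraudit.protocol import MeasurementRule

FIXTURE_BANDS = ((1.0, 1), (5.0, 2), (100.0, 3))
TEMP_RULE = MeasurementRule(minimum=82.0, maximum=100.0, unit="°C", margin=8.0)


@pytest.mark.parametrize(
    "raw, expected",
    [
        ([1, 2, 1, 3], 3),  # worst deviation of the day, not the average
        ([1, 1, 1], 1),
        ([2], 2),
        ([0, 1, 0, 2], 2),  # spot-level zeros are ignored
        ([], 0),            # never observed
        ([0, 0], 0),
    ],
)
def test_aggregate_behavioural_worst_deviation(raw, expected):
    assert h.aggregate_behavioural(raw) == expected


def test_aggregate_behavioural_rejects_bad_spot_scores():
    with pytest.raises(DomainError):
        h.aggregate_behavioural([1, 4])


@pytest.mark.parametrize(
    "freq, expected",
    [(0.0, 1), (1.0, 1), (3.0, 2), (5.0, 2), (6.0, 3), (100.0, 3)],
)
def test_aggregate_frequency_band_lookup(freq, expected):
    assert h.aggregate_frequency(freq, FIXTURE_BANDS) == expected


def test_aggregate_frequency_requires_bands_and_valid_domain():
    with pytest.raises(ConfigurationError):
        h.aggregate_frequency(3.0, None)
    with pytest.raises(DomainError):
        h.aggregate_frequency(120.0, FIXTURE_BANDS)


@pytest.mark.parametrize(
    "value, expected",
    [
        (87.0, 1),   # worked-example start-up temperature
        (82.0, 1),   # closed interval: exact boundary is acceptable
        (100.0, 1),
        (104.0, 2),  # within the grace margin
        (74.5, 2),
        (120.0, 3),  # beyond the margin
        (50.0, 3),
    ],
)
def test_score_measurement_against_range(value, expected):
    assert h.score_measurement((value, "°C"), TEMP_RULE) == expected


def test_score_measurement_without_margin_scores_three_outside():
    rule = MeasurementRule(minimum=82.0, maximum=100.0, unit="°C", margin=None)
    assert h.score_measurement((101.0, "°C"), rule) == 3


def test_score_measurement_unit_mismatch():
    with pytest.raises(DomainError, match="unit"):
        h.score_measurement((87.0, "F"), TEMP_RULE)
    with pytest.raises(ConfigurationError):
        h.score_measurement((87.0, "°C"), None)


def test_build_cells_reproduces_worked_example(table2):
    protocol, audit = table2
    cells = h.build_cells(audit, protocol)
    assert [(c.weighted_result, c.theoretical_max) for c in cells] == [
        (12, 18), (0, 18), (0, 0), (18, 18), (0, 36), (0, 0), (72, 72)
    ]


def test_build_cells_covers_every_crosstab_pair(sheep):
    empty = h.Audit(
        protocol_name=sheep.name, abattoir="X", line="1",
        date=datetime.date(2020, 1, 1), assessor="A", observations=[],
    )
    cells = h.build_cells(empty, sheep)
    assert len(cells) == sheep.n_pairs()
    assert all((c.weighted_result, c.theoretical_max) == (0, 0) for c in cells)


def test_build_cells_all_acceptable_gives_zero_weighted_sum(sheep):
    audit = h.random_audit(sheep, h.AuditScenario(seed=0, quality="excellent", coverage=1.0))
    for obs in audit.observations:  # force every observation to "acceptable"
        cp = sheep.catalog[obs.control_id]
        obs.raw_scores = [1] if cp.kind in ("behavioural", "structural") else None
        obs.frequency_percent = 0.0 if cp.kind == "frequency" else None
        obs.measurement = (90.0, "°C") if cp.kind == "measurement" else None
    cells = h.build_cells(audit, sheep)
    assert sum(c.weighted_result for c in cells) == 0
    expected_m = sum(
        3 * e * hw
        for ch, cid in sheep.pairs()
        for hw, e in [sheep.weights_for(ch, cid)]
    )
    assert sum(c.theoretical_max for c in cells) == expected_m


def test_build_cells_rejects_unknown_pair_and_duplicates(table2):
    protocol, audit = table2
    audit.observations.append(h.Observation(9, "hand_wash_facility", raw_scores=[1]))
    with pytest.raises(ValidationError, match="chapter 9"):
        h.build_cells(audit, protocol)
    audit.observations.pop()
    audit.observations.append(h.Observation(1, "sink_placement", raw_scores=[1]))
    with pytest.raises(ValidationError, match="duplicate"):
        h.build_cells(audit, protocol)
    audit.observations.pop()


def test_finalize_score_rejects_mismatched_evidence(table2):
    protocol, _ = table2
    obs = h.Observation(1, "skin_contam", raw_scores=[2])
    with pytest.raises(ValidationError, match="frequency"):
        h.finalize_score(obs, protocol.catalog["skin_contam"])
    obs2 = h.Observation(1, "hand_wash_facility", raw_scores=[2], frequency_percent=1.0)
    with pytest.raises(ValidationError, match="several evidence"):
        h.finalize_score(obs2, protocol.catalog["hand_wash_facility"])


def test_audit_json_round_trip_tolerates_comma_decimals(tmp_path, table2):
    _, audit = table2
    path = tmp_path / "audit.json"
    h.write_audit(audit, path)
    assert h.load_audit(path) == audit
    text = h.write_audit(audit).replace("87.0", '"87,0"')
    parsed = h.parse_audit(text)
    assert parsed == audit  # comma-decimal measurement reads back as 87.0


def test_parse_audit_rejects_malformed_document():
    with pytest.raises(ValidationError):
        h.parse_audit('{"observations": []}')
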