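"""Bundled protocol templates and deterministic synthetic audits.

Three things live here:

* :func:`sheep_template` — a representative sheep-slaughter-line protocol with
  the twelve standard chapters (Administration … Final inspection of
  carcasses) and ~30 cross-tabulated control points.  A production protocol
  carries far more control points (the scheme's full sheep catalog exceeds a
  hundred); this template is deliberately compact and the loader accepts
  protocols of any size.
* :func:`table2_audit` — the worked single-chapter "Skinning" example: seven
  control points with their recorded observations, weights and comments.
* :func:`random_audit` — a seed-reproducible audit generator over any
  protocol, parameterised by an :class:`AuditScenario` (quality level and
  observation coverage), so scoring, reporting and the CLI are testable with
  no external data.

Frequency→score thresholds and measurement margins are not part of the
published scheme; all bands and ranges here are synthetic, chosen to be
plausible and (for the worked example) consistent with the recorded scores.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np

from .errors import DomainError
from .protocol import Chapter, ControlPoint, MeasurementRule, Protocol
from .session import Audit, Observation, aggregate_frequency, score_measurement

SHEEP_CHAPTER_NAMES = (
    "Administration, leadership and premises",
    "Bleeding",
    "Rodding",
    "Pre-skinning",
    "Skinning",
    "Abdominal organ removal (evisceration)",
    "Breast organ removal (evisceration)",
    "Post mortem control",
    "Trimming, after-control",
    "Weighing, grading",
    "Handling of edible offal",
    "Final inspection of carcasses",
)

#: Synthetic score-sampling distributions per quality level: P(score = 1, 2, 3).
#: "excellent" draws no score-3 at all: a single "not acceptable" on a
#: high-weight point can sink a small chapter below the grade-B floor, which
#: is not what an excellent line looks like.
QUALITY_SCORE_PROBS: dict[str, tuple[float, float, float]] = {
    "excellent": (0.97, 0.03, 0.0),
    "mixed": (0.55, 0.35, 0.10),
    "poor": (0.10, 0.30, 0.60),
}

_TEMP_RANGE = MeasurementRule(minimum=82.0, maximum=100.0, unit="°C", margin=8.0)
# synthetic bands: tight for direct-contamination indicators, looser otherwise
_TIGHT_BANDS = ((0.5, 1), (2.0, 2), (100.0, 3))
_LOOSE_BANDS = ((1.0, 1), (5.0, 2), (100.0, 3))
_WIDE_BANDS = ((2.0, 1), (10.0, 2), (100.0, 3))


def _cp(cid, question, kind, h, e, bands=None, arange=None) -> ControlPoint:
    return ControlPoint(
        id=cid, question=question, kind=kind,
        hygienic_weight=h, economic_weight=e,
        frequency_bands=bands, acceptable_range=arange,
    )


def sheep_template() -> Protocol:
    """The bundled sheep-line protocol: 12 chapters, representative catalog."""
    catalog = {cp.id: cp for cp in [
        # management / premises (chapter 1)
        _cp("pre_slaughter_cleaning", "Is the slaughter line visibly clean before start-up?", "structural", 6, 2),
        _cp("leader_presence", "Are leaders regularly present in the slaughter hall?", "behavioural", 3, 2),
        _cp("communication", "Is hygiene-relevant communication between operators effective?", "behavioural", 3, 2),
        _cp("training", "Have operators documented hygiene training for their position?", "structural", 3, 1),
        _cp("maintenance_plan", "Is there an active maintenance plan for line equipment?", "structural", 1, 1),
        _cp("floor_walls", "Are floor, wall and ceiling materials intact and cleanable?", "structural", 3, 1),
        _cp("line_construction", "Is the slaughter line hygienically constructed (no carcass contact with fixtures)?", "structural", 6, 1),
        _cp("lighting", "Is lighting at working positions sufficient for hygiene control?", "structural", 1, 1),
        # shared structural GHP points
        _cp("hand_wash_facility", "All working positions are facilitated with hand wash", "structural", 6, 1),
        _cp("knife_disinfect_avail", "Are knife disinfecting tools available in all working positions?", "structural", 6, 1),
        _cp("equip_disinfect_avail", "Are all working positions, where necessary, facilitated with equipment disinfecting tools?", "structural", 6, 1),
        _cp("sink_placement", "Are sinks situated expediently in accordance with the work flow?", "structural", 6, 1),
        # start-up measurements
        _cp("knife_temp_startup", "Water temperature in knife disinfecting tool at start up slaughtering", "measurement", 6, 2, arange=_TEMP_RANGE),
        _cp("equip_temp_startup", "Temperature in equipment disinfecting tool at start up slaughtering", "measurement", 6, 2, arange=_TEMP_RANGE),
        # operator behaviour
        _cp("two_knives", "Is the two-knives method with knife disinfection used correctly?", "behavioural", 12, 2),
        _cp("knife_disinfect_freq", "Are knives disinfected with sufficient frequency?", "behavioural", 6, 2),
        _cp("handwash_quality", "Is hand washing appropriate, thorough and with soap?", "behavioural", 6, 2),
        _cp("clean_dirty_sep", "Is contact between clean carcass and dirty hands/knives avoided?", "behavioural", 12, 2),
        _cp("touch_fleece_carcass", "Do operators avoid touching the carcass after touching the fleece?", "behavioural", 12, 2),
        _cp("apron_clean", "Are aprons and protective clothing visibly clean and changed as needed?", "behavioural", 3, 2),
        _cp("tools_dropped", "Are dropped tools disinfected before reuse?", "behavioural", 3, 2),
        _cp("carcass_contact_structure", "Is carcass contact with platforms and structures avoided?", "behavioural", 6, 1),
        _cp("platform_clean", "Are working platforms kept clean during operation?", "structural", 3, 2),
        # frequency indicators
        _cp("skin_contam", "Visible contaminations from skin onto carcass", "frequency", 12, 2, bands=_TIGHT_BANDS),
        _cp("gut_puncture", "Percentage of rectums and intestines accidentally punctured", "frequency", 12, 2, bands=_LOOSE_BANDS),
        _cp("fleece_remnants", "Percentage of carcasses with remnants of fleece after deskinning", "frequency", 6, 2, bands=_WIDE_BANDS),
        _cp("fecal_carcass", "Visible fecal contamination on carcasses", "frequency", 12, 2, bands=_TIGHT_BANDS),
        _cp("offal_contam", "Visible contamination of edible offal", "frequency", 6, 2, bands=_LOOSE_BANDS),
    ]}
    chapter_controls = {
        1: ["pre_slaughter_cleaning", "leader_presence", "communication", "training",
            "maintenance_plan", "floor_walls", "line_construction", "lighting"],
        2: ["hand_wash_facility", "knife_disinfect_avail", "two_knives",
            "knife_disinfect_freq", "knife_temp_startup", "clean_dirty_sep"],
        3: ["hand_wash_facility", "knife_disinfect_avail", "two_knives",
            "handwash_quality", "clean_dirty_sep"],
        4: ["hand_wash_facility", "knife_disinfect_avail", "sink_placement",
            "two_knives", "touch_fleece_carcass", "knife_disinfect_freq"],
        5: ["hand_wash_facility", "knife_disinfect_avail", "equip_disinfect_avail",
            "sink_placement", "knife_temp_startup", "equip_temp_startup",
            "skin_contam", "touch_fleece_carcass", "handwash_quality"],
        6: ["hand_wash_facility", "knife_disinfect_avail", "two_knives",
            "gut_puncture", "clean_dirty_sep", "knife_disinfect_freq"],
        7: ["hand_wash_facility", "knife_disinfect_avail", "two_knives",
            "knife_disinfect_freq", "offal_contam"],
        8: ["hand_wash_facility", "knife_disinfect_avail", "knife_disinfect_freq",
            "handwash_quality", "carcass_contact_structure"],
        9: ["hand_wash_facility", "knife_disinfect_avail", "two_knives",
            "fleece_remnants", "fecal_carcass", "tools_dropped"],
        10: ["hand_wash_facility", "handwash_quality", "carcass_contact_structure",
             "platform_clean"],
        11: ["hand_wash_facility", "equip_disinfect_avail", "equip_temp_startup",
             "offal_contam", "apron_clean"],
        12: ["fecal_carcass", "fleece_remnants", "skin_contam",
             "carcass_contact_structure"],
    }
    chapters = [
        Chapter(index=i, name=SHEEP_CHAPTER_NAMES[i - 1], control_ids=chapter_controls[i])
        for i in range(1, 13)
    ]
    return Protocol(name="HPR sheep line", species="sheep", chapters=chapters, catalog=catalog)


def table2_audit() -> tuple[Protocol, Audit]:
    """The worked "Skinning" example: a one-chapter protocol fragment plus the
    audit reproducing its seven recorded observations.

    Two rows (equipment disinfecting tools; equipment-tool temperature) carry
    no observation and therefore score 0 with weighted result and theoretical
    maximum both 0.  The skin-contamination frequency bands are synthetic but
    chosen so the recorded 3 % maps to score 3, matching the example.
    """
    catalog = {cp.id: cp for cp in [
        _cp("hand_wash_facility", "All working positions are facilitated with hand wash", "structural", 6, 1),
        _cp("knife_disinfect_avail", "Are knife disinfecting tools available in all working positions?", "structural", 6, 1),
        _cp("equip_disinfect_avail", "Are all working positions, where necessary, facilitated with equipment disinfecting tools?", "structural", 6, 1),
        _cp("sink_placement", "Are sinks situated expediently in accordance with the work flow?", "structural", 6, 1),
        _cp("knife_temp_startup", "Water temperature in knife disinfecting tool at start up slaughtering", "measurement", 6, 2, arange=_TEMP_RANGE),
        _cp("equip_temp_startup", "Temperature in equipment disinfecting tool at start up slaughtering", "measurement", 6, 2, arange=_TEMP_RANGE),
        _cp("skin_contam", "Visible contaminations from skin onto carcass", "frequency", 12, 2, bands=_TIGHT_BANDS),
    ]}
    protocol = Protocol(
        name="HPR sheep line — skinning fragment",
        species="sheep",
        chapters=[Chapter(index=1, name="Skinning", control_ids=list(catalog))],
        catalog=catalog,
    )
    audit = Audit(
        protocol_name=protocol.name,
        abattoir="Example abattoir",
        line="Sheep line 1",
        date=_dt.date(2019, 1, 1),
        assessor="External assessor",
        observations=[
            Observation(1, "hand_wash_facility", raw_scores=[2], comment=(
                "No easy access to hand wash for the operator of the first machine. "
                "Operator must use hand wash belonging to neighbouring position")),
            Observation(1, "knife_disinfect_avail", raw_scores=[1], comment=(
                "Knife is used to a little extent. Last operator on the position uses "
                "knife and access to knife disinfecting tool is ok")),
            Observation(1, "sink_placement", raw_scores=[3], comment=(
                "Hand wash at skinning machine is situated too far from operator")),
            Observation(1, "knife_temp_startup", measurement=(87.0, "°C"), comment="87,0 °C"),
            Observation(1, "skin_contam", frequency_percent=3.0, comment="Frequency 3%"),
        ],
    )
    return protocol, audit


# ---------------------------------------------------------------------------
# synthetic audits


@dataclass(frozen=True)
class AuditScenario:
    """Deterministic generation recipe: same seed + scenario → identical audit."""

    seed: int
    quality: str = "mixed"
    coverage: float = 1.0

    def __post_init__(self) -> None:
        if self.quality not in QUALITY_SCORE_PROBS:
            raise DomainError(
                f"quality {self.quality!r} not in {sorted(QUALITY_SCORE_PROBS)}"
            )
        if not 0.0 < self.coverage <= 1.0:
            raise DomainError(f"coverage {self.coverage} outside (0, 1]")


def _frequency_for_score(rng, bands, target: int) -> tuple[float, int]:
    """Pick a frequency inside the band of ``target`` (or the closest band)."""
    scores = [s for _, s in bands]
    if target not in scores:
        target = min(scores, key=lambda s: abs(s - target))
    i = scores.index(target)
    lo = 0.0 if i == 0 else bands[i - 1][0]
    hi = bands[i][0]
    freq = round(lo + (hi - lo) * max(float(rng.random()), 1e-9), 3)
    if aggregate_frequency(freq, bands) != target:  # guard rounding at the bound
        freq = hi
    return freq, target


def _measurement_for_score(rng, rule, target: int) -> tuple[float, int]:
    span = max(rule.maximum - rule.minimum, 1.0)
    if target == 2 and rule.margin is None:
        target = 3
    if target == 1:
        value = rule.minimum + (rule.maximum - rule.minimum) * float(rng.random())
    elif target == 2:
        value = rule.maximum + rule.margin * float(rng.uniform(0.05, 0.95))
    else:
        excess = (rule.margin or 0.0) + span * float(rng.uniform(0.1, 1.0))
        value = rule.maximum + excess
    value = round(value, 2)
    got = score_measurement((value, rule.unit), rule)
    if got != target:  # rounding pushed the value over a boundary
        value = {1: rule.minimum, 2: rule.maximum + (rule.margin or 0.0), 3: value + span}[target]
        got = score_measurement((value, rule.unit), rule)
    return value, got


def random_audit(protocol: Protocol, scenario: AuditScenario) -> Audit:
    """Generate a synthetic audit of ``protocol`` under ``scenario``.

    Each crosstabulation pair is observed with probability ``coverage``; the
    intended score is drawn from the quality level's distribution and evidence
    of the right kind is synthesised to reduce back to exactly that score.
    """
    rng = np.random.default_rng(scenario.seed)
    probs = QUALITY_SCORE_PROBS[scenario.quality]
    observations: list[Observation] = []
    for chapter, control_id in protocol.pairs():
        if float(rng.random()) > scenario.coverage:
            continue
        cp = protocol.catalog[control_id]
        target = int(rng.choice((1, 2, 3), p=probs))
        comment = ""
        if cp.kind in ("behavioural", "structural"):
            n_spots = int(rng.integers(1, 4))
            raw = [int(rng.integers(1, target + 1)) for _ in range(n_spots - 1)] + [target]
            raw = [raw[i] for i in rng.permutation(len(raw))]
            obs = Observation(chapter.index, control_id, raw_scores=raw)
            final = max(raw)
        elif cp.kind == "frequency":
            freq, final = _frequency_for_score(rng, cp.frequency_bands, target)
            obs = Observation(chapter.index, control_id, frequency_percent=freq)
        else:
            value, final = _measurement_for_score(rng, cp.acceptable_range, target)
            obs = Observation(
                chapter.index, control_id, measurement=(value, cp.acceptable_range.unit)
            )
        if final >= 2:
            comment = f"Deviation observed (severity {final})"
        obs.comment = comment
        observations.append(obs)
    date = _dt.date(2020, 1, 1) + _dt.timedelta(days=int(scenario.seed) % 364)
    return Audit(
        protocol_name=protocol.name,
        abattoir=f"Synthetic abattoir {scenario.seed}",
        line="Line 1",
        date=date,
        assessor="Synthetic assessor",
        observations=observations,
    )
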