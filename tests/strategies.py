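"""Shared hypothesis strategies: scored-cell batches and random protocols."""

import hypothesis.strategies as st

from hpraudit import Chapter, ControlPoint, MeasurementRule, Protocol, score_cell

observation_scores = st.sampled_from([0, 1, 2, 3])
economic_weights = st.sampled_from([1, 2])
hygienic_weights = st.sampled_from([1, 3, 6, 12])

#: (chapter_index, score, econ, hyg) tuples describing one cell each
cell_spec = st.tuples(
    st.integers(1, 4), observation_scores, economic_weights, hygienic_weights
)
cell_batches = st.lists(cell_spec, min_size=1, max_size=30)


def build_cells_from_specs(specs):
    return [
        score_cell(ch, f"cp{i}", s, e, h) for i, (ch, s, e, h) in enumerate(specs)
    ]


_ids = st.from_regex(r"[a-z][a-z0-9_]{0,9}", fullmatch=True)
_text = st.text(
    alphabet=st.characters(blacklist_categories=("Cs",), blacklist_characters="\n\r"),
    min_size=1,
    max_size=30,
)
_quarters = st.integers(1, 400).map(lambda k: k / 4)  # exact binary decimals


@st.composite
def _control_point(draw, cid):
    kind = draw(st.sampled_from(["behavioural", "structural", "frequency", "measurement"]))
    bands = None
    arange = None
    if kind == "frequency":
        n = draw(st.integers(1, 3))
        bounds = sorted(draw(st.sets(_quarters, min_size=n, max_size=n)))
        scores = sorted(draw(st.lists(st.sampled_from([1, 2, 3]), min_size=n, max_size=n)))
        bands = tuple(zip(bounds, scores))
    if kind == "measurement":
        lo = draw(_quarters)
        hi = lo + draw(_quarters)
        margin = draw(st.one_of(st.none(), _quarters))
        arange = MeasurementRule(
            minimum=lo, maximum=hi, unit=draw(st.sampled_from(["°C", "C", "mm", "bar"])),
            margin=margin,
        )
    return ControlPoint(
        id=cid,
        question=draw(_text),
        kind=kind,
        hygienic_weight=draw(hygienic_weights),
        economic_weight=draw(economic_weights),
        frequency_bands=bands,
        acceptable_range=arange,
    )


@st.composite
def protocols(draw):
    """Small valid protocols: every catalog entry referenced, contiguous chapters."""
    ids = sorted(draw(st.sets(_ids, min_size=1, max_size=8)))
    catalog = {cid: draw(_control_point(cid)) for cid in ids}
    n_chapters = draw(st.integers(1, 4))
    groups: list[list[str]] = [[] for _ in range(n_chapters)]
    for cid in ids:
        groups[draw(st.integers(0, n_chapters - 1))].append(cid)
        for g in range(n_chapters):  # occasional extra membership → crosstabulation
            if cid not in groups[g] and draw(st.booleans()) and draw(st.booleans()):
                groups[g].append(cid)
    groups = [g for g in groups if g]
    chapters = []
    for i, group in enumerate(groups, start=1):
        overrides = {}
        for cid in group:
            if draw(st.booleans()) and draw(st.booleans()):
                overrides[cid] = (draw(hygienic_weights), draw(economic_weights))
        chapters.append(
            Chapter(index=i, name=draw(_text), control_ids=group, weight_overrides=overrides)
        )
    return Protocol(
        name=draw(_text), species=draw(_text), chapters=chapters, catalog=catalog
    )
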