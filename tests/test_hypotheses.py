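"""Rule-based hypothesis evaluation: verdict logic on controlled inputs."""

import pytest

import sesfit as sf
from sesfit.hypotheses import (
    INDETERMINATE,
    NOT_SUPPORTED,
    PARTIAL,
    SUPPORTED,
    evaluate_hypotheses,
)
from sesfit.nullmodel import BlockNull, NullDistribution, RandomizationScheme
from sesfit.positions import PositionOccupancy


def _nulldist(codes: dict[str, str]) -> NullDistribution:
    blocks = {}
    for bid in "abcdefghij":
        code = codes.get(bid, "0")
        pu = 0.001 if code == "++" else 0.03 if code == "+" else 1.0
        pl = 0.001 if code == "--" else 0.03 if code == "-" else 1.0
        blocks[bid] = BlockNull(bid, 1, 1.0, 1.0, pu, pl, code)
    return NullDistribution(blocks=blocks, scheme=RandomizationScheme(), R=100, seed=0)


def _occupancy(
    counts: dict[tuple[str, str], dict[str, int]],
    categories: dict[str, sf.ActorCategory],
    block_counts: dict[str, int],
) -> PositionOccupancy:
    row_norm = {
        k: ({a: v / sum(t.values()) for a, v in t.items()} if t else {})
        for k, t in counts.items()
    }
    by_cat = {
        (b, p, c): sum(s for a, s in shares.items() if categories.get(a) == c)
        for (b, p), shares in row_norm.items()
        for c in sf.ActorCategory
    }
    full_counts = {k: counts.get(k, {}) for k in set(counts) | {("c", "c-1"), ("h", "h-1"), ("g", "g-2"), ("e", "e-1")}}
    row_norm.update({k: row_norm.get(k, {}) for k in full_counts})
    by_cat.update(
        {
            (b, p, c): by_cat.get((b, p, c), 0.0)
            for (b, p) in full_counts
            for c in sf.ActorCategory
        }
    )
    return PositionOccupancy(
        counts=full_counts,
        row_norm=row_norm,
        by_category=by_cat,
        block_counts={bid: block_counts.get(bid, 0) for bid in "abcdefghij"},
        actor_categories=categories,
        multiplicity={k: 1 for k in full_counts},
    )


MOU = sf.ActorCategory.MOU
SG = sf.ActorCategory.SECOND_GEN
CATS = {"G": MOU, "I": MOU, "L": MOU, **{x: SG for x in "JKMNOPQRST"}}


def test_h1_supported_on_paper_signature(catalog):
    nd = _nulldist({"c": "++", "b": "--", "d": "--"})
    occ = _occupancy({}, CATS, {})
    rep = evaluate_hypotheses(nd, occ, catalog)
    assert rep.verdicts["H1"] == SUPPORTED
    assert len(rep.evidence["H1"]) >= 3


def test_h1_partial_on_conflicting_codes(catalog):
    nd = _nulldist({"c": "++", "h": "--"})  # good-fit block under-represented
    rep = evaluate_hypotheses(nd, _occupancy({}, CATS, {}), catalog)
    assert rep.verdicts["H1"] == PARTIAL


def test_all_codes_zero_nothing_supported(catalog):
    nd = _nulldist({})
    occ = _occupancy({}, CATS, {})
    rep = evaluate_hypotheses(nd, occ, catalog)
    assert rep.verdicts["H1"] == NOT_SUPPORTED
    assert rep.verdicts["H2"] == INDETERMINATE
    assert rep.verdicts["H3"] == INDETERMINATE
    assert all(rep.evidence[h] for h in rep.verdicts)


def test_h2_supported_when_mou_drive_chains(catalog):
    occ = _occupancy(
        {("c", "c-1"): {"G": 3, "J": 1}, ("h", "h-1"): {"I": 1, "J": 1}},
        CATS,
        {"c": 4, "h": 1},
    )
    rep = evaluate_hypotheses(_nulldist({}), occ, catalog)
    assert rep.verdicts["H2"] == SUPPORTED


def test_h2_partial_when_mou_only_in_collaborations(catalog):
    occ = _occupancy(
        {("c", "c-1"): {"J": 4}, ("h", "h-1"): {"G": 2, "J": 1, "K": 1}},
        CATS,
        {"c": 4, "h": 2},
    )
    rep = evaluate_hypotheses(_nulldist({}), occ, catalog)
    assert rep.verdicts["H2"] == PARTIAL


def test_h3_requires_both_support_and_hub_majority(catalog):
    base = {("g", "g-2"): {"G": 3, "J": 2}, ("e", "e-1"): {"G": 7, "I": 2, "J": 1}}
    occ = _occupancy(base, CATS, {"g": 5, "e": 10})
    rep = evaluate_hypotheses(_nulldist({}), occ, catalog)
    assert rep.verdicts["H3"] == SUPPORTED
    # hub majority lost -> only partial
    occ2 = _occupancy(
        {("g", "g-2"): {"G": 3, "J": 2}, ("e", "e-1"): {"J": 8, "G": 2}},
        CATS,
        {"g": 5, "e": 10},
    )
    rep2 = evaluate_hypotheses(_nulldist({}), occ2, catalog)
    assert rep2.verdicts["H3"] == PARTIAL


def test_verdicts_deterministic_and_pure(catalog):
    nd = _nulldist({"c": "++", "b": "--"})
    occ = _occupancy({("g", "g-2"): {"G": 3}}, CATS, {"g": 3})
    r1 = evaluate_hypotheses(nd, occ, catalog)
    r2 = evaluate_hypotheses(nd, occ, catalog)
    assert r1.verdicts == r2.verdicts
    assert r1.evidence == r2.evidence


def test_report_serialization(catalog):
    nd = _nulldist({"c": "++"})
    rep = evaluate_hypotheses(nd, _occupancy({}, CATS, {}), catalog)
    md = rep.to_markdown()
    assert "operationalization" in md and "H1" in md
    js = rep.to_json()
    assert "verdicts" in js


def test_thresholds_configurable(catalog):
    occ = _occupancy(
        {("g", "g-2"): {"G": 3, "J": 7}, ("e", "e-1"): {"G": 9, "J": 1}},
        CATS,
        {"g": 10, "e": 10},
    )
    strict = sf.RuleConfig(baseline_share=0.5)
    rep = evaluate_hypotheses(_nulldist({}), occ, catalog, rules=strict)
    # g-2 share 0.3 < 0.5 baseline, hub 0.9 > 0.5 -> partial
    assert rep.verdicts["H3"] == PARTIAL
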