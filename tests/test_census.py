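"""Census engine vs. hand-computed micro-examples and the brute-force oracle."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import sesfit as sf
from sesfit.synthetic import random_network


def _net(actors, ecos, social=(), eco=(), mem=()):
    return sf.SESNetwork.from_parts(
        actors=[sf.ActorNode(a) for a in actors],
        ecos=[sf.EcoNode(e) for e in ecos],
        social_edges=social,
        eco_edges=eco,
        membership_edges=mem,
    )


def test_single_lake_chain_group():
    net = _net("A", ["L1", "L2"], eco=[("L1", "L2")], mem=[("A", "L1"), ("A", "L2")])
    occs = sf.enumerate_block(net, sf.default_catalog()["c"])
    assert [o.assignment_dict for o in occs] == [{"A1": "A", "E1": "L1", "E2": "L2"}]


def test_micro_network_worked_example(catalog):
    # A-B social, A-L1 and B-L2 memberships, L1-L2 eco: exactly one lake
    # chain collaboration, and a supported-lake-group in each orientation
    net = _net("AB", ["L1", "L2"], [("A", "B")], [("L1", "L2")], [("A", "L1"), ("B", "L2")])
    counts = sf.census(net, catalog).counts
    assert counts == {"a": 0, "b": 0, "c": 0, "d": 0, "e": 0, "f": 2, "g": 0, "h": 1, "i": 0, "j": 0}
    assert counts == sf.brute_force_census(net, catalog).counts


@pytest.mark.parametrize("k", [2, 3, 5, 6])
def test_star_open_triads(catalog, k):
    spokes = [f"S{i}" for i in range(k)]
    net = _net(["H", *spokes], [], [("H", s) for s in spokes])
    occs = sf.enumerate_block(net, catalog["e"])
    assert len(occs) == k * (k - 1) // 2
    assert all(o.assignment_dict["A1"] == "H" for o in occs)


def test_triangle_has_no_open_triads(catalog):
    net = _net("XYZ", [], [("X", "Y"), ("Y", "Z"), ("X", "Z")])
    assert sf.census(net, catalog).counts["e"] == 0


def test_empty_network_all_zero(catalog):
    counts = sf.census(sf.SESNetwork(), catalog).counts
    assert set(counts) == set("abcdefghij") and not any(counts.values())


def test_enumeration_deterministic_and_canonical(catalog):
    net = random_network(6, 6, seed=42)
    for block in catalog:
        occs1 = sf.enumerate_block(net, block)
        occs2 = sf.enumerate_block(net, block)
        assert occs1 == occs2
        # canonical representative: lexicographically least in its orbit
        assert len({tuple(sorted(o.assignment)) for o in occs1}) == len(occs1)


@pytest.mark.parametrize("seed", range(12))
def test_oracle_equivalence_random_networks(catalog, seed):
    dens = [(0.15, 0.15, 0.15), (0.4, 0.3, 0.3), (0.7, 0.6, 0.5)][seed % 3]
    net = random_network(7, 7, *dens, seed=seed)
    fast = sf.census(net, catalog, keep_occurrences=True)
    slow = sf.brute_force_census(net, catalog)
    assert fast.counts == slow.counts
    assert fast.occurrences == slow.occurrences


def test_per_assignment_counting_on_lake_paths(catalog):
    # a group on a path of three lakes contributes one chain assignment per
    # adjacent pair, and one unconnected-pair assignment for the path ends
    net = _net("A", ["L1", "L2", "L3"], eco=[("L1", "L2"), ("L2", "L3")],
               mem=[("A", "L1"), ("A", "L2"), ("A", "L3")])
    assert sf.census(net, catalog).counts["c"] == 2
    assert sf.census(net, catalog).counts["d"] == 1  # the non-adjacent L1,L3 pair


def test_node_set_counting_switch():
    """node_sets mode collapses assignments sharing one node set."""
    from sesfit.motifs import BlockCatalog, BuildingBlock, validate_block

    # one-sided chain membership: a group on both lakes of a connected pair
    # realizes it twice per-assignment (either lake in the anchored slot),
    # once per node set
    blk = BuildingBlock(
        block_id="x",
        name="anchored chain end",
        slots=(("A1", "actor"), ("E1", "eco"), ("E2", "eco")),
        required=frozenset({("A1", "E1", "membership"), ("E1", "E2", "eco")}),
        forbidden=frozenset(),
        positions=(("x-1", ("A1",)),),
        symmetries=(("A1", "E1", "E2"),),
    )
    validate_block(blk)
    cat = BlockCatalog(blocks={"x": blk})
    net = _net("A", ["L1", "L2"], eco=[("L1", "L2")], mem=[("A", "L1"), ("A", "L2")])
    assert sf.census(net, cat).counts["x"] == 2
    assert sf.census(net, cat, counting="node_sets").counts["x"] == 1


def test_census_identities_direct_combinatorics(catalog):
    net = random_network(6, 6, 0.4, 0.4, 0.35, seed=7)
    counts = sf.census(net, catalog).counts
    lakes_of = {a: {l for x, l in net.membership_edges if x == a} for a in net.actors}
    members = {l: {a for a, x in net.membership_edges if x == l} for l in net.ecos}
    shared = sum(len(m) * (len(m) - 1) // 2 for m in members.values())
    assert counts["a"] + counts["b"] == shared
    pairs = sum(len(m) * (len(m) - 1) // 2 for m in lakes_of.values())
    assert counts["c"] + counts["d"] == pairs


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_social_edge_monotonicity(catalog, seed):
    """Adding a social tie never decreases h (tie required) and never
    increases b or i (tie forbidden)."""
    net = random_network(6, 6, 0.3, 0.3, 0.3, seed=seed)
    actors = sorted(net.actors)
    absent = [
        (u, v)
        for i, u in enumerate(actors)
        for v in actors[i + 1 :]
        if (u, v) not in net.social_edges
    ]
    if not absent:
        return
    before = sf.census(net, catalog).counts
    net.social_edges.add(absent[seed % len(absent)])
    after = sf.census(net, catalog).counts
    assert after["h"] >= before["h"]
    assert after["b"] <= before["b"]
    assert after["i"] <= before["i"]
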