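"""Synthetic landscape/group generator: structure, determinism, preferences."""

import numpy as np
import pytest

import sesfit as sf
from sesfit.synthetic import actor_labels


def _components(net):
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(net.ecos)
    g.add_edges_from(net.eco_edges)
    return nx.number_connected_components(g)


def test_landscape_paths_structure():
    cfg = sf.SyntheticConfig(n_lakes=29, n_watersheds=3, seed=1)
    land = sf.generate_landscape(cfg)
    assert len(land.ecos) == 29
    assert len(land.eco_edges) == 26  # forest: n - #components
    assert _components(land) == 3
    watersheds = {e.watershed for e in land.ecos.values()}
    assert watersheds == {"W1", "W2", "W3"}


def test_landscape_trees_structure():
    cfg = sf.SyntheticConfig(n_lakes=20, n_watersheds=4, chain_topology="trees", seed=2)
    land = sf.generate_landscape(cfg)
    assert len(land.eco_edges) == 16
    assert _components(land) == 4


def test_single_lake_landscape():
    land = sf.generate_landscape(sf.SyntheticConfig(n_lakes=1, n_watersheds=1))
    assert len(land.ecos) == 1 and len(land.eco_edges) == 0


def test_more_watersheds_than_lakes_rejected():
    with pytest.raises(ValueError, match="watersheds"):
        sf.generate_landscape(sf.SyntheticConfig(n_lakes=2, n_watersheds=3))


def test_generator_deterministic_per_seed():
    a = sf.generate_network(sf.SyntheticConfig(seed=5))
    b = sf.generate_network(sf.SyntheticConfig(seed=5))
    c = sf.generate_network(sf.SyntheticConfig(seed=6))
    assert a.equals(b)
    assert not a.equals(c)


@pytest.mark.parametrize("seed", range(5))
def test_generated_networks_valid_with_study_marginals(seed):
    net = sf.generate_network(sf.SyntheticConfig(seed=seed))
    assert sf.validate(net) == []
    s = sf.summarize(net)
    assert (s.n_actors, s.n_ecos) == (23, 29)
    assert s.actors_by_category[sf.ActorCategory.MOU] == 3
    assert s.actors_by_category[sf.ActorCategory.FIRST_GEN] == 7
    assert s.actors_by_category[sf.ActorCategory.SECOND_GEN] == 13


def test_full_chain_preference_forces_adjacent_pairs(catalog):
    # rho = 1, two lakes per group on a path landscape: no unconnected pairs
    for seed in range(5):
        net = sf.generate_network(sf.planted_chain_config(seed=seed))
        counts = sf.census(net, catalog, blocks=["c", "d"]).counts
        assert counts["d"] == 0
        assert counts["c"] == 23


def test_no_chains_without_eco_edges(catalog):
    cfg = sf.SyntheticConfig(
        n_lakes=12, n_watersheds=12, lakes_per_group=2, chain_pref=0.0, seed=3
    )
    net = sf.generate_network(cfg)
    assert sf.census(net, catalog, blocks=["c"]).counts["c"] == 0


def test_anti_chain_preference_avoids_adjacency(catalog):
    for seed in range(3):
        net = sf.generate_network(sf.anti_chain_config(seed=seed))
        assert sf.census(net, catalog, blocks=["c"]).counts["c"] == 0


def test_pure_mentor_preference_targets_mou():
    cfg = sf.SyntheticConfig(mentor_pref=1.0, seed=4)
    net = sf.generate_network(cfg)
    mou = {a for a, n in net.actors.items() if n.category == sf.ActorCategory.MOU}
    assert net.social_edges
    assert all(u in mou or v in mou for u, v in net.social_edges)


def test_chain_preference_monotone_in_rho(catalog):
    """E[count(c)] is nondecreasing in the chain preference."""
    means = []
    for rho in (0.0, 0.5, 1.0):
        cfg_counts = [
            sf.census(
                sf.generate_network(
                    sf.SyntheticConfig(chain_pref=rho, lakes_per_group=2, seed=s)
                ),
                catalog,
                blocks=["c"],
            ).counts["c"]
            for s in range(40)
        ]
        means.append(np.mean(cfg_counts))
    assert means[0] < means[1] < means[2]


def test_mentor_preference_monotone_in_mu(catalog):
    """E[MOU share of the hub position] is nondecreasing in mentor_pref."""
    def mou_hub_share(mu, seeds=30):
        shares = []
        for s in range(seeds):
            net = sf.generate_network(sf.SyntheticConfig(mentor_pref=mu, seed=s))
            cens = sf.census(net, catalog_, keep_occurrences=True, blocks=["e"])
            if cens.counts["e"] == 0:
                continue
            occ = sf.positional_occupancy(net, catalog_, cens)
            shares.append(sf.category_share(occ, "e", "e-1", "MOU"))
        return np.mean(shares)

    catalog_ = sf.default_catalog()
    assert mou_hub_share(0.0) < mou_hub_share(0.9)


def test_neutral_config_matches_null_scheme_marginals():
    cfg = sf.neutral_config(seed=0)
    assert cfg.chain_pref == 0.0 and cfg.mentor_pref == 0.0 and cfg.shared_lake_pref == 0.0
    assert cfg.n_actors == 23 and cfg.n_lakes == 29


def test_neutral_law_equals_null_law(catalog):
    """Census means over neutral draws match null-model means on one draw."""
    cfg = sf.neutral_config(seed=0)
    draws = []
    for s in range(500):
        net = sf.generate_network(sf.neutral_config(seed=s))
        draws.append(sf.census(net, catalog, blocks=["c", "e", "b"]).counts)
    gen_means = {b: np.mean([d[b] for d in draws]) for b in ("c", "e", "b")}
    nd = sf.null_distribution(
        sf.generate_network(cfg), catalog, R=1000, seed=12345, blocks=["c", "e", "b"]
    )
    for b in ("e", "b"):  # means well above 1: relative comparison
        null_mean = nd.blocks[b].null_mean
        assert abs(gen_means[b] - null_mean) / null_mean < 0.10
    # block c's null mean is well below one; compare absolutely
    assert abs(gen_means["c"] - nd.blocks["c"].null_mean) < 0.15


def test_infeasible_group_size_rejected():
    cfg = sf.SyntheticConfig(n_lakes=3, n_watersheds=1, lakes_per_group=5)
    with pytest.raises(ValueError, match="exceeds"):
        sf.generate_network(cfg)


def test_config_json_round_trip(tmp_path):
    cfg = sf.SyntheticConfig(chain_pref=0.25, lakes_per_group={1: 0.5, 2: 0.5}, seed=9)
    cfg.to_json(tmp_path / "cfg.json")
    again = sf.SyntheticConfig.from_json(tmp_path / "cfg.json")
    assert again == cfg


def test_actor_labels_spreadsheet_style():
    labels = actor_labels(30)
    assert labels[:3] == ["A", "B", "C"]
    assert labels[25] == "Z" and labels[26] == "AA" and labels[29] == "AD"
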