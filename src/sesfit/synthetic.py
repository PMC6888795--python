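"""Synthetic lake-landscape and lake-group network generator.

The generator emulates the structure the fit analysis assumes: a fixed
hydrological landscape of lakes arranged in chains within edge-disjoint
watersheds, plus actor groups in three categories (MOU, 1st-generation,
2nd-generation) that acquire lake memberships and social ties with
tunable preferences:

* ``chain_pref`` (rho): probability that a multi-lake group's additional
  lake is drawn from the eco-neighbours of its current lakes instead of
  uniformly from all remaining lakes. Negative values (an extension)
  *avoid* neighbours with probability abs(rho), producing anti-chain
  portfolios.
* ``shared_lake_pref``: probability that a group's first lake is drawn
  from lakes already tended by another group.
* ``mentor_pref`` (mu): probability that a social edge is a
  2nd-generation-to-MOU attachment instead of a uniform pair, giving MOU
  hubs.

Defaults mirror the study marginals (23 groups split 3/7/13, 29 lakes, 3
watersheds) with pronounced chain and mentor preferences. Setting all
three preferences to zero (:func:`neutral_config`) makes the generative
law *identical* to the default randomization scheme's null: the social
layer is then a uniform simple graph of fixed edge count (edges drawn
sequentially, uniformly over absent pairs) and each group's lake set is a
uniform subset of fixed size -- the type-I calibration baseline.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np

from .network import ActorCategory, ActorNode, EcoNode, SESNetwork


@dataclass(frozen=True)
class SyntheticConfig:
    n_lakes: int = 29
    n_watersheds: int = 3
    chain_topology: str = "paths"  # "paths" | "trees"
    n_mou: int = 3
    n_first_gen: int = 7
    n_second_gen: int = 13
    # int -> every group that size; mapping size -> probability otherwise
    lakes_per_group: int | Mapping[int, float] = field(
        default_factory=lambda: {1: 0.75, 2: 0.20, 3: 0.05}
    )
    chain_pref: float = 0.9
    shared_lake_pref: float = 0.1
    mean_ties_per_group: float = 2.4
    mentor_pref: float = 0.8
    cross_watershed_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.chain_pref <= 1.0:
            raise ValueError("chain_pref must be in [-1, 1]")
        for name in ("shared_lake_pref", "mentor_pref", "cross_watershed_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_lakes < 1 or self.n_watersheds < 1:
            raise ValueError("n_lakes and n_watersheds must be positive")
        if self.chain_topology not in ("paths", "trees"):
            raise ValueError("chain_topology must be 'paths' or 'trees'")
        if min(self.n_mou, self.n_first_gen, self.n_second_gen) < 0:
            raise ValueError("category counts must be non-negative")

    @property
    def n_actors(self) -> int:
        return self.n_mou + self.n_first_gen + self.n_second_gen

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        if isinstance(d["lakes_per_group"], dict):
            d["lakes_per_group"] = {str(k): v for k, v in d["lakes_per_group"].items()}
        Path(path).write_text(json.dumps(d, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticConfig":
        d = json.loads(Path(path).read_text())
        if isinstance(d.get("lakes_per_group"), dict):
            d["lakes_per_group"] = {int(k): float(v) for k, v in d["lakes_per_group"].items()}
        return cls(**d)


def actor_labels(n: int) -> list[str]:
    """Spreadsheet-style labels A, B, ..., Z, AA, AB, ..."""
    out = []
    for i in range(n):
        label = ""
        k = i
        while True:
            label = string.ascii_uppercase[k % 26] + label
            k = k // 26 - 1
            if k < 0:
                break
        out.append(label)
    return out


def _lake_labels(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"L{i + 1:0{width}d}" for i in range(n)]


def _partition_sizes(total: int, parts: int) -> list[int]:
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


def generate_landscape(cfg: SyntheticConfig, rng: np.random.Generator | None = None) -> SESNetwork:
    """Eco layer only: lakes partitioned into watershed chains or trees.

    Each watershed is a path (or a uniform random labelled tree), so a
    watershed with k lakes has k-1 eco edges and watersheds are
    edge-disjoint components unless ``cross_watershed_prob`` > 0.
    """
    if cfg.n_watersheds > cfg.n_lakes:
        raise ValueError("more watersheds than lakes")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    labels = _lake_labels(cfg.n_lakes)
    sizes = _partition_sizes(cfg.n_lakes, cfg.n_watersheds)
    ecos = []
    eco_edges: set[tuple[str, str]] = set()
    start = 0
    groups_of_lakes: list[list[str]] = []
    for w, size in enumerate(sizes, start=1):
        ws_lakes = labels[start : start + size]
        start += size
        groups_of_lakes.append(ws_lakes)
        ecos.extend(EcoNode(l, watershed=f"W{w}") for l in ws_lakes)
        if cfg.chain_topology == "paths":
            eco_edges.update(zip(ws_lakes, ws_lakes[1:]))
        else:
            if size > 1:
                import networkx as nx

                tree = nx.random_labeled_tree(size, seed=int(rng.integers(0, 2**31 - 1)))
                eco_edges.update((ws_lakes[u], ws_lakes[v]) for u, v in tree.edges)
    if cfg.cross_watershed_prob > 0:
        for i in range(len(groups_of_lakes)):
            for j in range(i + 1, len(groups_of_lakes)):
                if rng.random() < cfg.cross_watershed_prob:
                    u = groups_of_lakes[i][int(rng.integers(len(groups_of_lakes[i])))]
                    v = groups_of_lakes[j][int(rng.integers(len(groups_of_lakes[j])))]
                    eco_edges.add((u, v))
    return SESNetwork.from_parts(actors=[], ecos=ecos, eco_edges=eco_edges)


def _draw_group_size(cfg: SyntheticConfig, rng: np.random.Generator) -> int:
    if isinstance(cfg.lakes_per_group, int):
        return cfg.lakes_per_group
    sizes = sorted(cfg.lakes_per_group)
    probs = np.asarray([cfg.lakes_per_group[s] for s in sizes], dtype=float)
    probs = probs / probs.sum()
    return int(rng.choice(sizes, p=probs))


def _uniform_new_pair(
    existing: set[tuple[str, str]], actors: list[str], rng: np.random.Generator
) -> tuple[str, str]:
    n = len(actors)
    all_pairs = [
        (actors[i], actors[j]) for i in range(n) for j in range(i + 1, n)
    ]
    free = [p for p in all_pairs if p not in existing]
    if not free:
        raise ValueError("social layer saturated")
    return free[int(rng.integers(len(free)))]


def generate_groups(cfg: SyntheticConfig, landscape: SESNetwork) -> SESNetwork:
    """Populate a landscape with actor groups, memberships and social ties."""
    rng = np.random.default_rng(cfg.seed + 1)
    lakes = sorted(landscape.ecos)
    eco_adj: dict[str, set[str]] = {l: set() for l in lakes}
    for u, v in landscape.eco_edges:
        eco_adj[u].add(v)
        eco_adj[v].add(u)

    n = cfg.n_actors
    labels = actor_labels(n)
    cats = (
        [ActorCategory.MOU] * cfg.n_mou
        + [ActorCategory.FIRST_GEN] * cfg.n_first_gen
        + [ActorCategory.SECOND_GEN] * cfg.n_second_gen
    )
    actors = [ActorNode(lab, cat) for lab, cat in zip(labels, cats)]

    membership: set[tuple[str, str]] = set()
    occupied: set[str] = set()
    for actor in actors:
        k = _draw_group_size(cfg, rng)
        if k > len(lakes):
            raise ValueError(
                f"group size {k} exceeds the number of lakes ({len(lakes)})"
            )
        mine: set[str] = set()
        # first lake
        pool = sorted(occupied) if (occupied and rng.random() < cfg.shared_lake_pref) else lakes
        first = pool[int(rng.integers(len(pool)))]
        mine.add(first)
        while len(mine) < k:
            remaining = [l for l in lakes if l not in mine]
            rho = cfg.chain_pref
            chosen = None
            if rho != 0.0 and rng.random() < abs(rho):
                nbrs = set().union(*(eco_adj[l] for l in mine)) - mine
                pool2 = sorted(nbrs) if rho > 0 else sorted(set(remaining) - nbrs)
                if pool2:
                    chosen = pool2[int(rng.integers(len(pool2)))]
            if chosen is None:
                chosen = remaining[int(rng.integers(len(remaining)))]
            mine.add(chosen)
        membership.update((actor.id, l) for l in sorted(mine))
        occupied.update(mine)

    m_target = int(round(cfg.mean_ties_per_group * n / 2))
    m_target = min(m_target, n * (n - 1) // 2)
    social: set[tuple[str, str]] = set()
    mou_ids = [a.id for a in actors if a.category == ActorCategory.MOU]
    second_ids = [a.id for a in actors if a.category == ActorCategory.SECOND_GEN]
    attempts = 0
    max_attempts = 200 * max(m_target, 1)
    while len(social) < m_target:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError("could not place requested number of social ties")
        if mou_ids and second_ids and rng.random() < cfg.mentor_pref:
            u = second_ids[int(rng.integers(len(second_ids)))]
            v = mou_ids[int(rng.integers(len(mou_ids)))]
            edge = (u, v) if u <= v else (v, u)
            if edge not in social:
                social.add(edge)
        else:
            social.add(_uniform_new_pair(social, labels, rng))

    return SESNetwork.from_parts(
        actors=actors,
        ecos=[landscape.ecos[l] for l in lakes],
        social_edges=social,
        eco_edges=landscape.eco_edges,
        membership_edges=membership,
    )


def generate_network(cfg: SyntheticConfig) -> SESNetwork:
    """Landscape + groups in one call, fully determined by ``cfg.seed``."""
    return generate_groups(cfg, generate_landscape(cfg))


def neutral_config(
    n_actors: int = 23, n_lakes: int = 29, seed: int = 0, **overrides
) -> SyntheticConfig:
    """A configuration whose generative law equals the default null scheme.

    With all preferences at zero the social layer is a uniform simple
    graph of fixed edge count and each lake set a uniform subset of fixed
    size, i.e. exactly what the default randomization scheme draws; see
    the package methods notes for the argument.
    """
    n_mou = overrides.pop("n_mou", max(1, round(n_actors * 3 / 23)))
    n_first = overrides.pop("n_first_gen", max(0, round(n_actors * 7 / 23)))
    n_second = overrides.pop("n_second_gen", n_actors - n_mou - n_first)
    if n_second < 0:
        raise ValueError("category counts exceed n_actors")
    return SyntheticConfig(
        n_lakes=n_lakes,
        n_mou=n_mou,
        n_first_gen=n_first,
        n_second_gen=n_second,
        chain_pref=0.0,
        shared_lake_pref=0.0,
        mentor_pref=0.0,
        seed=seed,
        **overrides,
    )


def random_network(
    n_actors: int,
    n_ecos: int,
    p_social: float = 0.3,
    p_eco: float = 0.3,
    p_mem: float = 0.3,
    seed: int = 0,
    categories: list[ActorCategory] | None = None,
) -> SESNetwork:
    """Uniform independent-edge network over all three layers.

    Unstructured counterpart of :func:`generate_network`, mainly for
    exercising the census against its brute-force oracle across densities.
    Actor categories default to cycling through MOU / 1st / 2nd generation.
    """
    rng = np.random.default_rng(seed)
    alabels = actor_labels(n_actors)
    cycle = categories or [
        ActorCategory.MOU,
        ActorCategory.FIRST_GEN,
        ActorCategory.SECOND_GEN,
    ]
    actors = [ActorNode(a, cycle[i % len(cycle)]) for i, a in enumerate(alabels)]
    ecos = [EcoNode(l) for l in _lake_labels(n_ecos)]
    eids = [e.id for e in ecos]
    social = {
        (alabels[i], alabels[j])
        for i in range(n_actors)
        for j in range(i + 1, n_actors)
        if rng.random() < p_social
    }
    eco_edges = {
        (eids[i], eids[j])
        for i in range(n_ecos)
        for j in range(i + 1, n_ecos)
        if rng.random() < p_eco
    }
    membership = {(a, l) for a in alabels for l in eids if rng.random() < p_mem}
    return SESNetwork.from_parts(
        actors=actors,
        ecos=ecos,
        social_edges=social,
        eco_edges=eco_edges,
        membership_edges=membership,
    )


def planted_chain_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Strong chain preference at the study marginals: every group works
    two hydrologically adjacent lakes (rho = 1)."""
    overrides.setdefault("lakes_per_group", 2)
    return SyntheticConfig(chain_pref=1.0, shared_lake_pref=0.0, seed=seed, **overrides)


def anti_chain_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Strong chain avoidance: each group works four pairwise-unconnected
    lakes (rho = -1), the planted signal for over-represented misfit."""
    overrides.setdefault("lakes_per_group", 4)
    return SyntheticConfig(chain_pref=-1.0, shared_lake_pref=0.0, seed=seed, **overrides)
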