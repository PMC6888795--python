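"""Motif census: enumerate building-block occurrences in a network.

The counting unit is a symmetry-distinct slot assignment: every injective
mapping of slots to nodes that realizes all required edges and none of the
forbidden ones counts once per orbit of the block's symmetry group. A group
working three mutually connected lakes therefore contributes C(3,2)=3 lake
chain assignments, not one node subset. ``counting="node_sets"`` is
available as a documented alternative that collapses occurrences sharing
the same node set.

Two independent code paths exist on purpose:

* :func:`enumerate_block` / :func:`census` -- an order-optimized
  backtracking enumerator used everywhere, fast enough to sit inside the
  randomization null loop;
* :func:`brute_force_census` -- a plain exhaustive filter over all
  injective slot assignments, kept as the oracle the fast path is tested
  against.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .motifs import ACTOR, ECO, BlockCatalog, BuildingBlock
from .network import SESNetwork


@dataclass(frozen=True)
class Occurrence:
    """One motif occurrence: the canonical slot -> node assignment."""

    block_id: str
    assignment: tuple[tuple[str, str], ...]  # ((slot_name, node_id), ...) in slot order

    @property
    def assignment_dict(self) -> dict[str, str]:
        return dict(self.assignment)

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(n for _, n in self.assignment)


@dataclass
class MotifCensus:
    counts: dict[str, int]
    occurrences: dict[str, list[Occurrence]] | None = None
    counting: str = "assignments"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.counts.items()), columns=["block_id", "count"]
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def occurrences_frame(self) -> pd.DataFrame:
        if self.occurrences is None:
            raise ValueError("census was run without occurrence retention")
        rows = []
        for bid in sorted(self.occurrences):
            for k, occ in enumerate(self.occurrences[bid]):
                for slot, node in occ.assignment:
                    rows.append({"block_id": bid, "occurrence": k, "slot": slot, "node": node})
        return pd.DataFrame(rows, columns=["block_id", "occurrence", "slot", "node"])


class NetIndex:
    """Adjacency index for fast constraint checks, shared across blocks."""

    __slots__ = ("actors", "ecos", "social", "eco_adj", "lakes_of", "actors_of")

    def __init__(
        self,
        actors: Iterable[str],
        ecos: Iterable[str],
        social_edges: Iterable[tuple[str, str]],
        eco_edges: Iterable[tuple[str, str]],
        membership_edges: Iterable[tuple[str, str]],
    ):
        self.actors = sorted(actors)
        self.ecos = sorted(ecos)
        self.social: dict[str, set[str]] = {a: set() for a in self.actors}
        self.eco_adj: dict[str, set[str]] = {l: set() for l in self.ecos}
        self.lakes_of: dict[str, set[str]] = {a: set() for a in self.actors}
        self.actors_of: dict[str, set[str]] = {l: set() for l in self.ecos}
        for u, v in social_edges:
            self.social[u].add(v)
            self.social[v].add(u)
        for u, v in eco_edges:
            self.eco_adj[u].add(v)
            self.eco_adj[v].add(u)
        for a, l in membership_edges:
            self.lakes_of[a].add(l)
            self.actors_of[l].add(a)

    @classmethod
    def from_network(cls, net: SESNetwork) -> "NetIndex":
        return cls(
            net.actors, net.ecos, net.social_edges, net.eco_edges, net.membership_edges
        )

    def neighbors(self, layer: str, node: str, target_type: str) -> set[str]:
        if layer == "social":
            return self.social[node]
        if layer == "eco":
            return self.eco_adj[node]
        return self.lakes_of[node] if target_type == ECO else self.actors_of[node]


# -- backtracking plan ------------------------------------------------------


@dataclass(frozen=True)
class _Step:
    slot_index: int  # index into block.slots
    node_type: str
    # constraints against already-placed steps: (position in plan order, layer)
    required: tuple[tuple[int, str], ...]
    forbidden: tuple[tuple[int, str], ...]


@lru_cache(maxsize=256)
def _plan(block: BuildingBlock) -> tuple[_Step, ...]:
    """Slot visit order greedily maximizing required-edge anchoring."""
    names = block.slot_names
    idx = {s: i for i, s in enumerate(names)}
    req_pairs = [(idx[a], idx[b], lay) for a, b, lay in block.required]
    forb_pairs = [(idx[a], idx[b], lay) for a, b, lay in block.forbidden]
    order: list[int] = []
    remaining = set(range(len(names)))
    while remaining:
        def score(i: int) -> tuple[int, int, int]:
            r = sum(1 for a, b, _ in req_pairs if (a == i and b in placed) or (b == i and a in placed))
            t = sum(1 for a, b, _ in req_pairs if i in (a, b))
            return (r, t, -i)

        placed = set(order)
        nxt = max(remaining, key=score)
        order.append(nxt)
        remaining.discard(nxt)
    pos_in_order = {slot: k for k, slot in enumerate(order)}
    steps = []
    for k, slot in enumerate(order):
        req = []
        forb = []
        for a, b, lay in req_pairs:
            if a == slot and pos_in_order[b] < k:
                req.append((pos_in_order[b], lay))
            elif b == slot and pos_in_order[a] < k:
                req.append((pos_in_order[a], lay))
        for a, b, lay in forb_pairs:
            if a == slot and pos_in_order[b] < k:
                forb.append((pos_in_order[b], lay))
            elif b == slot and pos_in_order[a] < k:
                forb.append((pos_in_order[a], lay))
        steps.append(
            _Step(
                slot_index=slot,
                node_type=block.slots[slot][1],
                required=tuple(req),
                forbidden=tuple(forb),
            )
        )
    return tuple(steps)


@lru_cache(maxsize=256)
def _symmetry_sources(block: BuildingBlock) -> tuple[tuple[int, ...], ...]:
    """For each symmetry, image[i] = assignment[src[i]] in slot order."""
    names = block.slot_names
    idx = {s: i for i, s in enumerate(names)}
    out = []
    for sym in block.symmetries:
        # sym maps slot i -> sym[i]; node of slot j lands at slot sym[j],
        # so slot i receives the node of the slot mapped onto it.
        src = [0] * len(names)
        for j, target in enumerate(sym):
            src[idx[target]] = j
        out.append(tuple(src))
    return tuple(out)


def _iter_assignments(index: NetIndex, block: BuildingBlock):
    """Yield every satisfying injective assignment as a tuple in plan order."""
    plan = _plan(block)
    n = len(plan)
    assign: list[str | None] = [None] * n
    used: set[str] = set()
    slot_types = [block.slots[step.slot_index][1] for step in plan]

    def rec(d: int):
        if d == n:
            yield tuple(assign)
            return
        step = plan[d]
        ttype = slot_types[d]
        if step.required:
            base = None
            for j, lay in step.required:
                nb = index.neighbors(lay, assign[j], ttype)
                if base is None or len(nb) < len(base):
                    base = nb
            cands = sorted(base)
        else:
            cands = index.actors if ttype == ACTOR else index.ecos
        for v in cands:
            if v in used:
                continue
            ok = True
            for j, lay in step.required:
                if v not in index.neighbors(lay, assign[j], ttype):
                    ok = False
                    break
            if ok:
                for j, lay in step.forbidden:
                    if v in index.neighbors(lay, assign[j], ttype):
                        ok = False
                        break
            if not ok:
                continue
            assign[d] = v
            used.add(v)
            yield from rec(d + 1)
            used.discard(v)
        assign[d] = None

    yield from rec(0)


def _to_slot_order(block: BuildingBlock, plan_tuple: tuple[str, ...]) -> tuple[str, ...]:
    plan = _plan(block)
    out = [""] * len(plan)
    for d, step in enumerate(plan):
        out[step.slot_index] = plan_tuple[d]
    return tuple(out)


def _is_canonical(assign: tuple[str, ...], sym_sources) -> bool:
    for src in sym_sources:
        image = tuple(assign[j] for j in src)
        if image < assign:
            return False
    return True


def enumerate_block(
    net: SESNetwork | NetIndex, block: BuildingBlock
) -> list[Occurrence]:
    """All occurrences of ``block``, one canonical representative per orbit.

    The canonical representative is the lexicographically smallest
    assignment tuple (in slot order) within its symmetry orbit; the result
    is sorted, so enumeration order is deterministic.
    """
    index = net if isinstance(net, NetIndex) else NetIndex.from_network(net)
    syms = _symmetry_sources(block)
    names = block.slot_names
    occs = []
    for plan_tuple in _iter_assignments(index, block):
        assign = _to_slot_order(block, plan_tuple)
        if _is_canonical(assign, syms):
            occs.append(Occurrence(block.block_id, tuple(zip(names, assign))))
    occs.sort(key=lambda o: o.assignment)
    return occs


def _count_block(index: NetIndex, block: BuildingBlock) -> int:
    # every injective assignment's orbit has size |sym| exactly, so counting
    # all assignments and dividing is exact (and skips canonicalization)
    total = sum(1 for _ in _iter_assignments(index, block))
    nsym = len(block.symmetries)
    assert total % nsym == 0
    return total // nsym


def census(
    net: SESNetwork | NetIndex,
    catalog: BlockCatalog,
    keep_occurrences: bool = False,
    blocks: Iterable[str] | None = None,
    counting: str = "assignments",
) -> MotifCensus:
    """Observed counts per block; occurrence lists retained on request."""
    if counting not in ("assignments", "node_sets"):
        raise ValueError(f"unknown counting mode {counting!r}")
    index = net if isinstance(net, NetIndex) else NetIndex.from_network(net)
    wanted = list(blocks) if blocks is not None else [b.block_id for b in catalog]
    counts: dict[str, int] = {}
    occs: dict[str, list[Occurrence]] | None = {} if keep_occurrences else None
    for bid in wanted:
        block = catalog[bid]
        if keep_occurrences or counting == "node_sets":
            found = enumerate_block(index, block)
            if counting == "node_sets":
                counts[bid] = len({o.nodes for o in found})
            else:
                counts[bid] = len(found)
            if occs is not None:
                occs[bid] = found
        else:
            counts[bid] = _count_block(index, block)
    return MotifCensus(counts=counts, occurrences=occs, counting=counting)


# -- independent oracle -----------------------------------------------------


def _brute_occurrences(net: SESNetwork, block: BuildingBlock) -> list[Occurrence]:
    actor_slots = [s for s, t in block.slots if t == ACTOR]
    eco_slots = [s for s, t in block.slots if t == ECO]
    actors = sorted(net.actors)
    ecos = sorted(net.ecos)
    social = net.social_edges
    eco_e = net.eco_edges
    mem = net.membership_edges
    names = block.slot_names

    def has_edge(assign: dict[str, str], s1: str, s2: str, layer: str) -> bool:
        u, v = assign[s1], assign[s2]
        if layer == "social":
            return ((u, v) if u <= v else (v, u)) in social
        if layer == "eco":
            return ((u, v) if u <= v else (v, u)) in eco_e
        # normalized (actor_slot, eco_slot)
        return (u, v) in mem

    syms = _symmetry_sources(block)
    out = []
    for atup in itertools.permutations(actors, len(actor_slots)):
        for etup in itertools.permutations(ecos, len(eco_slots)):
            assign = dict(zip(actor_slots, atup))
            assign.update(zip(eco_slots, etup))
            if not all(has_edge(assign, *e) for e in block.required):
                continue
            if any(has_edge(assign, *e) for e in block.forbidden):
                continue
            ordered = tuple(assign[s] for s in names)
            if _is_canonical(ordered, syms):
                out.append(Occurrence(block.block_id, tuple(zip(names, ordered))))
    out.sort(key=lambda o: o.assignment)
    return out


def brute_force_census(
    net: SESNetwork,
    catalog: BlockCatalog,
    keep_occurrences: bool = True,
    counting: str = "assignments",
) -> MotifCensus:
    """Exhaustive census over all injective slot assignments (test oracle).

    Intended for small networks (roughly <= 10 nodes per type); independent
    of the backtracking path in :func:`enumerate_block`.
    """
    counts: dict[str, int] = {}
    occs: dict[str, list[Occurrence]] | None = {} if keep_occurrences else None
    for block in catalog:
        found = _brute_occurrences(net, block)
        if counting == "node_sets":
            counts[block.block_id] = len({o.nodes for o in found})
        else:
            counts[block.block_id] = len(found)
        if occs is not None:
            occs[block.block_id] = found
    return MotifCensus(counts=counts, occurrences=occs, counting=counting)
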