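"""Building-block (motif) templates over the two-level network.

A building block is a small typed template: named slots (actor or eco),
required edges, forbidden edges, reportable positions, and the slot
permutations under which the template is invariant (its symmetry group).
Layers a block does not mention are unconstrained, so blocks are induced
only on the pairs they explicitly require or forbid.

The default catalogue holds the ten blocks *a*-*j* used in the fit
analysis, organised in four families:

* shared lake      -- two groups work with the same lake, with (*a*) or
                      without (*b*) a collaboration tie;
* multiple lakes   -- one group works with two lakes that are hydrologically
                      connected (*c*, a "lake chain group") or not (*d*);
* mediated access  -- a tie where only one of the two groups holds the
                      resource link: centralized communication (*e*, an open
                      triad), a supported lake group (*f*), and external
                      support for a lake-chain group (*g*);
* parallel work    -- two groups work with one lake each on connected lakes,
                      with (*h*, "lake chain collaboration") or without (*i*)
                      a tie, or communicate over unconnected lakes (*j*).

Each block carries a fit label per hypothesis (good / poor / neutral fit).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

ACTOR = "actor"
ECO = "eco"
LAYERS = ("social", "eco", "membership")

Edge = tuple[str, str, str]  # (slot, slot, layer)


@dataclass(frozen=True)
class BuildingBlock:
    block_id: str
    name: str
    slots: tuple[tuple[str, str], ...]  # (slot_name, node_type)
    required: frozenset[Edge]
    forbidden: frozenset[Edge]
    # (position_name, slots pooled into it); symmetric slots share a position
    positions: tuple[tuple[str, tuple[str, ...]], ...]
    # each symmetry maps slots[i] -> symmetry[i]; identity always present
    symmetries: tuple[tuple[str, ...], ...]
    fit_labels: tuple[tuple[str, str], ...] = ()

    @property
    def slot_names(self) -> tuple[str, ...]:
        return tuple(s for s, _ in self.slots)

    @property
    def slot_types(self) -> dict[str, str]:
        return dict(self.slots)

    @property
    def positions_dict(self) -> dict[str, tuple[str, ...]]:
        return dict(self.positions)

    @property
    def fit_labels_dict(self) -> dict[str, str]:
        return dict(self.fit_labels)

    def fit_label(self, hypothesis: str) -> str:
        return self.fit_labels_dict.get(hypothesis, "neutral")

    def normalize_edge(self, edge: Edge) -> Edge:
        s1, s2, layer = edge
        if layer == "membership":
            # stored as (actor_slot, eco_slot)
            if self.slot_types[s1] == ECO:
                s1, s2 = s2, s1
            return (s1, s2, layer)
        order = {name: i for i, name in enumerate(self.slot_names)}
        if order[s1] > order[s2]:
            s1, s2 = s2, s1
        return (s1, s2, layer)

    def apply_symmetry(self, sym: tuple[str, ...], edges: frozenset[Edge]) -> frozenset[Edge]:
        mapping = dict(zip(self.slot_names, sym))
        return frozenset(
            self.normalize_edge((mapping[s1], mapping[s2], layer)) for s1, s2, layer in edges
        )


class CatalogError(ValueError):
    pass


def validate_block(block: BuildingBlock) -> None:
    """Raise :class:`CatalogError` on any template inconsistency."""
    names = block.slot_names
    if len(set(names)) != len(names):
        raise CatalogError(f"block {block.block_id}: duplicate slot names")
    types = block.slot_types
    for t in types.values():
        if t not in (ACTOR, ECO):
            raise CatalogError(f"block {block.block_id}: unknown node type {t!r}")
    for edges, kind in ((block.required, "required"), (block.forbidden, "forbidden")):
        for s1, s2, layer in edges:
            if layer not in LAYERS:
                raise CatalogError(f"block {block.block_id}: unknown layer {layer!r}")
            if s1 not in types or s2 not in types:
                raise CatalogError(f"block {block.block_id}: {kind} edge uses unknown slot")
            pair = (types[s1], types[s2])
            ok = {
                "social": pair == (ACTOR, ACTOR),
                "eco": pair == (ECO, ECO),
                "membership": set(pair) == {ACTOR, ECO},
            }[layer]
            if not ok:
                raise CatalogError(
                    f"block {block.block_id}: {kind} {layer} edge {s1}-{s2} is type-inconsistent"
                )
            if s1 == s2:
                raise CatalogError(f"block {block.block_id}: {kind} self-edge at slot {s1}")
            if block.normalize_edge((s1, s2, layer)) != (s1, s2, layer):
                raise CatalogError(
                    f"block {block.block_id}: {kind} edge {(s1, s2, layer)} not normalized"
                )
    if block.required & block.forbidden:
        raise CatalogError(f"block {block.block_id}: required and forbidden edges overlap")
    syms = set(block.symmetries)
    if tuple(names) not in syms:
        raise CatalogError(f"block {block.block_id}: symmetry group lacks the identity")
    # closure under composition, type preservation, edge-set invariance
    for sym in syms:
        if sorted(sym) != sorted(names):
            raise CatalogError(f"block {block.block_id}: symmetry {sym} is not a permutation")
        mapping = dict(zip(names, sym))
        for s in names:
            if types[mapping[s]] != types[s]:
                raise CatalogError(f"block {block.block_id}: symmetry mixes node types")
        if block.apply_symmetry(sym, block.required) != block.required:
            raise CatalogError(f"block {block.block_id}: symmetry breaks required edges")
        if block.apply_symmetry(sym, block.forbidden) != block.forbidden:
            raise CatalogError(f"block {block.block_id}: symmetry breaks forbidden edges")
    for s1 in syms:
        m1 = dict(zip(names, s1))
        for s2 in syms:
            m2 = dict(zip(names, s2))
            comp = tuple(m2[m1[s]] for s in names)
            if comp not in syms:
                raise CatalogError(f"block {block.block_id}: symmetry group not closed")
    for pos, pslots in block.positions:
        for s in pslots:
            if s not in types:
                raise CatalogError(f"block {block.block_id}: position {pos} uses unknown slot {s}")


@dataclass(frozen=True)
class BlockCatalog:
    blocks: Mapping[str, BuildingBlock]

    def __iter__(self):
        return iter(self.blocks.values())

    def __getitem__(self, block_id: str) -> BuildingBlock:
        return self.blocks[block_id]

    def __len__(self) -> int:
        return len(self.blocks)


def _mk(
    block_id: str,
    name: str,
    slots,
    required,
    forbidden,
    positions,
    symmetries,
    fit_labels=(),
) -> BuildingBlock:
    blk = BuildingBlock(
        block_id=block_id,
        name=name,
        slots=tuple(tuple(s) for s in slots),
        required=frozenset(),
        forbidden=frozenset(),
        positions=tuple((p, tuple(ss)) for p, ss in positions),
        symmetries=tuple(tuple(s) for s in symmetries),
        fit_labels=tuple(fit_labels),
    )
    req = frozenset(blk.normalize_edge(tuple(e)) for e in required)
    forb = frozenset(blk.normalize_edge(tuple(e)) for e in forbidden)
    blk = BuildingBlock(
        block_id=blk.block_id,
        name=blk.name,
        slots=blk.slots,
        required=req,
        forbidden=forb,
        positions=blk.positions,
        symmetries=blk.symmetries,
        fit_labels=blk.fit_labels,
    )
    validate_block(blk)
    return blk


def default_catalog() -> BlockCatalog:
    """The ten-block catalogue *a*-*j* with default fit labels for H1.

    Good fit for H1: collaborative lake sharing (*a*), lake chain groups
    (*c*) and lake chain collaborations (*h*). Poor fit: non-collaborative
    sharing (*b*), work on unconnected lakes (*d*) and uncoordinated
    parallel work on connected lakes (*i*). The remaining blocks describe
    communication structure and are neutral for H1.
    """
    AA = ("A1", ACTOR)
    blocks = [
        _mk(
            "a",
            "collaborative shared lake",
            [AA, ("A2", ACTOR), ("E1", ECO)],
            [("A1", "E1", "membership"), ("A2", "E1", "membership"), ("A1", "A2", "social")],
            [],
            [("a-1", ("A1", "A2"))],
            [("A1", "A2", "E1"), ("A2", "A1", "E1")],
            [("H1", "good")],
        ),
        _mk(
            "b",
            "non-collaborative sharing of lakes",
            [AA, ("A2", ACTOR), ("E1", ECO)],
            [("A1", "E1", "membership"), ("A2", "E1", "membership")],
            [("A1", "A2", "social")],
            [("b-1", ("A1", "A2"))],
            [("A1", "A2", "E1"), ("A2", "A1", "E1")],
            [("H1", "poor")],
        ),
        _mk(
            "c",
            "lake chain group",
            [AA, ("E1", ECO), ("E2", ECO)],
            [("A1", "E1", "membership"), ("A1", "E2", "membership"), ("E1", "E2", "eco")],
            [],
            [("c-1", ("A1",))],
            [("A1", "E1", "E2"), ("A1", "E2", "E1")],
            [("H1", "good")],
        ),
        _mk(
            "d",
            "group working with unconnected lakes",
            [AA, ("E1", ECO), ("E2", ECO)],
            [("A1", "E1", "membership"), ("A1", "E2", "membership")],
            [("E1", "E2", "eco")],
            [("d-1", ("A1",))],
            [("A1", "E1", "E2"), ("A1", "E2", "E1")],
            [("H1", "poor")],
        ),
        _mk(
            "e",
            "centralized communication",
            [AA, ("A2", ACTOR), ("A3", ACTOR)],
            [("A1", "A2", "social"), ("A1", "A3", "social")],
            [("A2", "A3", "social")],
            [("e-1", ("A1",)), ("e-2", ("A2", "A3"))],
            [("A1", "A2", "A3"), ("A1", "A3", "A2")],
        ),
        _mk(
            "f",
            "supported lake group",
            [AA, ("A2", ACTOR), ("E1", ECO)],
            [("A1", "A2", "social"), ("A1", "E1", "membership")],
            [("A2", "E1", "membership")],
            [("f-1", ("A1",)), ("f-2", ("A2",))],
            [("A1", "A2", "E1")],
        ),
        _mk(
            "g",
            "external support for a lake chain group",
            [AA, ("A2", ACTOR), ("E1", ECO), ("E2", ECO)],
            [
                ("A1", "A2", "social"),
                ("A1", "E1", "membership"),
                ("A1", "E2", "membership"),
                ("E1", "E2", "eco"),
            ],
            [("A2", "E1", "membership"), ("A2", "E2", "membership")],
            [("g-1", ("A1",)), ("g-2", ("A2",))],
            [("A1", "A2", "E1", "E2"), ("A1", "A2", "E2", "E1")],
        ),
        _mk(
            "h",
            "lake chain collaboration",
            [AA, ("A2", ACTOR), ("E1", ECO), ("E2", ECO)],
            [
                ("A1", "A2", "social"),
                ("A1", "E1", "membership"),
                ("A2", "E2", "membership"),
                ("E1", "E2", "eco"),
            ],
            [("A1", "E2", "membership"), ("A2", "E1", "membership")],
            [("h-1", ("A1", "A2"))],
            [("A1", "A2", "E1", "E2"), ("A2", "A1", "E2", "E1")],
            [("H1", "good")],
        ),
        _mk(
            "i",
            "parallel work on connected lakes without a tie",
            [AA, ("A2", ACTOR), ("E1", ECO), ("E2", ECO)],
            [
                ("A1", "E1", "membership"),
                ("A2", "E2", "membership"),
                ("E1", "E2", "eco"),
            ],
            [
                ("A1", "A2", "social"),
                ("A1", "E2", "membership"),
                ("A2", "E1", "membership"),
            ],
            [("i-1", ("A1", "A2"))],
            [("A1", "A2", "E1", "E2"), ("A2", "A1", "E2", "E1")],
            [("H1", "poor")],
        ),
        _mk(
            "j",
            "communication over unconnected lakes",
            [AA, ("A2", ACTOR), ("E1", ECO), ("E2", ECO)],
            [
                ("A1", "A2", "social"),
                ("A1", "E1", "membership"),
                ("A2", "E2", "membership"),
            ],
            [
                ("E1", "E2", "eco"),
                ("A1", "E2", "membership"),
                ("A2", "E1", "membership"),
            ],
            [("j-1", ("A1", "A2"))],
            [("A1", "A2", "E1", "E2"), ("A2", "A1", "E2", "E1")],
        ),
    ]
    return BlockCatalog(blocks={b.block_id: b for b in blocks})


# ---------------------------------------------------------------------------
# JSON (de)serialization so users can amend or replace templates.
# ---------------------------------------------------------------------------


def _block_to_json(b: BuildingBlock) -> dict:
    return {
        "id": b.block_id,
        "name": b.name,
        "slots": [list(s) for s in b.slots],
        "required": [list(e) for e in sorted(b.required)],
        "forbidden": [list(e) for e in sorted(b.forbidden)],
        "positions": {p: list(ss) for p, ss in b.positions},
        "symmetries": [list(s) for s in b.symmetries],
        "fit_labels": dict(b.fit_labels),
    }


def save_catalog(catalog: BlockCatalog, path: str | Path) -> None:
    payload = {"blocks": [_block_to_json(b) for b in catalog]}
    Path(path).write_text(json.dumps(payload, indent=2))


def load_catalog(path: str | Path) -> BlockCatalog:
    """Load a catalogue from the documented JSON schema, validating fully."""
    payload = json.loads(Path(path).read_text())
    blocks = {}
    for spec in payload["blocks"]:
        blk = _mk(
            spec["id"],
            spec.get("name", spec["id"]),
            [tuple(s) for s in spec["slots"]],
            [tuple(e) for e in spec.get("required", [])],
            [tuple(e) for e in spec.get("forbidden", [])],
            list(spec.get("positions", {}).items()),
            spec.get("symmetries") or [[s for s, _ in spec["slots"]]],
            sorted(spec.get("fit_labels", {}).items()),
        )
        if blk.block_id in blocks:
            raise CatalogError(f"duplicate block id {blk.block_id!r}")
        blocks[blk.block_id] = blk
    return BlockCatalog(blocks=blocks)
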