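"""Typed two-level social-ecological network: data model, validation and I/O.

The network has two node types -- actors (e.g. lake groups) and ecosystem
nodes (e.g. lakes) -- and three undirected edge layers:

* ``social``     : actor--actor collaboration ties,
* ``eco``        : eco--eco physical connections (e.g. water flow),
* ``membership`` : actor--eco management/work ties.

Edges are stored as normalized tuples (sorted within the social and eco
layers; ``(actor_id, eco_id)`` for membership), so symmetric duplicates
collapse on construction. Validation is separate from construction: an
invalid network *can* be represented (tests rely on this) and
:func:`validate` reports every violation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd


class ActorCategory(str, Enum):
    """Actor attribute used by the positional analysis.

    ``MOU`` actors hold a formal co-management agreement with authorities;
    ``FIRST_GEN`` / ``SECOND_GEN`` distinguish groups founded before/after
    such agreements were introduced; ``OTHER`` is for non-study uses.
    """

    MOU = "MOU"
    FIRST_GEN = "FIRST_GEN"
    SECOND_GEN = "SECOND_GEN"
    OTHER = "OTHER"


@dataclass(frozen=True)
class ActorNode:
    id: str
    category: ActorCategory = ActorCategory.OTHER
    start_year: int | None = None


@dataclass(frozen=True)
class EcoNode:
    id: str
    watershed: str | None = None


def _und(u: str, v: str) -> tuple[str, str]:
    """Normalized undirected pair (self-loops kept representable)."""
    return (u, v) if u <= v else (v, u)


@dataclass
class SESNetwork:
    """A two-level network over actor and ecosystem nodes.

    ``actors`` / ``ecos`` map node id to node object. Edge sets hold
    normalized tuples. ``eco_edge_annotations`` carries optional per-edge
    metadata (e.g. a flow ``direction`` column) that is preserved by I/O
    but ignored by all analyses.
    """

    actors: dict[str, ActorNode] = field(default_factory=dict)
    ecos: dict[str, EcoNode] = field(default_factory=dict)
    social_edges: set[tuple[str, str]] = field(default_factory=set)
    eco_edges: set[tuple[str, str]] = field(default_factory=set)
    membership_edges: set[tuple[str, str]] = field(default_factory=set)
    eco_edge_annotations: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.social_edges = {_und(*e) for e in self.social_edges}
        self.eco_edges = {_und(*e) for e in self.eco_edges}
        self.membership_edges = {tuple(e) for e in self.membership_edges}
        self.eco_edge_annotations = {
            _und(*e): v for e, v in self.eco_edge_annotations.items()
        }

    # -- construction ----------------------------------------------------
    @classmethod
    def from_parts(
        cls,
        actors: Iterable[ActorNode],
        ecos: Iterable[EcoNode],
        social_edges: Iterable[tuple[str, str]] = (),
        eco_edges: Iterable[tuple[str, str]] = (),
        membership_edges: Iterable[tuple[str, str]] = (),
    ) -> "SESNetwork":
        a = {}
        for node in actors:
            if node.id in a:
                raise ValueError(f"duplicate actor id {node.id!r}")
            a[node.id] = node
        e = {}
        for node in ecos:
            if node.id in e or node.id in a:
                raise ValueError(f"duplicate or actor-colliding eco id {node.id!r}")
            e[node.id] = node
        return cls(
            actors=a,
            ecos=e,
            social_edges=set(map(tuple, social_edges)),
            eco_edges=set(map(tuple, eco_edges)),
            membership_edges=set(map(tuple, membership_edges)),
        )

    # -- convenience -----------------------------------------------------
    def copy(self) -> "SESNetwork":
        return SESNetwork(
            actors=dict(self.actors),
            ecos=dict(self.ecos),
            social_edges=set(self.social_edges),
            eco_edges=set(self.eco_edges),
            membership_edges=set(self.membership_edges),
            eco_edge_annotations=dict(self.eco_edge_annotations),
        )

    def equals(self, other: "SESNetwork") -> bool:
        """Order-insensitive structural equality (nodes, attributes, edges)."""
        return (
            self.actors == other.actors
            and self.ecos == other.ecos
            and self.social_edges == other.social_edges
            and self.eco_edges == other.eco_edges
            and self.membership_edges == other.membership_edges
        )


@dataclass(frozen=True)
class Violation:
    """One invariant violation; ``tag`` is machine-codable, ``message`` human."""

    tag: str
    message: str


@dataclass(frozen=True)
class NetworkSummary:
    n_actors: int
    n_ecos: int
    n_social_edges: int
    n_eco_edges: int
    n_membership_edges: int
    actors_by_category: Mapping[ActorCategory, int]


def validate(net: SESNetwork) -> list[Violation]:
    """Return all invariant violations (empty list means valid)."""
    out: list[Violation] = []
    overlap = set(net.actors) & set(net.ecos)
    for nid in sorted(overlap):
        out.append(Violation("namespace_overlap", f"id {nid!r} is both actor and eco"))
    for u, v in sorted(net.social_edges):
        if u == v:
            out.append(Violation("self_loop", f"social self-loop at {u!r}"))
        for x in (u, v):
            if x not in net.actors:
                out.append(
                    Violation("dangling_endpoint", f"social edge {u}-{v}: {x!r} is not an actor")
                )
    for u, v in sorted(net.eco_edges):
        if u == v:
            out.append(Violation("self_loop", f"eco self-loop at {u!r}"))
        for x in (u, v):
            if x not in net.ecos:
                out.append(
                    Violation("dangling_endpoint", f"eco edge {u}-{v}: {x!r} is not an eco node")
                )
    for a, l in sorted(net.membership_edges):
        if a not in net.actors:
            out.append(
                Violation("dangling_endpoint", f"membership edge {a}-{l}: {a!r} is not an actor")
            )
        if l not in net.ecos:
            out.append(
                Violation("dangling_endpoint", f"membership edge {a}-{l}: {l!r} is not an eco node")
            )
    for aid, node in net.actors.items():
        if not isinstance(node.category, ActorCategory):
            out.append(Violation("bad_category", f"actor {aid!r} has invalid category"))
    return out


def summarize(net: SESNetwork) -> NetworkSummary:
    by_cat = {c: 0 for c in ActorCategory}
    for node in net.actors.values():
        by_cat[node.category] += 1
    return NetworkSummary(
        n_actors=len(net.actors),
        n_ecos=len(net.ecos),
        n_social_edges=len(net.social_edges),
        n_eco_edges=len(net.eco_edges),
        n_membership_edges=len(net.membership_edges),
        actors_by_category=by_cat,
    )


# ---------------------------------------------------------------------------
# Delimited-text I/O: five comma-separated, headered, UTF-8 files.
# ---------------------------------------------------------------------------

_ACTOR_COLS = ("id", "category", "start_year")
_ECO_COLS = ("id", "watershed")


def _read(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return df


def load_network(
    actor_table: str | Path,
    eco_table: str | Path,
    social_table: str | Path,
    eco_edge_table: str | Path,
    membership_table: str | Path,
) -> SESNetwork:
    """Load and validate a network from the five-file CSV bundle.

    Edges are undirected: a pair listed in either (or both) orientations
    yields one edge, matching a reported-by-either-party tie definition.
    Referential or structural problems raise ``ValueError`` naming the
    offending row.
    """
    adf = _read(actor_table, ("id", "category"))
    actors: dict[str, ActorNode] = {}
    for i, row in adf.iterrows():
        aid = row["id"].strip()
        if aid in actors:
            raise ValueError(f"{actor_table} row {i}: duplicate actor id {aid!r}")
        try:
            cat = ActorCategory(row["category"].strip())
        except ValueError:
            raise ValueError(
                f"{actor_table} row {i}: unknown category {row['category']!r}"
            ) from None
        year = None
        if "start_year" in adf.columns and row["start_year"].strip():
            year = int(row["start_year"])
        actors[aid] = ActorNode(aid, cat, year)

    edf = _read(eco_table, ("id",))
    ecos: dict[str, EcoNode] = {}
    for i, row in edf.iterrows():
        eid = row["id"].strip()
        if eid in ecos:
            raise ValueError(f"{eco_table} row {i}: duplicate eco id {eid!r}")
        if eid in actors:
            raise ValueError(f"{eco_table} row {i}: id {eid!r} already used for an actor")
        ws = row["watershed"].strip() if "watershed" in edf.columns else ""
        ecos[eid] = EcoNode(eid, ws or None)

    net = SESNetwork(actors=actors, ecos=ecos)

    sdf = _read(social_table, ("actor1", "actor2"))
    for i, row in sdf.iterrows():
        u, v = row["actor1"].strip(), row["actor2"].strip()
        for x in (u, v):
            if x not in actors:
                raise ValueError(f"{social_table} row {i}: unknown actor id {x!r}")
        if u == v:
            raise ValueError(f"{social_table} row {i}: self-loop at {u!r}")
        net.social_edges.add(_und(u, v))

    gdf = _read(eco_edge_table, ("eco1", "eco2"))
    for i, row in gdf.iterrows():
        u, v = row["eco1"].strip(), row["eco2"].strip()
        for x in (u, v):
            if x not in ecos:
                raise ValueError(f"{eco_edge_table} row {i}: unknown eco id {x!r}")
        if u == v:
            raise ValueError(f"{eco_edge_table} row {i}: self-loop at {u!r}")
        net.eco_edges.add(_und(u, v))
        if "direction" in gdf.columns and row["direction"].strip():
            net.eco_edge_annotations[_und(u, v)] = row["direction"].strip()

    mdf = _read(membership_table, ("actor", "eco"))
    for i, row in mdf.iterrows():
        a, l = row["actor"].strip(), row["eco"].strip()
        if a not in actors:
            raise ValueError(f"{membership_table} row {i}: unknown actor id {a!r}")
        if l not in ecos:
            raise ValueError(f"{membership_table} row {i}: unknown eco id {l!r}")
        net.membership_edges.add((a, l))

    problems = validate(net)
    if problems:
        raise ValueError("invalid network: " + "; ".join(v.message for v in problems))
    return net


def write_network(net: SESNetwork, out_dir: str | Path) -> dict[str, Path]:
    """Write the five-file CSV bundle; returns the paths keyed by table name."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "actors": out / "actors.csv",
        "lakes": out / "lakes.csv",
        "social_edges": out / "social_edges.csv",
        "eco_edges": out / "eco_edges.csv",
        "membership": out / "membership.csv",
    }
    pd.DataFrame(
        [
            {
                "id": a.id,
                "category": a.category.value,
                "start_year": "" if a.start_year is None else a.start_year,
            }
            for a in sorted(net.actors.values(), key=lambda n: n.id)
        ],
        columns=list(_ACTOR_COLS),
    ).to_csv(paths["actors"], index=False)
    pd.DataFrame(
        [
            {"id": e.id, "watershed": e.watershed or ""}
            for e in sorted(net.ecos.values(), key=lambda n: n.id)
        ],
        columns=list(_ECO_COLS),
    ).to_csv(paths["lakes"], index=False)
    pd.DataFrame(
        sorted(net.social_edges), columns=["actor1", "actor2"]
    ).to_csv(paths["social_edges"], index=False)
    pd.DataFrame(
        [
            {"eco1": u, "eco2": v, "direction": net.eco_edge_annotations.get((u, v), "")}
            for u, v in sorted(net.eco_edges)
        ],
        columns=["eco1", "eco2", "direction"],
    ).to_csv(paths["eco_edges"], index=False)
    pd.DataFrame(
        sorted(net.membership_edges), columns=["actor", "eco"]
    ).to_csv(paths["membership"], index=False)
    return paths


def to_networkx(net: SESNetwork):
    """Flatten to a single ``networkx.Graph`` with typed nodes/edges.

    Node attribute ``ntype`` is ``actor`` or ``eco``; edge attribute
    ``layer`` is ``social``, ``eco`` or ``membership``.
    """
    import networkx as nx

    g = nx.Graph()
    for a in net.actors.values():
        g.add_node(
            a.id,
            ntype="actor",
            category=a.category.value,
            **({"start_year": a.start_year} if a.start_year is not None else {}),
        )
    for e in net.ecos.values():
        g.add_node(e.id, ntype="eco", **({"watershed": e.watershed} if e.watershed else {}))
    for u, v in sorted(net.social_edges):
        g.add_edge(u, v, layer="social")
    for u, v in sorted(net.eco_edges):
        g.add_edge(u, v, layer="eco")
    for a, l in sorted(net.membership_edges):
        g.add_edge(a, l, layer="membership")
    return g


def write_graphml(net: SESNetwork, path: str | Path) -> None:
    import networkx as nx

    nx.write_graphml(to_networkx(net), str(path))
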