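"""Positional-occupancy analysis: who sits where in each building block.

For every retained occurrence and every reportable position of its block,
the occupying actor's tally is incremented. Symmetric slots pool into one
position (e.g. the two peripheral slots of the centralized-communication
triad are a single ``e-2`` position), so a block's tallies for a position
sum to ``count(block) * multiplicity`` where multiplicity is the number of
pooled slots. Row-normalized shares are normalized per (block, position)
row and are therefore not comparable between rows. Category aggregates sum
the shares of actors with a given attribute (e.g. the MOU share of the hub
position ``e-1``).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .census import MotifCensus
from .motifs import BlockCatalog
from .network import ActorCategory, SESNetwork


@dataclass
class PositionOccupancy:
    # (block_id, position) -> actor -> tally
    counts: dict[tuple[str, str], dict[str, int]]
    # (block_id, position) -> actor -> share in [0, 1]
    row_norm: dict[tuple[str, str], dict[str, float]]
    # (block_id, position, category) -> share
    by_category: dict[tuple[str, str, ActorCategory], float]
    block_counts: dict[str, int]
    actor_categories: dict[str, ActorCategory]
    multiplicity: dict[tuple[str, str], int]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (bid, pos), tally in sorted(self.counts.items()):
            for actor in sorted(tally):
                rows.append(
                    {
                        "block_id": bid,
                        "position": pos,
                        "actor_id": actor,
                        "count": tally[actor],
                        "share": self.row_norm[(bid, pos)][actor],
                    }
                )
        return pd.DataFrame(rows, columns=["block_id", "position", "actor_id", "count", "share"])

    def category_frame(self) -> pd.DataFrame:
        rows = [
            {"block_id": bid, "position": pos, "category": cat.value, "share": share}
            for (bid, pos, cat), share in sorted(
                self.by_category.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2].value)
            )
        ]
        return pd.DataFrame(rows, columns=["block_id", "position", "category", "share"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def positional_occupancy(
    net: SESNetwork, catalog: BlockCatalog, census_result: MotifCensus
) -> PositionOccupancy:
    """Tally actor occupancy of every reportable position.

    Requires a census run with ``keep_occurrences=True``; raises otherwise.
    """
    if census_result.occurrences is None:
        raise ValueError(
            "census has no occurrence lists; re-run census(..., keep_occurrences=True)"
        )
    counts: dict[tuple[str, str], dict[str, int]] = {}
    multiplicity: dict[tuple[str, str], int] = {}
    for bid, occs in census_result.occurrences.items():
        block = catalog[bid]
        for pos, slots in block.positions:
            key = (bid, pos)
            multiplicity[key] = len(slots)
            tally: Counter[str] = Counter()
            for occ in occs:
                assign = occ.assignment_dict
                for slot in slots:
                    tally[assign[slot]] += 1
            counts[key] = dict(tally)
    row_norm: dict[tuple[str, str], dict[str, float]] = {}
    for key, tally in counts.items():
        total = sum(tally.values())
        row_norm[key] = (
            {a: c / total for a, c in tally.items()} if total > 0 else {}
        )
    cats = {aid: node.category for aid, node in net.actors.items()}
    by_category: dict[tuple[str, str, ActorCategory], float] = {}
    for (bid, pos), shares in row_norm.items():
        for cat in ActorCategory:
            by_category[(bid, pos, cat)] = sum(
                s for a, s in shares.items() if cats.get(a) == cat
            )
    return PositionOccupancy(
        counts=counts,
        row_norm=row_norm,
        by_category=by_category,
        block_counts=dict(census_result.counts),
        actor_categories=cats,
        multiplicity=multiplicity,
    )


def category_share(
    occ: PositionOccupancy,
    block_id: str,
    position: str,
    category: ActorCategory | str,
) -> float:
    """Share of a (block, position) row held by actors of ``category``.

    Returns NaN when the block has no occurrences (the share is undefined).
    """
    cat = ActorCategory(category)
    key = (block_id, position)
    if key not in occ.counts:
        raise KeyError(f"unknown block/position {key}")
    if sum(occ.counts[key].values()) == 0:
        return math.nan
    return occ.by_category[(block_id, position, cat)]


def plot_occupancy(
    occ: PositionOccupancy,
    path: str | Path | None = None,
    actor_order: list[str] | None = None,
):
    """Dot-matrix presence plot: one row per (block, position), one column
    per actor; filled dots mark presence, bar height the row-share."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    actors = actor_order or sorted(occ.actor_categories)
    keys = sorted(occ.counts)
    fig, ax = plt.subplots(figsize=(0.35 * len(actors) + 2, 0.45 * len(keys) + 1.5))
    for r, key in enumerate(keys):
        shares = occ.row_norm[key]
        for cidx, a in enumerate(actors):
            share = shares.get(a, 0.0)
            present = occ.counts[key].get(a, 0) > 0
            ax.plot(
                cidx,
                len(keys) - 1 - r,
                "o",
                mfc="black" if present else "white",
                mec="black",
                ms=6,
            )
            if share > 0:
                ax.bar(cidx, share * 0.8, bottom=len(keys) - 1 - r + 0.15, width=0.5,
                       color="steelblue", alpha=0.7)
    ax.set_xticks(range(len(actors)), actors)
    ax.set_yticks(range(len(keys)), [f"{b}:{p}" for b, p in reversed(keys)])
    ax.set_xlabel("actor")
    ax.set_title("positional occupancy (bars: row-normalized share)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
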