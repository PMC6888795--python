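"""Randomized-network null models and empirical significance codes.

The ecological layer is never randomized: the physical landscape is a
fixed constraint, and the question is whether actors direct collaboration
and management effort toward it more (or less) than chance. The default
scheme keeps each actor's number of managed lakes ("workload") and the
total number of social ties, randomizing who ties with whom and which
lakes are managed:

* ``social: fixed_count_shuffle``      -- uniform simple graph with the
  observed edge count (``degree_preserving_swap`` and ``frozen`` are
  selectable alternatives);
* ``membership: actor_degree_preserving`` -- each actor's lake set redrawn
  uniformly at its observed size (``both_degrees_preserving`` checkerboard
  swaps and ``frozen`` available);
* ``eco: frozen`` (always).

Per block, significance against R randomized replicates uses the +1
corrected empirical probabilities

    p_upper = (1 + #{null >= obs}) / (R + 1)
    p_lower = (1 + #{null <= obs}) / (R + 1)

coded ``++``/``+`` for over-representation at p<0.01 / p<0.05 and
``--``/``-`` symmetrically for under-representation, else ``0``. Two
one-sided tests are used (rather than one doubled two-sided p) because the
codes are signed. A z-score variant against the null mean/sd is exposed as
an option for comparison with normal-approximation reports.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .census import NetIndex, census
from .motifs import BlockCatalog
from .network import SESNetwork, _und

SOCIAL_MODES = ("fixed_count_shuffle", "degree_preserving_swap", "frozen")
MEMBERSHIP_MODES = ("actor_degree_preserving", "both_degrees_preserving", "frozen")

STRONG = 0.01
WEAK = 0.05


@dataclass(frozen=True)
class RandomizationScheme:
    social_mode: str = "fixed_count_shuffle"
    membership_mode: str = "actor_degree_preserving"
    eco_mode: str = "frozen"

    def __post_init__(self) -> None:
        if self.social_mode not in SOCIAL_MODES:
            raise ValueError(f"unknown social_mode {self.social_mode!r}")
        if self.membership_mode not in MEMBERSHIP_MODES:
            raise ValueError(f"unknown membership_mode {self.membership_mode!r}")
        if self.eco_mode != "frozen":
            raise ValueError("the eco layer is always frozen")


def _shuffle_social(
    actors: list[str], m: int, rng: np.random.Generator
) -> set[tuple[str, str]]:
    pairs = [(actors[i], actors[j]) for i in range(len(actors)) for j in range(i + 1, len(actors))]
    if m > len(pairs):
        raise ValueError("more social edges than actor pairs")
    picked = rng.choice(len(pairs), size=m, replace=False)
    return {pairs[k] for k in picked}


def _swap_social(
    edges: set[tuple[str, str]], rng: np.random.Generator
) -> set[tuple[str, str]]:
    """Degree-preserving double-edge swaps (>= 10x|E| successful swaps)."""
    edge_list = sorted(edges)
    m = len(edge_list)
    if m < 2:
        return set(edge_list)
    edge_set = set(edge_list)
    target = 10 * m
    done = 0
    tries = 0
    max_tries = 200 * m + 1000
    while done < target and tries < max_tries:
        tries += 1
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        (a, b), (c, d) = edge_list[i], edge_list[j]
        if rng.random() < 0.5:
            c, d = d, c
        # rewire a-b, c-d  ->  a-c, b-d
        if len({a, b, c, d}) < 4:
            continue
        e1, e2 = _und(a, c), _und(b, d)
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(edge_list[i])
        edge_set.discard(edge_list[j])
        edge_set.add(e1)
        edge_set.add(e2)
        edge_list[i], edge_list[j] = e1, e2
        done += 1
    return edge_set


def _shuffle_membership_actor(
    lakes_of: Mapping[str, set[str]], ecos: list[str], rng: np.random.Generator
) -> set[tuple[str, str]]:
    out: set[tuple[str, str]] = set()
    n = len(ecos)
    for a in sorted(lakes_of):
        k = len(lakes_of[a])
        if k == 0:
            continue
        picked = rng.choice(n, size=k, replace=False)
        out.update((a, ecos[p]) for p in picked)
    return out


def _swap_membership_both(
    edges: set[tuple[str, str]], rng: np.random.Generator
) -> set[tuple[str, str]]:
    """Bipartite checkerboard swaps preserving both degree sequences."""
    edge_list = sorted(edges)
    m = len(edge_list)
    if m < 2:
        return set(edge_list)
    edge_set = set(edge_list)
    target = 10 * m
    done = 0
    tries = 0
    max_tries = 200 * m + 1000
    while done < target and tries < max_tries:
        tries += 1
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        (a1, l1), (a2, l2) = edge_list[i], edge_list[j]
        if a1 == a2 or l1 == l2:
            continue
        e1, e2 = (a1, l2), (a2, l1)
        if e1 in edge_set or e2 in edge_set:
            continue
        edge_set.discard(edge_list[i])
        edge_set.discard(edge_list[j])
        edge_set.add(e1)
        edge_set.add(e2)
        edge_list[i], edge_list[j] = e1, e2
        done += 1
    return edge_set


def _randomize_layers(
    index: NetIndex, scheme: RandomizationScheme, rng: np.random.Generator
) -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
    """Randomized (social_edges, membership_edges) under ``scheme``."""
    social = {
        (a, b) for a in index.social for b in index.social[a] if a < b
    }
    if scheme.social_mode == "fixed_count_shuffle":
        social = _shuffle_social(index.actors, len(social), rng)
    elif scheme.social_mode == "degree_preserving_swap":
        social = _swap_social(social, rng)
    mem = {(a, l) for a in index.lakes_of for l in index.lakes_of[a]}
    if scheme.membership_mode == "actor_degree_preserving":
        mem = _shuffle_membership_actor(index.lakes_of, index.ecos, rng)
    elif scheme.membership_mode == "both_degrees_preserving":
        mem = _swap_membership_both(mem, rng)
    return social, mem


def randomize(net: SESNetwork, scheme: RandomizationScheme, seed: int) -> SESNetwork:
    """One randomized replicate: same nodes and eco layer, reshuffled ties."""
    rng = np.random.default_rng(seed)
    index = NetIndex.from_network(net)
    social, mem = _randomize_layers(index, scheme, rng)
    return SESNetwork(
        actors=dict(net.actors),
        ecos=dict(net.ecos),
        social_edges=social,
        eco_edges=set(net.eco_edges),
        membership_edges=mem,
        eco_edge_annotations=dict(net.eco_edge_annotations),
    )


@dataclass(frozen=True)
class BlockNull:
    block_id: str
    observed: int
    null_mean: float
    null_sd: float
    p_upper: float
    p_lower: float
    code: str
    null_counts: tuple[int, ...] | None = None


@dataclass
class NullDistribution:
    blocks: dict[str, BlockNull]
    scheme: RandomizationScheme
    R: int
    seed: int
    method: str = "empirical"

    def code(self, block_id: str) -> str:
        return self.blocks[block_id].code

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "block_id": b.block_id,
                "observed": b.observed,
                "null_mean": b.null_mean,
                "null_sd": b.null_sd,
                "p_upper": b.p_upper,
                "p_lower": b.p_lower,
                "code": b.code,
            }
            for b in (self.blocks[k] for k in sorted(self.blocks))
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def null_matrix(self) -> pd.DataFrame:
        cols = {
            bid: b.null_counts
            for bid, b in sorted(self.blocks.items())
            if b.null_counts is not None
        }
        return pd.DataFrame(cols)

    def manifest(self, net: SESNetwork | None = None) -> dict:
        out = {
            "scheme": {
                "social_mode": self.scheme.social_mode,
                "membership_mode": self.scheme.membership_mode,
                "eco_mode": self.scheme.eco_mode,
            },
            "R": self.R,
            "seed": self.seed,
            "method": self.method,
        }
        if net is not None:
            digest = hashlib.sha256(
                json.dumps(
                    {
                        "actors": sorted(net.actors),
                        "ecos": sorted(net.ecos),
                        "social": sorted(net.social_edges),
                        "eco": sorted(net.eco_edges),
                        "membership": sorted(net.membership_edges),
                    }
                ).encode()
            ).hexdigest()
            out["input_digest"] = digest
        return out


def significance_code(
    p_upper: float, p_lower: float, strong: float = STRONG, weak: float = WEAK
) -> str:
    """Signed code from two one-sided p-values; over-representation first."""
    if p_upper < strong:
        return "++"
    if p_upper < weak:
        return "+"
    if p_lower < strong:
        return "--"
    if p_lower < weak:
        return "-"
    return "0"


def _normal_sf(z: float) -> float:
    return 0.5 * math.erfc(z / math.sqrt(2.0))


def null_distribution(
    net: SESNetwork,
    catalog: BlockCatalog,
    scheme: RandomizationScheme | None = None,
    R: int = 1000,
    seed: int = 0,
    blocks: Iterable[str] | None = None,
    keep_null_counts: bool = True,
    method: str = "empirical",
    strong: float = STRONG,
    weak: float = WEAK,
) -> NullDistribution:
    """Observed vs. R randomized replicates, per block.

    Replicate seeds are drawn from a generator seeded with ``seed``, and
    each replicate is censused with the same engine as the observed
    network, so the whole object is reproducible bit-for-bit. Restricting
    ``blocks`` skips needless enumeration when only some blocks matter.
    ``method="zscore"`` replaces the empirical p's with a normal
    approximation from the null mean and sd.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if method not in ("empirical", "zscore"):
        raise ValueError(f"unknown method {method!r}")
    scheme = scheme or RandomizationScheme()
    index = NetIndex.from_network(net)
    wanted = list(blocks) if blocks is not None else [b.block_id for b in catalog]
    observed = census(index, catalog, blocks=wanted).counts

    rng_master = np.random.default_rng(seed)
    rep_seeds = rng_master.integers(0, 2**31 - 1, size=R)
    null_counts: dict[str, list[int]] = {bid: [] for bid in wanted}
    for s in rep_seeds:
        rng = np.random.default_rng(int(s))
        social, mem = _randomize_layers(index, scheme, rng)
        rep_index = NetIndex(
            index.actors,
            index.ecos,
            social,
            [(u, v) for u in index.eco_adj for v in index.eco_adj[u] if u < v],
            mem,
        )
        rep_counts = census(rep_index, catalog, blocks=wanted).counts
        for bid in wanted:
            null_counts[bid].append(rep_counts[bid])

    out: dict[str, BlockNull] = {}
    for bid in wanted:
        arr = np.asarray(null_counts[bid])
        obs = observed[bid]
        if method == "empirical":
            p_up = (1 + int((arr >= obs).sum())) / (R + 1)
            p_lo = (1 + int((arr <= obs).sum())) / (R + 1)
        else:
            sd = float(arr.std(ddof=1)) if R > 1 else 0.0
            if sd == 0.0:
                p_up = 1.0 if obs <= arr.mean() else 0.0
                p_lo = 1.0 if obs >= arr.mean() else 0.0
            else:
                z = (obs - float(arr.mean())) / sd
                p_up = _normal_sf(z)
                p_lo = _normal_sf(-z)
        out[bid] = BlockNull(
            block_id=bid,
            observed=obs,
            null_mean=float(arr.mean()),
            null_sd=float(arr.std(ddof=1)) if R > 1 else 0.0,
            p_upper=p_up,
            p_lower=p_lo,
            code=significance_code(p_up, p_lo, strong, weak),
            null_counts=tuple(int(x) for x in arr) if keep_null_counts else None,
        )
    return NullDistribution(blocks=out, scheme=scheme, R=R, seed=seed, method=method)
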