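"""Preliminary complex-core mining by structural similarity.

Core proteins of a complex share many common neighbors.  Around every seed
vertex v the closed neighborhoods

    SN(v) = {v} ∪ N(v)

are compared by the cosine-style structural similarity

    SS(v, w) = |SN(v) ∩ SN(w)| / sqrt(|SN(v)| · |SN(w)|),

and the neighbors w of v with SS(v, w) ≥ ss (a user threshold, default 0.4)
join the seed to form a preliminary core Core(PC_v).  Similarity is purely
topological — computed on the reliability-filtered network but without its
edge weights.  Cores of size < 2 are dropped and identical member sets from
different seeds are collapsed, keeping the lexicographically first seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import FrozenSet, List, Set, Tuple

from .network import Edge, WeightedNetwork, edge_key


@dataclass(frozen=True)
class ComplexCore:
    """Seed vertex plus its structurally similar neighbors (V_core, E_core)."""

    seed: str
    members: FrozenSet[str]
    core_edges: FrozenSet[Edge]

    def __post_init__(self) -> None:
        if self.seed not in self.members:
            raise ValueError("seed must be a core member")


def structural_neighborhood(wnet: WeightedNetwork, v: str) -> Set[str]:
    """Closed neighborhood {v} ∪ N(v) in the filtered network."""
    return {v} | wnet.neighbors(v)


def structural_similarity(wnet: WeightedNetwork, v: str, w: str) -> float:
    """Closed-common-neighborhood count over the geometric mean of sizes."""
    sn_v = structural_neighborhood(wnet, v)
    sn_w = structural_neighborhood(wnet, w)
    return len(sn_v & sn_w) / math.sqrt(len(sn_v) * len(sn_w))


def _induced_edges(wnet: WeightedNetwork, members: FrozenSet[str]) -> FrozenSet[Edge]:
    return frozenset(
        edge_key(u, v)
        for u in members
        for v in wnet.neighbors(u)
        if v in members and u < v
    )


def detect_cores(wnet: WeightedNetwork, ss: float = 0.4) -> List[ComplexCore]:
    """Mine one candidate core per seed vertex; filter and deduplicate.

    Seeds are visited in lexicographic order so deduplication tie-breaking
    is deterministic.  Raising ``ss`` can only shrink each seed's core
    (member sets are nested across thresholds).
    """
    if not (0 < ss <= 1):
        raise ValueError(f"ss must lie in (0, 1], got {ss}")
    cores: List[ComplexCore] = []
    seen: Set[FrozenSet[str]] = set()
    for v in sorted(wnet.vertices):
        members = frozenset(
            {v} | {w for w in wnet.neighbors(v) if structural_similarity(wnet, v, w) >= ss}
        )
        if len(members) < 2 or members in seen:
            continue
        seen.add(members)
        cores.append(
            ComplexCore(seed=v, members=members, core_edges=_induced_edges(wnet, members))
        )
    return cores
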