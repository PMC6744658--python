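"""Graph containers for PPI networks and complex sets.

A protein–protein interaction (PPI) network is an undirected graph whose
vertices are opaque protein identifiers.  Edges may carry an externally
supplied confidence weight in (0, 1]; the detection pipeline ignores such
weights (it computes its own reliability scores) but they are preserved for
round-tripping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Set, Tuple

import networkx as nx

Edge = Tuple[str, str]


def edge_key(u: str, v: str) -> Edge:
    """Canonical unordered representation of an edge."""
    return (u, v) if u <= v else (v, u)


class PPINetwork:
    """Undirected PPI network over opaque string identifiers.

    Self-loops are rejected; (u, v) and (v, u) denote the same edge.
    """

    def __init__(
        self,
        vertices: Iterable[str] = (),
        edges: Iterable[Edge] = (),
        edge_weight: Optional[Dict[Edge, float]] = None,
    ) -> None:
        g = nx.Graph()
        g.add_nodes_from(vertices)
        for u, v in edges:
            if u == v:
                raise ValueError(f"self-loop on vertex {u!r}")
            g.add_edge(u, v)
        self._g = g
        self.edge_weight: Dict[Edge, float] = {}
        if edge_weight:
            for (u, v), w in edge_weight.items():
                if not g.has_edge(u, v):
                    raise ValueError(f"weight given for non-edge ({u!r}, {v!r})")
                if not (w > 0):
                    raise ValueError(f"edge weight must be finite and > 0, got {w}")
                self.edge_weight[edge_key(u, v)] = float(w)

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def vertices(self) -> Set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> Set[Edge]:
        return {edge_key(u, v) for u, v in self._g.edges}

    def n_vertices(self) -> int:
        return self._g.number_of_nodes()

    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def has_vertex(self, v: str) -> bool:
        return self._g.has_node(v)

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def neighbors(self, v: str) -> Set[str]:
        """Open neighborhood N(v)."""
        if not self._g.has_node(v):
            raise KeyError(f"unknown vertex {v!r}")
        return set(self._g.neighbors(v))

    def __contains__(self, v: str) -> bool:
        return self._g.has_node(v)

    def __repr__(self) -> str:
        return f"PPINetwork({self.n_vertices()} vertices, {self.n_edges()} edges)"


class WeightedNetwork:
    """HOCN-weighted network: the reliability-filtered view of a PPINetwork.

    ``hocn`` maps each *retained* edge to its weight in (0, 1].  Edges whose
    endpoints share no common neighbor in the base network are absent (they
    were judged unreliable and discarded).  The vertex set is that of the
    base network; vertices isolated by filtering remain.
    """

    def __init__(self, base: PPINetwork, hocn: Dict[Edge, float]) -> None:
        self.base = base
        self.hocn = {edge_key(u, v): w for (u, v), w in hocn.items()}
        g = nx.Graph()
        g.add_nodes_from(base.graph.nodes)
        for (u, v), w in self.hocn.items():
            g.add_edge(u, v, weight=w)
        self._g = g

    @property
    def graph(self) -> nx.Graph:
        return self._g

    @property
    def vertices(self) -> Set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> Set[Edge]:
        return set(self.hocn)

    def neighbors(self, v: str) -> Set[str]:
        """Open neighborhood in the filtered network."""
        if not self._g.has_node(v):
            raise KeyError(f"unknown vertex {v!r}")
        return set(self._g.neighbors(v))

    def weight(self, u: str, v: str) -> float:
        return self.hocn[edge_key(u, v)]

    def __repr__(self) -> str:
        return (
            f"WeightedNetwork({self._g.number_of_nodes()} vertices, "
            f"{len(self.hocn)} retained edges)"
        )


@dataclass
class ComplexSet:
    """Ordered list of complexes, each a set of member identifiers.

    ``roles`` optionally carries, per complex, a member → role mapping with
    roles in {"core", "peripheral", "overlapping"} (attached by the
    assembly stage; plain readers leave it None).
    """

    complexes: List[FrozenSet[str]] = field(default_factory=list)
    labels: Optional[List[str]] = None
    roles: Optional[List[Dict[str, str]]] = None

    def __post_init__(self) -> None:
        self.complexes = [frozenset(c) for c in self.complexes]
        for i, c in enumerate(self.complexes):
            if len(c) < 1:
                raise ValueError(f"complex {i} is empty")

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)

    def __getitem__(self, i: int) -> FrozenSet[str]:
        return self.complexes[i]
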