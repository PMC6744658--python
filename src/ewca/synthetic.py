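"""Synthetic networks: a small hand-worked fixture and a planted generator.

The generator emulates what the method assumes about real interactomes:
complexes are dense cores that are sparsely connected to the rest of the
network, with two flavours of attachment protein — peripheral (bound to one
complex) and overlapping (shared between complexes) — plus background
vertices and uniform noise edges standing in for false-positive
interactions.  Ground truth is returned alongside the network so the full
pipeline can be scored without external reference sets.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Set, Tuple

from .network import ComplexSet, PPINetwork, edge_key


def example_network() -> PPINetwork:
    """The 11-protein hand-worked network used to illustrate edge weighting.

    Fourteen of its fifteen interactions are uniquely reconstructible from
    the neighbor sets printed in the worked reliability example:
    a-b, a-d, a-h, a-r, b-c, b-d, b-k, b-s, c-d, c-e, c-k, d-e, d-f, d-g.
    The fifteenth edge lies somewhere among {e,f,g,h,k,r,s} and is
    deliberately omitted rather than guessed: no quantity in the worked
    example involves the neighborhood of those vertices, so its absence
    cannot change any illustrated value.
    """
    edges = [
        ("a", "b"), ("a", "d"), ("a", "h"), ("a", "r"),
        ("b", "c"), ("b", "d"), ("b", "k"), ("b", "s"),
        ("c", "d"), ("c", "e"), ("c", "k"),
        ("d", "e"), ("d", "f"), ("d", "g"),
    ]
    vertices = {v for e in edges for v in e}
    assert len(vertices) == 11 and len(edges) == 14
    return PPINetwork(vertices=vertices, edges=edges)


@dataclass
class PlantedTruth:
    """Ground truth of a generated network.

    ``complexes`` holds one (core, peripheral, overlapping) triple per
    planted complex; cores are vertex-disjoint, each overlapping protein is
    listed in at least two triples.
    """

    complexes: List[Tuple[FrozenSet[str], FrozenSet[str], FrozenSet[str]]]
    noise_edges: int
    rng_seed: int

    def reference_set(self) -> ComplexSet:
        """Full planted complexes (core ∪ peripheral ∪ overlapping)."""
        return ComplexSet(
            complexes=[core | peri | over for core, peri, over in self.complexes]
        )

    def overlapping_proteins(self) -> Set[str]:
        out: Set[str] = set()
        for _, _, over in self.complexes:
            out |= over
        return out


def generate_planted(
    n_complexes: int = 5,
    core_size_range: Tuple[int, int] = (4, 8),
    p_core: float = 0.9,
    n_peripheral: int = 2,
    n_overlap: int = 3,
    n_background: int = 10,
    p_noise: float = 0.02,
    seed: int = 42,
) -> Tuple[PPINetwork, PlantedTruth]:
    """Build a network of dense planted cores with attachment fringes.

    Parameters
    ----------
    n_complexes : number of vertex-disjoint planted complexes.
    core_size_range : inclusive (low, high) bounds on core sizes.
    p_core : probability of each within-core edge (cores are additionally
        forced connected so a sampled core cannot fall apart).
    n_peripheral : peripheral proteins attached to each complex; each binds
        2–3 mutually adjacent members of exactly one core.
    n_overlap : overlapping proteins; each binds roughly 60% of the members
        of each of two distinct host cores, so that its attachment to either
        complex is substantial while its weight is pulled outward by the
        other — the signature the classifier keys on.
    n_background : free vertices participating only in noise edges.
    p_noise : probability of a spurious edge between any vertex pair not
        inside the same core.
    seed : seed of the single pseudo-random stream; identical seeds give
        identical networks.
    """
    lo, hi = core_size_range
    if lo < 3:
        raise ValueError("core sizes must be ≥ 3")
    if not (0 <= p_core <= 1 and 0 <= p_noise <= 1):
        raise ValueError("probabilities must lie in [0, 1]")
    if n_overlap > 0 and n_complexes < 2:
        raise ValueError("overlapping proteins need at least two complexes")
    rng = random.Random(seed)

    edges: Set[Tuple[str, str]] = set()
    cores: List[List[str]] = []

    def add_edge(u: str, v: str) -> None:
        if u != v:
            edges.add(edge_key(u, v))

    # Dense, connected planted cores.
    for i in range(n_complexes):
        k = rng.randint(lo, hi)
        members = [f"c{i}_{j}" for j in range(k)]
        cores.append(members)
        for a in range(k):
            for b in range(a + 1, k):
                if rng.random() < p_core:
                    add_edge(members[a], members[b])
        # splice components together if the Bernoulli draw disconnected the core
        comp = {m: m for m in members}

        def find(x: str) -> str:
            while comp[x] != x:
                comp[x] = comp[comp[x]]
                x = comp[x]
            return x

        for u, v in sorted(edges):
            if u in comp and v in comp:
                comp[find(u)] = find(v)
        roots = sorted({find(m) for m in members})
        for a, b in zip(roots, roots[1:]):
            add_edge(a, b)

    # Peripheral proteins: bound to one core via 2-3 mutually adjacent members.
    peripheral: List[List[str]] = [[] for _ in range(n_complexes)]
    for i, members in enumerate(cores):
        core_edges = sorted(e for e in edges if e[0] in members and e[1] in members)
        for j in range(n_peripheral):
            p = f"p{i}_{j}"
            peripheral[i].append(p)
            t1, t2 = rng.choice(core_edges)
            anchors = {t1, t2}
            if rng.random() < 0.5:
                extra = [m for m in members if m not in anchors]
                if extra:
                    anchors.add(rng.choice(extra))
            for t in sorted(anchors):
                add_edge(p, t)

    # Overlapping proteins: substantial attachment to two host cores.
    overlap_hosts: List[Tuple[str, Tuple[int, int]]] = []
    for j in range(n_overlap):
        o = f"o{j}"
        i1, i2 = rng.sample(range(n_complexes), 2)
        overlap_hosts.append((o, (i1, i2)))
        for i in (i1, i2):
            members = cores[i]
            m = max(2, math.ceil(0.6 * len(members)))
            for t in rng.sample(members, m):
                add_edge(o, t)

    background = [f"bg{j}" for j in range(n_background)]

    all_vertices = (
        [m for c in cores for m in c]
        + [p for ps in peripheral for p in ps]
        + [o for o, _ in overlap_hosts]
        + background
    )

    # Uniform noise edges between pairs not inside the same core.
    core_of: Dict[str, int] = {m: i for i, c in enumerate(cores) for m in c}
    n_noise = 0
    for a in range(len(all_vertices)):
        for b in range(a + 1, len(all_vertices)):
            u, v = all_vertices[a], all_vertices[b]
            if core_of.get(u, -1) == core_of.get(v, -2):
                continue
            if edge_key(u, v) in edges:
                continue
            if rng.random() < p_noise:
                add_edge(u, v)
                n_noise += 1

    net = PPINetwork(vertices=all_vertices, edges=edges)
    truth_complexes = []
    for i in range(n_complexes):
        over = frozenset(o for o, hosts in overlap_hosts if i in hosts)
        truth_complexes.append(
            (frozenset(cores[i]), frozenset(peripheral[i]), over)
        )
    truth = PlantedTruth(
        complexes=truth_complexes, noise_edges=n_noise, rng_seed=seed
    )
    return net, truth
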