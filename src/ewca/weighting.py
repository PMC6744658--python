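"""Interaction-reliability weighting by high-order common neighbors (HOCN).

High-throughput PPI data are noisy; edges whose endpoints share no network
context are likely false positives.  Each edge (v, u) is scored by combining
the Jaccard coefficient of the endpoint neighborhoods with the support its
common neighbors lend through their own Jaccard similarity to both ends:

    JCS(v, u)  = |CN(v, u)| / |N(v) ∪ N(u)|      if |CN(v, u)| ≥ 1, else 0
    CNS(v, u)  = Σ_{w ∈ CN(v, u)} JCS(v, w) · JCS(w, u)
    HOCN(v, u) = (JCS(v, u) + CNS(v, u)) / (|CN(v, u)| + 1)

where CN(v, u) = N(v) ∩ N(u).  An edge whose endpoints share no common
neighbor is judged unreliable and discarded.  All quantities are computed
from the ORIGINAL neighborhoods in a single pass; discarding does not
cascade.
"""

from __future__ import annotations

from typing import Dict, Optional

from .network import Edge, PPINetwork, WeightedNetwork, edge_key


def jaccard_coefficient(net: PPINetwork, v: str, u: str) -> float:
    """Jaccard coefficient of the open neighborhoods of v and u.

    Defined for any vertex pair, adjacent or not (the common-neighbor
    support sum needs it for non-adjacent pairs).  When the two are
    adjacent, each endpoint sits in the other's neighbor set and hence in
    the union.  Returns 0 when the neighborhoods are disjoint.
    """
    if v == u:
        raise ValueError("jaccard_coefficient requires two distinct vertices")
    nv = net.neighbors(v)
    nu = net.neighbors(u)
    cn = nv & nu
    if not cn:
        return 0.0
    return len(cn) / len(nv | nu)


def common_neighbor_support(net: PPINetwork, v: str, u: str) -> float:
    """Σ over common neighbors w of JCS(v, w) · JCS(w, u); 0 if none."""
    cn = net.neighbors(v) & net.neighbors(u)
    return sum(
        jaccard_coefficient(net, v, w) * jaccard_coefficient(net, w, u) for w in cn
    )


def hocn_weight(net: PPINetwork, v: str, u: str) -> Optional[float]:
    """HOCN reliability weight of the edge (v, u).

    Returns None when the endpoints share no common neighbor, signalling
    that the edge is to be discarded as unreliable.
    """
    if not net.has_edge(v, u):
        raise ValueError(f"({v!r}, {u!r}) is not an edge of the network")
    cn = net.neighbors(v) & net.neighbors(u)
    if not cn:
        return None
    jcs = jaccard_coefficient(net, v, u)
    cns = common_neighbor_support(net, v, u)
    return (jcs + cns) / (len(cn) + 1)


def weight_network(net: PPINetwork) -> WeightedNetwork:
    """Score every edge and drop those without a common neighbor.

    The vertex set is preserved: vertices isolated by the filtering remain
    in the weighted network and simply never enter any complex.
    """
    hocn: Dict[Edge, float] = {}
    for u, v in net.edges:
        w = hocn_weight(net, u, v)
        if w is not None:
            hocn[edge_key(u, v)] = w
    return WeightedNetwork(base=net, hocn=hocn)
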