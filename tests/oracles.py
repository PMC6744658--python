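"""Independent brute-force reference implementations used only by tests.

Everything here works on plain edge lists / member-set lists with naive
loops and exact set arithmetic, deliberately sharing no code with the
package under test.
"""

from __future__ import annotations

import math
from fractions import Fraction
from itertools import combinations
from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

Edge = Tuple[str, str]


def nbrs(edges: Set[Edge], v: str) -> Set[str]:
    out = set()
    for a, b in edges:
        if a == v:
            out.add(b)
        elif b == v:
            out.add(a)
    return out


def jcs(edges: Set[Edge], v: str, u: str) -> float:
    nv, nu = nbrs(edges, v), nbrs(edges, u)
    if not (nv & nu):
        return 0.0
    return len(nv & nu) / len(nv | nu)


def hocn(edges: Set[Edge], v: str, u: str):
    cn = nbrs(edges, v) & nbrs(edges, u)
    if not cn:
        return None
    s = 0.0
    for w in cn:
        s += jcs(edges, v, w) * jcs(edges, w, u)
    return (jcs(edges, v, u) + s) / (len(cn) + 1)


def weighted_edges(edges: Set[Edge]) -> Dict[Edge, float]:
    out = {}
    for a, b in edges:
        w = hocn(edges, a, b)
        if w is not None:
            out[(min(a, b), max(a, b))] = w
    return out


def structural_similarity(retained: Set[Edge], v: str, w: str) -> float:
    sn_v = {v} | nbrs(retained, v)
    sn_w = {w} | nbrs(retained, w)
    return len(sn_v & sn_w) / math.sqrt(len(sn_v) * len(sn_w))


def candidate_attachments(retained: Set[Edge], vertices: Set[str],
                          core: Set[str]) -> Set[str]:
    return {
        p for p in vertices - core
        if len(nbrs(retained, p) & core) >= 2
    }


def classify(weights: Dict[Edge, float], core: Set[str],
             cap: Set[str]) -> Tuple[Set[str], Set[str]]:
    """(overlapping, peripheral) by direct evaluation of the conditions."""
    def w(a, b):
        return weights.get((min(a, b), max(a, b)), 0.0)

    core_total = math.fsum(
        w(a, b) for a, b in combinations(sorted(core), 2)
        if (min(a, b), max(a, b)) in weights
    )
    weight_avg = 2 * core_total / len(core)
    win = {}
    wout = {}
    for p in cap:
        win[p] = math.fsum(w(p, t) for t in core)
        wout[p] = math.fsum(
            v for (a, b), v in weights.items()
            if (a == p and b not in core) or (b == p and a not in core)
        )
    overlapping = {
        p for p in cap if wout[p] >= win[p] and win[p] >= 0.5 * weight_avg
    }
    cp = cap - overlapping
    peripheral = set()
    if cp:
        cp_avg = math.fsum(win[p] for p in cp) / len(cp)
        peripheral = {p for p in cp if win[p] > wout[p] and win[p] >= cp_avg}
    return overlapping, peripheral


def na(p: Set[str], r: Set[str]) -> float:
    return len(p & r) ** 2 / (len(p) * len(r))


def recall_precision_f(pred: Sequence[Set[str]], ref: Sequence[Set[str]],
                       t: float) -> Tuple[float, float, float]:
    n_mr = sum(1 for r in ref if any(na(set(p), set(r)) >= t for p in pred))
    n_mp = sum(1 for p in pred if any(na(set(p), set(r)) >= t for r in ref))
    recall = n_mr / len(ref) if ref else 0.0
    precision = n_mp / len(pred) if pred else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return recall, precision, f


def coverage_rate(pred: Sequence[Set[str]], ref: Sequence[Set[str]]) -> float:
    num = sum(max((len(set(r) & set(p)) for p in pred), default=0) for r in ref)
    return num / sum(len(r) for r in ref)


def mmr_exhaustive(pred: Sequence[Set[str]], ref: Sequence[Set[str]],
                   threshold: float = 0.0) -> float:
    """Maximum-weight matching by explicit recursion over all matchings."""
    weights = [
        [v if (v := na(set(r), set(p))) > threshold else 0.0 for p in pred]
        for r in ref
    ]

    def best(i: int, used: FrozenSet[int]) -> float:
        if i == len(ref):
            return 0.0
        skip = best(i + 1, used)
        take = 0.0
        for j in range(len(pred)):
            if j not in used and weights[i][j] > 0:
                take = max(take, weights[i][j] + best(i + 1, used | {j}))
        return max(skip, take)

    return best(0, frozenset()) / len(ref)


def hypergeom_upper_tail_exact(N: int, C: int, F: int, m: int) -> Fraction:
    """P(X >= m) by exact rational arithmetic over the hypergeometric pmf."""
    total = math.comb(N, C)
    s = Fraction(0)
    for i in range(m, min(C, F) + 1):
        s += Fraction(math.comb(F, i) * math.comb(N - F, C - i), total)
    return s
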