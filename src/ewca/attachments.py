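"""Attachment-protein detection: overlapping vs peripheral classification.

A candidate attachment protein for a core is any outside vertex with at
least two weighted-network neighbors inside the core.  Candidates are then
split by how their edge weight distributes relative to the core:

overlapping (shared between complexes):
    weight_out(p) ≥ weight_in(p)                  — pulled outward at least
                                                    as strongly as inward
    weight_in(p) ≥ ½ · weight_avg(Core)           — still substantially tied
                                                    to the core, where
    weight_avg(Core) = 2 Σ_{(v,u)∈E_core} w(v,u) / |V_core| is the average
    weighted degree inside the core.

peripheral (specific to this complex), tested on CP = CAP − Overlapping:
    weight_in(p) > weight_out(p)                  — strictly inward-bound
    weight_in(p) ≥ mean of weight_in over CP      — among the better-attached
                                                    candidates.

Classification is per-core and independent: the same protein may be an
attachment of several cores.  All comparisons are scale-covariant in the
edge weights and the out/in tie goes to overlapping (the peripheral test
is strict).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import FrozenSet, Set, Tuple

from .cores import ComplexCore
from .network import WeightedNetwork


@dataclass(frozen=True)
class AttachmentResult:
    """Candidate set and its overlapping/peripheral split for one core."""

    core: ComplexCore
    candidates: FrozenSet[str]
    overlapping: FrozenSet[str]
    peripheral: FrozenSet[str]

    @property
    def attachment(self) -> FrozenSet[str]:
        return self.overlapping | self.peripheral


def candidate_attachments(wnet: WeightedNetwork, core: ComplexCore) -> Set[str]:
    """Vertices outside the core with ≥ 2 neighbors inside it."""
    members = core.members
    cap: Set[str] = set()
    neighborhood: Set[str] = set()
    for m in members:
        neighborhood |= wnet.neighbors(m)
    for p in neighborhood - members:
        if len(wnet.neighbors(p) & members) >= 2:
            cap.add(p)
    return cap


def core_weight_stats(wnet: WeightedNetwork, core: ComplexCore) -> float:
    """Average weighted degree inside the core: 2·Σ w(E_core) / |V_core|."""
    total = math.fsum(wnet.weight(u, v) for u, v in core.core_edges)
    return 2.0 * total / len(core.members)


def in_out_weights(
    wnet: WeightedNetwork, p: str, core: ComplexCore
) -> Tuple[float, float]:
    """Total edge weight of p into the core vs to everything outside it."""
    if p in core.members:
        raise ValueError(f"{p!r} is a core member")
    nbrs = wnet.neighbors(p)
    w_in = math.fsum(wnet.weight(p, q) for q in nbrs if q in core.members)
    w_out = math.fsum(wnet.weight(p, q) for q in nbrs if q not in core.members)
    return w_in, w_out


def classify_overlapping(
    wnet: WeightedNetwork, core: ComplexCore, cap: Set[str]
) -> Set[str]:
    half_avg = 0.5 * core_weight_stats(wnet, core)
    out = set()
    for p in cap:
        w_in, w_out = in_out_weights(wnet, p, core)
        if w_out >= w_in and w_in >= half_avg:
            out.add(p)
    return out


def classify_peripheral(
    wnet: WeightedNetwork, core: ComplexCore, cap: Set[str], overlapping: Set[str]
) -> Set[str]:
    cp = cap - overlapping
    if not cp:
        return set()
    w_ins = {p: in_out_weights(wnet, p, core) for p in cp}
    cp_avg = math.fsum(w for w, _ in w_ins.values()) / len(cp)
    return {p for p, (w_in, w_out) in w_ins.items() if w_in > w_out and w_in >= cp_avg}


def attach(wnet: WeightedNetwork, core: ComplexCore) -> AttachmentResult:
    """Build the candidate set and classify it for one core."""
    cap = candidate_attachments(wnet, core)
    overlapping = classify_overlapping(wnet, core, cap)
    peripheral = classify_peripheral(wnet, core, cap, overlapping)
    return AttachmentResult(
        core=core,
        candidates=frozenset(cap),
        overlapping=frozenset(overlapping),
        peripheral=frozenset(peripheral),
    )
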