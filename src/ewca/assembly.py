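"""Final complex formation: core ∪ attachment, size filter, dedup.

Each predicted complex is the union of a preliminary core and its
attachment proteins.  Complexes with fewer than 3 members are discarded
(pairs are not meaningful complexes) and complexes whose member sets are
identical — different seeds can converge on the same set — are collapsed
to the first in input order.  Proper subsets are NOT removed: keeping
genuinely overlapping complexes is the point of the method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List

from .attachments import AttachmentResult
from .network import ComplexSet


@dataclass(frozen=True)
class PredictedComplex:
    """A complex with per-member roles; the three role sets are disjoint."""

    members: FrozenSet[str]
    core_members: FrozenSet[str]
    peripheral_members: FrozenSet[str]
    overlapping_members: FrozenSet[str]

    def __post_init__(self) -> None:
        if self.members != self.core_members | self.peripheral_members | self.overlapping_members:
            raise ValueError("members must be the union of the three role sets")

    def role_map(self) -> Dict[str, str]:
        roles = {m: "core" for m in self.core_members}
        roles.update({m: "peripheral" for m in self.peripheral_members})
        roles.update({m: "overlapping" for m in self.overlapping_members})
        return roles


def assemble(
    cores_with_attachments: List[AttachmentResult], min_size: int = 3
) -> List[PredictedComplex]:
    """Form final complexes, drop those below ``min_size``, deduplicate."""
    out: List[PredictedComplex] = []
    seen: set = set()
    for res in cores_with_attachments:
        members = res.core.members | res.attachment
        if len(members) < min_size or members in seen:
            continue
        seen.add(members)
        out.append(
            PredictedComplex(
                members=members,
                core_members=res.core.members,
                peripheral_members=res.peripheral,
                overlapping_members=res.overlapping,
            )
        )
    return out


def to_complex_set(predicted: List[PredictedComplex]) -> ComplexSet:
    """Package predictions for writing, carrying member roles along."""
    return ComplexSet(
        complexes=[pc.members for pc in predicted],
        roles=[pc.role_map() for pc in predicted],
    )
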