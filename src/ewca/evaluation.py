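"""Evaluation metrics for predicted complex sets, plus enrichment p-values.

Predicted complexes P are compared against a reference set R through the
neighborhood affinity

    NA(p, r) = |p ∩ r|² / (|p| · |r|),

with p and r matched when NA ≥ t (t = 0.2 by convention).  From the match
counts come recall (matched references / |R|), precision (matched
predictions / |P|) and their harmonic mean, the F-measure.  Two further
metrics are match-free: the coverage rate CR (summed best per-reference
overlaps over total reference protein count) and the maximum matching
ratio MMR (total NA weight of a maximum-weight one-to-one matching between
R and P, divided by |R|).

Functional enrichment of a single complex uses the hypergeometric upper
tail: the probability of drawing ≥ m annotated proteins in a complex of
size C from a universe of N proteins of which F carry the annotation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Sequence, Set, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.stats import hypergeom

from .network import ComplexSet

log = logging.getLogger(__name__)

MemberSets = Sequence[FrozenSet[str]]


@dataclass
class EvaluationReport:
    recall: float
    precision: float
    f_measure: float
    coverage_rate: float
    mmr: float
    na_threshold: float

    def summary(self) -> str:
        return (
            f"recall    {self.recall:8.4f}\n"
            f"precision {self.precision:8.4f}\n"
            f"F-measure {self.f_measure:8.4f}\n"
            f"CR        {self.coverage_rate:8.4f}\n"
            f"MMR       {self.mmr:8.4f}\n"
            f"(match threshold t = {self.na_threshold})"
        )


def neighborhood_affinity(p: Iterable[str], r: Iterable[str]) -> float:
    """Squared overlap over the product of sizes; 1 iff the sets coincide."""
    p, r = set(p), set(r)
    if not p or not r:
        raise ValueError("neighborhood affinity requires two non-empty sets")
    return len(p & r) ** 2 / (len(p) * len(r))


def recall_precision_f(
    pred: ComplexSet, ref: ComplexSet, t: float = 0.2
) -> Tuple[float, float, float]:
    """Match-count recall, precision and F-measure at NA threshold t."""
    if not (0 < t <= 1):
        raise ValueError(f"t must lie in (0, 1], got {t}")
    if len(pred) == 0 or len(ref) == 0:
        log.warning("empty prediction or reference set; metrics default to 0")
    n_mr = sum(
        1
        for r in ref
        if any(neighborhood_affinity(r, p) >= t for p in pred)
    )
    n_mp = sum(
        1
        for p in pred
        if any(neighborhood_affinity(p, r) >= t for r in ref)
    )
    recall = n_mr / len(ref) if len(ref) else 0.0
    precision = n_mp / len(pred) if len(pred) else 0.0
    denom = precision + recall
    f = 2 * precision * recall / denom if denom > 0 else 0.0
    return recall, precision, f


def coverage_rate(pred: ComplexSet, ref: ComplexSet) -> float:
    """Σ_i max_j |r_i ∩ p_j|  /  Σ_i |r_i|."""
    if len(ref) == 0:
        raise ValueError("coverage rate needs a non-empty reference set")
    covered = sum(
        max((len(r & p) for p in pred), default=0) for r in ref
    )
    return covered / sum(len(r) for r in ref)


def maximum_matching_ratio(
    pred: ComplexSet, ref: ComplexSet, threshold: float = 0.0
) -> float:
    """Maximum-weight one-to-one matching of NA scores, normalized by |R|.

    Entries with NA ≤ threshold carry no edge (default 0: all positive
    affinities participate).  Solved as a rectangular assignment problem;
    the matched total weight is unique even where the matching is not.
    """
    if len(ref) == 0:
        raise ValueError("MMR needs a non-empty reference set")
    if len(pred) == 0:
        return 0.0
    na = np.zeros((len(ref), len(pred)))
    for i, r in enumerate(ref):
        for j, p in enumerate(pred):
            v = neighborhood_affinity(r, p)
            if v > threshold:
                na[i, j] = v
    rows, cols = linear_sum_assignment(na, maximize=True)
    return float(na[rows, cols].sum()) / len(ref)


def evaluate(
    pred: ComplexSet,
    ref: ComplexSet,
    t: float = 0.2,
    mmr_threshold: float = 0.0,
) -> EvaluationReport:
    """Compute the full metric panel for a predicted set vs a reference."""
    recall, precision, f = recall_precision_f(pred, ref, t)
    return EvaluationReport(
        recall=recall,
        precision=precision,
        f_measure=f,
        coverage_rate=coverage_rate(pred, ref),
        mmr=maximum_matching_ratio(pred, ref, mmr_threshold),
        na_threshold=t,
    )


@dataclass(frozen=True)
class EnrichmentInput:
    """Hypergeometric setup: universe N, complex size C, group size F, overlap m."""

    universe_size: int
    complex_size: int
    group_size: int
    overlap: int

    def __post_init__(self) -> None:
        n, c, f, m = self.universe_size, self.complex_size, self.group_size, self.overlap
        if not (0 <= m <= min(c, f) and c <= n and f <= n):
            raise ValueError(f"impossible hypergeometric input N={n} C={c} F={f} m={m}")


def enrichment_p_value(inp: EnrichmentInput) -> float:
    """P(X ≥ m) for X hypergeometric(N, F, C); 1.0 when m = 0."""
    if inp.overlap == 0:
        return 1.0
    p = hypergeom.sf(
        inp.overlap - 1, inp.universe_size, inp.group_size, inp.complex_size
    )
    return float(min(1.0, max(0.0, p)))


SIGNIFICANCE_CUTOFF = 0.01


def complex_enrichment(
    complexes: ComplexSet,
    groups: Dict[str, Set[str]],
    universe_size: int,
) -> List[Tuple[float, str]]:
    """Smallest p-value over all functional groups, per complex.

    Returns one (p_value, group_label) pair per complex; complexes with no
    annotated member get (1.0, "").  A complex is conventionally called
    significant when its smallest p-value is below 0.01.
    """
    out: List[Tuple[float, str]] = []
    for members in complexes:
        best = (1.0, "")
        for label, annotated in groups.items():
            m = len(members & annotated)
            if m == 0:
                continue
            p = enrichment_p_value(
                EnrichmentInput(
                    universe_size=universe_size,
                    complex_size=len(members),
                    group_size=len(annotated),
                    overlap=m,
                )
            )
            if p < best[0]:
                best = (p, label)
        out.append(best)
    return out
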