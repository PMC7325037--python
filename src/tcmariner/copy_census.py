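"""Copy-number census of an element against a genome hit table.

Genome BLASTn hits of one element are clustered into candidate insertion
loci and each locus is classified, in precedence order, as full-length,
MITE, partial, non-autonomous or unclassified:

* full-length — a hit with >= 95% identity over >= 95% of the element;
* MITE — hits with >= 95% identity covering both TIR intervals (by
  element coordinates) without qualifying as full-length;
* partial — a hit with >= 80% identity over >= 50% of the element;
* non-autonomous — a hit with >= 50% identity over >= 25% of the element.

All boundaries are inclusive.  MITE sits between full-length and partial
because TIR-specific evidence is the more specific claim: a MITE locus
can incidentally satisfy the weaker partial rule.  Coverage for the
full/partial/non-autonomous rules is the single best hit's span on the
element ("a scaffold hit", singular); TIR coverage for the MITE rule is
the union of qualifying hit intervals, with the minimum identity over the
TIR-overlapping hits as the conservative identity.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .element_annotate import ElementAnnotation, TIRPair
from .seqio import HitRecord, NucRecord

__all__ = [
    "CensusThresholds",
    "CopyClass",
    "Locus",
    "cluster_loci",
    "classify_locus",
    "census",
]


class CopyClass(str, Enum):
    full_length = "full_length"
    mite = "mite"
    partial = "partial"
    non_autonomous = "non_autonomous"
    unclassified = "unclassified"


@dataclass(frozen=True)
class CensusThresholds:
    full_min_identity_pct: float = 95.0
    full_min_coverage: float = 0.95
    partial_min_identity_pct: float = 80.0
    partial_min_coverage: float = 0.50
    nonaut_min_identity_pct: float = 50.0
    nonaut_min_coverage: float = 0.25
    mite_tir_min_identity_pct: float = 95.0

    def __post_init__(self) -> None:
        if not (
            self.full_min_identity_pct
            >= self.partial_min_identity_pct
            >= self.nonaut_min_identity_pct
        ):
            raise ValueError("identity thresholds must be ordered full >= partial >= nonaut")
        if not (
            self.full_min_coverage
            >= self.partial_min_coverage
            >= self.nonaut_min_coverage
        ):
            raise ValueError("coverage thresholds must be ordered full >= partial >= nonaut")


@dataclass
class Locus:
    """A candidate insertion site: co-located same-strand hits."""

    subject_id: str
    strand: str
    hits: list[HitRecord] = field(default_factory=list)

    @property
    def subject_interval(self) -> tuple[int, int]:
        los, his = zip(*(h.subject_interval for h in self.hits))
        return (min(los), max(his))


def cluster_loci(
    hits: Sequence[HitRecord],
    element_length: int,
    max_gap: Optional[int] = None,
) -> list[Locus]:
    """Single-linkage clustering of hits into loci.

    Hits on the same subject and strand whose subject intervals lie
    within ``max_gap`` (default 2 x element length) of each other join
    one locus.  Ordering is deterministic: by subject id, then leftmost
    subject coordinate.
    """
    if not hits:
        return []
    if any(h.query_id != hits[0].query_id for h in hits):
        raise ValueError("hits must share a single query (the element)")
    if max_gap is None:
        max_gap = 2 * element_length

    by_key: dict[tuple[str, str], list[HitRecord]] = {}
    for h in hits:
        by_key.setdefault((h.subject_id, h.strand), []).append(h)

    loci: list[Locus] = []
    for (subject_id, strand), group in sorted(by_key.items()):
        group = sorted(group, key=lambda h: h.subject_interval)
        current = Locus(subject_id, strand, [group[0]])
        cur_end = group[0].subject_interval[1]
        for h in group[1:]:
            lo, hi = h.subject_interval
            if lo - cur_end <= max_gap:
                current.hits.append(h)
                cur_end = max(cur_end, hi)
            else:
                loci.append(current)
                current = Locus(subject_id, strand, [h])
                cur_end = hi
        loci.append(current)
    loci.sort(key=lambda l: (l.subject_id, l.subject_interval, l.strand))
    return loci


def _covers(intervals: list[tuple[int, int]], target: tuple[int, int]) -> bool:
    """True iff the union of ``intervals`` contains ``target`` entirely."""
    lo, hi = target
    if lo >= hi:
        return True
    pieces = sorted(i for i in intervals if i[0] < hi and i[1] > lo)
    pos = lo
    for a, b in pieces:
        if a > pos:
            return False
        pos = max(pos, b)
        if pos >= hi:
            return True
    return pos >= hi


def classify_locus(
    locus: Locus,
    element_length: int,
    tir: Optional[TIRPair] = None,
    thresholds: CensusThresholds = CensusThresholds(),
) -> CopyClass:
    """Assign exactly one copy class to a locus (precedence order).

    ``tir`` is required only for the MITE rule; without it a locus can
    never be called a MITE.  Both readings of the MITE evidence are
    accepted: one hit spanning both TIRs, or separate hits on each TIR.
    """
    if element_length <= 0:
        raise ValueError("element_length must be positive")
    t = thresholds

    def hit_qualifies(min_id: float, min_cov: float) -> bool:
        return any(
            h.pct_identity >= min_id and h.query_span / element_length >= min_cov
            for h in locus.hits
        )

    if hit_qualifies(t.full_min_identity_pct, t.full_min_coverage):
        return CopyClass.full_length

    if tir is not None:
        strong = [
            h for h in locus.hits if h.pct_identity >= t.mite_tir_min_identity_pct
        ]
        if strong:
            intervals = [h.query_interval for h in strong]
            if _covers(intervals, tir.tir5) and _covers(intervals, tir.tir3):
                return CopyClass.mite

    if hit_qualifies(t.partial_min_identity_pct, t.partial_min_coverage):
        return CopyClass.partial
    if hit_qualifies(t.nonaut_min_identity_pct, t.nonaut_min_coverage):
        return CopyClass.non_autonomous
    return CopyClass.unclassified


def census(
    hits: Sequence[HitRecord],
    element: NucRecord,
    annotation: Optional[ElementAnnotation] = None,
    thresholds: CensusThresholds = CensusThresholds(),
    max_gap: Optional[int] = None,
) -> dict[CopyClass, int]:
    """Counts per copy class over all loci; counts sum to locus number."""
    counts: Counter[CopyClass] = Counter({c: 0 for c in CopyClass})
    if not hits:
        return dict(counts)
    tir = annotation.tir if annotation is not None else None
    for locus in cluster_loci(hits, len(element.bases), max_gap):
        counts[classify_locus(locus, len(element.bases), tir, thresholds)] += 1
    return dict(counts)
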