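"""Hit-retention filtering and the iterative query-expansion loop.

The mining stage keeps a homology hit when it shows at least 50% identity
over at least 50% of the length of the query sequence (both thresholds
configurable, both boundaries inclusive).  Mining then iterates: retained
sequences sufficiently unlike every query used so far seed the next
search round, one representative per novelty cluster, until a fixed point
or a round limit.  The search engine itself is pluggable — any callable
mapping a query to (hit, sequence) pairs — so the core stays offline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from .alignment import global_align
from .seqio import HitRecord, ProteinRecord

__all__ = [
    "RetentionThresholds",
    "MiningResult",
    "MiningAborted",
    "filter_hits",
    "iterate_mining",
]


@dataclass(frozen=True)
class RetentionThresholds:
    """Minimum identity (percent) and query coverage (fraction) to keep a hit."""

    min_identity_pct: float = 50.0
    min_query_coverage: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_identity_pct <= 100.0:
            raise ValueError("min_identity_pct outside [0, 100]")
        if not 0.0 <= self.min_query_coverage <= 1.0:
            raise ValueError("min_query_coverage outside [0, 1]")


def filter_hits(
    hits: Sequence[HitRecord],
    query_lengths: Mapping[str, int],
    thresholds: RetentionThresholds = RetentionThresholds(),
) -> list[HitRecord]:
    """Retain hits meeting both thresholds; order preserved.

    Coverage is the alignment span on the query, (q_end - q_start + 1)
    divided by the query length, which is robust to gapped alignments.
    """
    kept = []
    for hit in hits:
        if hit.query_id not in query_lengths:
            raise KeyError(f"no length for query {hit.query_id!r}")
        qlen = query_lengths[hit.query_id]
        coverage = hit.query_span / qlen
        if (
            hit.pct_identity >= thresholds.min_identity_pct
            and coverage >= thresholds.min_query_coverage
        ):
            kept.append(hit)
    return kept


SearchFn = Callable[[ProteinRecord], Sequence[tuple[HitRecord, ProteinRecord]]]


@dataclass
class MiningResult:
    """Deduplicated union of retained sequences plus round bookkeeping."""

    sequences: list[ProteinRecord]
    queries_used: list[str]
    rounds: int
    aborted: bool = False
    abort_reason: str = ""


class MiningAborted(RuntimeError):
    """Search failure mid-mining; carries the partial result."""

    def __init__(self, reason: str, partial: MiningResult) -> None:
        super().__init__(reason)
        self.partial = partial


def _max_identity_to(seq: str, references: Sequence[str]) -> float:
    return max((global_align(seq, ref).pct_identity for ref in references), default=0.0)


def iterate_mining(
    search: SearchFn,
    seeds: Sequence[ProteinRecord],
    thresholds: RetentionThresholds = RetentionThresholds(),
    novelty_identity_pct: float = 50.0,
    max_rounds: int = 5,
) -> MiningResult:
    """Iterative mining with novelty-clustered query expansion.

    Round 1 searches every seed.  After each round, retained sequences
    with global identity below ``novelty_identity_pct`` to every query
    used so far are single-linkage clustered (link = identity >= the same
    threshold); the longest member of each cluster (ties by id) becomes a
    next-round query.  Terminates when no new query arises or
    ``max_rounds`` is reached.
    """
    if max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")

    collected: dict[str, ProteinRecord] = {}
    queries_done: list[ProteinRecord] = []
    pending: list[ProteinRecord] = list(seeds)
    rounds = 0

    while pending and rounds < max_rounds:
        rounds += 1
        retained_this_round: list[ProteinRecord] = []
        for query in pending:
            queries_done.append(query)
            try:
                results = search(query)
            except Exception as exc:
                partial = MiningResult(
                    list(collected.values()),
                    [q.id for q in queries_done],
                    rounds,
                    aborted=True,
                    abort_reason=str(exc),
                )
                raise MiningAborted(str(exc), partial) from exc
            hits = [h for h, _ in results]
            seqs = {h.subject_id: s for h, s in results}
            kept = filter_hits(hits, {query.id: len(query)}, thresholds)
            for h in kept:
                rec = seqs[h.subject_id]
                if rec.id not in collected:
                    collected[rec.id] = rec
                    retained_this_round.append(rec)

        query_seqs = [q.residues for q in queries_done]
        novel = [
            r
            for r in sorted(retained_this_round, key=lambda r: r.id)
            if _max_identity_to(r.residues, query_seqs) < novelty_identity_pct
        ]
        pending = _cluster_representatives(novel, novelty_identity_pct)

    return MiningResult(
        sorted(collected.values(), key=lambda r: r.id),
        [q.id for q in queries_done],
        rounds,
    )


def _cluster_representatives(
    records: Sequence[ProteinRecord], link_identity_pct: float
) -> list[ProteinRecord]:
    """Single-linkage clusters (edge = identity >= threshold); one
    representative per cluster: longest sequence, ties by id."""
    n = len(records)
    if n == 0:
        return []
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            ident = global_align(records[i].residues, records[j].residues).pct_identity
            if ident >= link_identity_pct:
                parent[find(i)] = find(j)

    clusters: dict[int, list[ProteinRecord]] = {}
    for i, rec in enumerate(records):
        clusters.setdefault(find(i), []).append(rec)
    reps = [
        min(members, key=lambda r: (-len(r.residues), r.id))
        for members in clusters.values()
    ]
    return sorted(reps, key=lambda r: r.id)
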