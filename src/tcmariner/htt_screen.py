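"""Horizontal transposon transfer (HTT) candidate screening.

A pair of elements from distantly related hosts (differing at or above a
configurable taxonomy rank, phylum by default) is screened in three steps:

1. pairwise identities — amino-acid identity of the catalytic (DDE)
   domain, nucleotide identity of the transposase ORF, and, when both
   elements are full-length (TIRs present), nucleotide identity of the
   whole element;
2. genome copy check — loci of the element in its own host genome; a
   single locus is a contamination suspect (a real resident transposon
   leaves multiple copies), and copies >= 95% identical in one genome but
   < 95% in the other flag an identity asymmetry;
3. decision table — single-copy evidence rejects as contamination
   suspect; low per-copy identity (< 92%) or low full-element identity
   (< 80%) rejects as divergent (ordinary vertical divergence explains
   the similarity); identity asymmetry rejects as contamination suspect;
   a genome without a hit table is unverifiable; everything surviving is
   a candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .alignment import global_align
from .copy_census import cluster_loci
from .element_annotate import AnnotationParams, find_orfs, find_tirs
from .motif import detect_motif_denovo
from .seqio import HitRecord, NucRecord, TaxonTable

__all__ = [
    "HTTThresholds",
    "PairIdentities",
    "CopyReport",
    "HTTVerdict",
    "pair_identities",
    "genome_copy_check",
    "screen_pairs",
]


@dataclass(frozen=True)
class HTTThresholds:
    min_host_divergence_rank: str = "phylum"
    copy_identity_high_pct: float = 95.0
    full_element_low_pct: float = 80.0
    copy_identity_low_pct: float = 92.0
    min_copies_for_confidence: int = 2


@dataclass
class PairIdentities:
    aa_identity_dde: Optional[float]
    nt_identity_transposase: Optional[float]
    nt_identity_full_element: Optional[float]
    unverifiable_reason: str = ""


@dataclass
class CopyReport:
    element_id: str
    copy_count: int
    per_copy_identities: list[float] = field(default_factory=list)

    @property
    def single_copy(self) -> bool:
        return self.copy_count == 1

    @property
    def best_identity(self) -> Optional[float]:
        return max(self.per_copy_identities, default=None)


@dataclass
class HTTVerdict:
    element_a: str
    element_b: str
    identities: PairIdentities
    copy_report_a: Optional[CopyReport]
    copy_report_b: Optional[CopyReport]
    flags: frozenset[str]
    verdict: str  # candidate | rejected_contamination_suspect | rejected_divergent | unverifiable


def _transposase_orf(element: NucRecord, min_len_aa: int = 50):
    orfs = find_orfs(element, min_len_aa=min_len_aa)
    return orfs[0] if orfs else None


def _dde_domain(protein: str, spacing_range=(25, 70)) -> Optional[tuple[int, int]]:
    calls = detect_motif_denovo(protein, spacing_range=spacing_range)
    if not calls:
        return None
    # prefer the canonical triad closest to the classic spacings; ties by position
    call = min(calls, key=lambda c: (abs(c.spacing - 34), c.pos1, c.pos2, c.pos3))
    return call.pos1, call.pos3 + 1


def pair_identities(
    a: NucRecord,
    b: NucRecord,
    annotation_params: AnnotationParams = AnnotationParams(),
) -> PairIdentities:
    """Three-way identity report for a candidate pair.

    The transposase is the longest ORF; the DDE domain is the triad span
    located de novo in its translation.  Full-element identity is
    reported only when both elements carry detectable TIRs (i.e. both are
    TIR-to-TIR sequences).  A missing motif in either element makes the
    pair unverifiable rather than raising.
    """
    orf_a, orf_b = _transposase_orf(a), _transposase_orf(b)
    if orf_a is None or orf_b is None:
        return PairIdentities(None, None, None, "no transposase ORF")
    prot_a, prot_b = orf_a.translate(a.bases), orf_b.translate(b.bases)
    dom_a, dom_b = _dde_domain(prot_a), _dde_domain(prot_b)
    if dom_a is None or dom_b is None:
        return PairIdentities(None, None, None, "DDE motif not found")

    aa_id = global_align(prot_a[dom_a[0] : dom_a[1]], prot_b[dom_b[0] : dom_b[1]]).pct_identity
    nt_id = global_align(orf_a.extract(a.bases), orf_b.extract(b.bases)).pct_identity

    full_id = None
    tir_a = find_tirs(
        a,
        window=annotation_params.tir_window,
        min_len=annotation_params.tir_min_len,
        min_identity_pct=annotation_params.tir_min_identity_pct,
        slack=annotation_params.tir_slack,
    )
    tir_b = find_tirs(
        b,
        window=annotation_params.tir_window,
        min_len=annotation_params.tir_min_len,
        min_identity_pct=annotation_params.tir_min_identity_pct,
        slack=annotation_params.tir_slack,
    )
    if tir_a is not None and tir_b is not None:
        full_id = global_align(a.bases, b.bases).pct_identity
    return PairIdentities(aa_id, nt_id, full_id)


def genome_copy_check(
    element: NucRecord,
    genome_hits: Sequence[HitRecord],
    thresholds: HTTThresholds = HTTThresholds(),
) -> CopyReport:
    """Locus count and per-copy identities of an element in one genome."""
    loci = cluster_loci(genome_hits, len(element.bases)) if genome_hits else []
    per_copy = [max(h.pct_identity for h in locus.hits) for locus in loci]
    return CopyReport(element.id, len(loci), per_copy)


def _decide(
    ids: PairIdentities,
    rep_a: Optional[CopyReport],
    rep_b: Optional[CopyReport],
    t: HTTThresholds,
) -> tuple[frozenset[str], str]:
    flags: set[str] = set()
    if ids.unverifiable_reason:
        return frozenset({"motif_unverifiable"}), "unverifiable"
    if rep_a is None or rep_b is None:
        return frozenset({"genome_unavailable"}), "unverifiable"

    if rep_a.single_copy or rep_b.single_copy:
        flags.add("single_copy_contamination_suspect")
        return frozenset(flags), "rejected_contamination_suspect"

    best_a, best_b = rep_a.best_identity, rep_b.best_identity
    low_copies = (
        best_a is not None
        and best_b is not None
        and (best_a < t.copy_identity_low_pct or best_b < t.copy_identity_low_pct)
    )
    low_full = (
        ids.nt_identity_full_element is not None
        and ids.nt_identity_full_element < t.full_element_low_pct
    )
    if low_copies or low_full:
        flags.add("divergent_pair")
        return frozenset(flags), "rejected_divergent"

    if best_a is not None and best_b is not None:
        hi = t.copy_identity_high_pct
        if (best_a >= hi) != (best_b >= hi):
            flags.add("asymmetric_identity")
            return frozenset(flags), "rejected_contamination_suspect"

    return frozenset(flags), "candidate"


def screen_pairs(
    elements: Sequence[tuple[NucRecord, str]],
    taxonomy: TaxonTable,
    genome_hits: Mapping[str, Optional[Sequence[HitRecord]]],
    thresholds: HTTThresholds = HTTThresholds(),
) -> list[HTTVerdict]:
    """Screen all host-divergent element pairs.

    ``elements`` pairs each element with its host lineage_id;
    ``genome_hits`` maps element_id to that element's hits in its own
    host genome (None = genome unavailable).  Pairs whose hosts do not
    differ at or above the gate rank are not evaluated at all — vertical
    inheritance is plausible there.
    """
    verdicts: list[HTTVerdict] = []
    for i in range(len(elements)):
        for j in range(i + 1, len(elements)):
            (el_a, host_a), (el_b, host_b) = elements[i], elements[j]
            if not taxonomy.differ_at_or_above(
                host_a, host_b, thresholds.min_host_divergence_rank
            ):
                continue
            ids = pair_identities(el_a, el_b)
            hits_a = genome_hits.get(el_a.id)
            hits_b = genome_hits.get(el_b.id)
            rep_a = (
                genome_copy_check(el_a, hits_a, thresholds)
                if hits_a is not None
                else None
            )
            rep_b = (
                genome_copy_check(el_b, hits_b, thresholds)
                if hits_b is not None
                else None
            )
            flags, verdict = _decide(ids, rep_a, rep_b, thresholds)
            verdicts.append(
                HTTVerdict(el_a.id, el_b.id, ids, rep_a, rep_b, flags, verdict)
            )
    return verdicts
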