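"""Global pairwise alignment and sequence-to-profile alignment.

Percent identity follows the EMBOSS stretcher convention used throughout
the package: identical columns divided by total alignment columns, gap
columns included in the denominator.  This single definition feeds the
horizontal-transfer thresholds, the mining novelty clustering and the TIR
identity check, so it is fixed here and nowhere else.

The profile aligner adds one query to a fixed multiple alignment (the
seed DDE-domain profile): existing columns are immutable, query residues
either land in a seed column or are recorded as insertions between
columns.  It is a plain affine-gap dynamic program against per-column
residue frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "PairwiseAlignment",
    "SeedProfile",
    "AlignedQuery",
    "global_align",
    "align_to_profile",
    "pct_identity",
]

_PROTEIN = set("ACDEFGHIKLMNPQRSTVWYX*")
_NUC = set("ACGTN")

_blosum62 = substitution_matrices.load("BLOSUM62")


def _alphabet_of(seq: str) -> str:
    letters = set(seq.upper())
    if letters <= _NUC:
        return "nucleotide"
    if letters <= _PROTEIN:
        return "protein"
    raise ValueError(f"unrecognized alphabet: {sorted(letters - _PROTEIN)}")


@dataclass
class PairwiseAlignment:
    """A global alignment of two sequences with its identity."""

    aligned_a: str
    aligned_b: str
    score: float
    pct_identity: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")


def pct_identity(aligned_a: str, aligned_b: str) -> float:
    """Identical columns / total columns (gaps included), as a percentage."""
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned strings differ in length")
    if not aligned_a:
        return 0.0
    same = sum(
        1
        for x, y in zip(aligned_a, aligned_b)
        if x == y and x not in "-."
    )
    return 100.0 * same / len(aligned_a)


def _make_aligner(
    kind: str,
    match: Optional[float],
    mismatch: Optional[float],
    gap_open: float,
    gap_extend: float,
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    if kind == "protein":
        aligner.substitution_matrix = _blosum62
    else:
        aligner.match_score = 5.0 if match is None else match
        aligner.mismatch_score = -4.0 if mismatch is None else mismatch
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def global_align(
    a: str,
    b: str,
    *,
    match: Optional[float] = None,
    mismatch: Optional[float] = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> PairwiseAlignment:
    """Optimal global (Needleman-Wunsch, affine-gap) alignment.

    Protein pairs are scored with BLOSUM62; nucleotide pairs with
    match/mismatch scores (defaults +5/-4).  ``gap_open``/``gap_extend``
    are penalties (positive numbers).
    """
    a, b = a.upper(), b.upper()
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    ka, kb = _alphabet_of(a), _alphabet_of(b)
    if ka != kb:
        raise ValueError(f"mixed alphabets: {ka} vs {kb}")
    aligner = _make_aligner(ka, match, mismatch, gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    rows = str(aln).splitlines()
    # biopython >=1.80 formats blocks; use the indices API instead
    ga, gb = aln[0], aln[1]
    return PairwiseAlignment(ga, gb, float(aln.score), pct_identity(ga, gb))


@dataclass
class SeedProfile:
    """A fixed gapped seed alignment plus its three catalytic columns."""

    ids: list[str]
    rows: list[str]
    catalytic_columns: tuple[int, int, int]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("profile must have at least one row")
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise ValueError("profile rows must have equal length")
        c1, c2, c3 = self.catalytic_columns
        if not (0 <= c1 < c2 < c3 < L):
            raise ValueError("catalytic columns must be increasing and in range")
        for rid, row in zip(self.ids, self.rows):
            for c in self.catalytic_columns:
                if row[c] in "-.":
                    raise ValueError(
                        f"seed row {rid!r} has a gap at catalytic column {c}"
                    )

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])


@dataclass
class AlignedQuery:
    """One query placed in profile coordinates.

    ``column_to_query[c]`` is the 0-based ungapped query index aligned to
    profile column ``c``, or None where the query has a gap.
    ``insertions`` holds (after_column, query_start, length) records for
    query residues falling between seed columns (after_column = -1 for an
    N-terminal insertion).
    """

    query_id: str
    query: str
    column_to_query: list[Optional[int]]
    insertions: list[tuple[int, int, int]] = field(default_factory=list)

    def gapped_row(self, profile: SeedProfile) -> str:
        """The query as a gapped row in seed-column coordinates
        (insertions omitted, as in a profile alignment projection)."""
        return "".join(
            self.query[i] if i is not None else "-" for i in self.column_to_query
        )


def _column_scores(profile: SeedProfile, alphabet: str) -> np.ndarray:
    """score[c, a] = mean BLOSUM62 score of residue a against column c
    (non-gap residues only)."""
    letters = list(alphabet)
    idx = {a: k for k, a in enumerate(letters)}
    ncol = profile.n_columns
    scores = np.zeros((ncol, len(letters)))
    for c in range(ncol):
        col = [r[c] for r in profile.rows if r[c] not in "-."]
        if not col:
            continue
        for a in letters:
            s = 0.0
            for r in col:
                try:
                    s += _blosum62[a, r]
                except (KeyError, IndexError):
                    s += _blosum62["X", "X"]
            scores[c, idx[a]] = s / len(col)
    return scores


def align_to_profile(
    query_id: str,
    seq: str,
    profile: SeedProfile,
    *,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignedQuery:
    """Align one sequence to a fixed profile (seed columns immutable).

    Affine-gap dynamic programming of the query against per-column mean
    BLOSUM62 scores.  Deletions (gap in query at a seed column) and
    insertions (query residues between seed columns) are penalized with
    the same affine scheme.  End gaps are charged, keeping the alignment
    global on both profile and query.
    """
    seq = seq.upper()
    if not seq:
        raise ValueError("empty query")
    alphabet = "ACDEFGHIKLMNPQRSTVWYX"
    seq_clean = "".join(ch if ch in alphabet else "X" for ch in seq)
    aidx = {a: k for k, a in enumerate(alphabet)}
    col_scores = _column_scores(profile, alphabet)

    n, m = len(seq_clean), profile.n_columns
    NEG = -1e18
    go, ge = -abs(gap_open), -abs(gap_extend)

    # M[i,j]: seq[i-1] in column j-1; Ix: insertion (query residue between
    # columns); Iy: deletion (column without query residue).
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)
    Iy = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = go + ge * (i - 1)
    for j in range(1, m + 1):
        Iy[0, j] = go + ge * (j - 1)

    ptrM = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrX = np.zeros((n + 1, m + 1), dtype=np.int8)
    ptrY = np.zeros((n + 1, m + 1), dtype=np.int8)

    for i in range(1, n + 1):
        srow = col_scores[:, aidx[seq_clean[i - 1]]]
        for j in range(1, m + 1):
            s = srow[j - 1]
            cands = (M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            k = int(np.argmax(cands))
            M[i, j] = cands[k] + s
            ptrM[i, j] = k
            cx = (M[i - 1, j] + go, Ix[i - 1, j] + ge)
            kx = 0 if cx[0] >= cx[1] else 1
            Ix[i, j] = cx[kx]
            ptrX[i, j] = kx
            cy = (M[i, j - 1] + go, Iy[i, j - 1] + ge)
            ky = 0 if cy[0] >= cy[1] else 1
            Iy[i, j] = cy[ky]
            ptrY[i, j] = ky
        # Ix at j=0 handled by init; Iy row 0 by init.

    ends = (M[n, m], Ix[n, m], Iy[n, m])
    state = int(np.argmax(ends))

    column_to_query: list[Optional[int]] = [None] * m
    insertions: list[tuple[int, int, int]] = []
    i, j = n, m
    pending_ins: list[int] = []  # query indices of a running insertion

    def flush_ins(after_col: int) -> None:
        if pending_ins:
            start = pending_ins[-1]
            insertions.append((after_col, start, len(pending_ins)))
            pending_ins.clear()

    while i > 0 or j > 0:
        if state == 0:  # M
            column_to_query[j - 1] = i - 1
            flush_ins(j - 1)
            state = ptrM[i, j]
            i, j = i - 1, j - 1
        elif state == 1:  # Ix: query residue between columns j and j+1
            pending_ins.append(i - 1)
            if i == 1 and j == 0:
                state = 0
            else:
                state = ptrX[i, j] if j > 0 else 1
            i -= 1
        else:  # Iy: column j-1 deleted in query
            flush_ins(j - 1)
            # ptrY codes 0 = from M, 1 = from Iy (never Ix)
            state = (0 if ptrY[i, j] == 0 else 2) if i > 0 else 2
            j -= 1
    flush_ins(-1)
    insertions.reverse()

    return AlignedQuery(query_id, seq, column_to_query, insertions)
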