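"""DDD/E catalytic-triad location and family signature assignment.

Tc1/mariner transposases carry a catalytic triad of two aspartates and a
third aspartate or glutamate (DDD/E).  Families are named by the number
of residues strictly between the second and third catalytic positions:
DD34E means 34 residues separate the second D from the E.  Degenerate
residues at catalytic positions (as in domesticated TIGD genes, e.g.
DA30P) are reported verbatim, never rejected.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

from .alignment import AlignedQuery, SeedProfile

__all__ = [
    "MotifCall",
    "MotifNotFound",
    "FamilySignature",
    "detect_motif",
    "detect_motif_denovo",
    "assign_family",
    "parse_signature",
    "FAMILY_LOOKUP",
]


@dataclass
class MotifCall:
    """A located catalytic triad in ungapped query coordinates."""

    pos1: int
    pos2: int
    pos3: int
    res1: str
    res2: str
    res3: str

    def __post_init__(self) -> None:
        if not self.pos1 < self.pos2 < self.pos3:
            raise ValueError("catalytic positions must be strictly increasing")

    @property
    def spacing(self) -> int:
        """Residues strictly between positions 2 and 3 (DD34E => 34)."""
        return self.pos3 - self.pos2 - 1

    @property
    def spacing12(self) -> int:
        """Residues between positions 1 and 2; reported, never classified on."""
        return self.pos2 - self.pos1 - 1

    @property
    def signature(self) -> str:
        return f"{self.res1}{self.res2}{self.spacing}{self.res3}"


@dataclass
class MotifNotFound:
    """No-call marker with the reason (e.g. deleted catalytic position)."""

    reason: str


# Family signature lookup.  DD34E is intrinsically ambiguous (Tc1, the
# ciliate Tec and TBE families and HvSm all carry it) and is resolved only
# by clade membership downstream; the candidate set is never collapsed here.
FAMILY_LOOKUP: dict[str, frozenset[str]] = {
    "DD34D": frozenset({"mariner"}),
    "DD34E": frozenset({"Tc1", "Tec", "TBE", "HvSm"}),
    "DD39D": frozenset({"PlantMar"}),
    "DD37D": frozenset({"maT"}),
    "DD41D": frozenset({"rosa"}),
    "DD37E": frozenset({"TRT", "impala", "DD37E(L31)"}),
}

# pogo transposases show clade-dependent DDD spacings (DD35D in some
# subgroups, DD30D in others, DD30-32D elsewhere); any DD(30-35)D not
# claimed above is a pogo candidate.
_POGO_SPACINGS = range(30, 36)

_SIG_RE = re.compile(r"^([A-Z])([A-Z])(\d+)([A-Z])$")


@dataclass
class FamilySignature:
    """A signature string plus the families compatible with it."""

    signature: str
    candidate_families: frozenset[str] = field(default_factory=frozenset)
    note: str = ""

    @property
    def is_canonical(self) -> bool:
        """True when the triad is D,D,D/E; degenerate residues otherwise."""
        r1, r2, _, r3 = parse_signature(self.signature)
        return r1 == "D" and r2 == "D" and r3 in "DE"


def parse_signature(signature: str) -> tuple[str, str, int, str]:
    m = _SIG_RE.match(signature)
    if not m:
        raise ValueError(f"malformed signature {signature!r}")
    return m.group(1), m.group(2), int(m.group(3)), m.group(4)


def assign_family(signature: str) -> FamilySignature:
    """Map a signature to its candidate families.

    Exact table matches first; then the pogo DD(30-35)D band; anything
    else is unknown.  Degenerate triads (non-D/D/D-or-E residues) are
    flagged as domesticated-gene-like patterns.
    """
    r1, r2, spacing, r3 = parse_signature(signature)
    if signature in FAMILY_LOOKUP:
        return FamilySignature(signature, FAMILY_LOOKUP[signature])
    if r1 == "D" and r2 == "D" and r3 == "D" and spacing in _POGO_SPACINGS:
        return FamilySignature(signature, frozenset({"pogo"}))
    note = ""
    if not (r1 == "D" and r2 == "D" and r3 in "DE"):
        note = "degenerate catalytic motif (domesticated-gene-like pattern)"
    return FamilySignature(signature, frozenset({"unknown"}), note)


def detect_motif(
    aligned: AlignedQuery, profile: SeedProfile
) -> MotifCall | MotifNotFound:
    """Read the triad off a profile-aligned query.

    The residues at the profile's three catalytic columns are mapped back
    to ungapped query coordinates; a gap at any catalytic column is a
    no-call.  Insertions between the second and third column enlarge the
    spacing, deletions shrink it — the spacing is counted on the ungapped
    query, not on the seed.
    """
    positions = []
    for c in profile.catalytic_columns:
        qi = aligned.column_to_query[c]
        if qi is None:
            return MotifNotFound("deleted catalytic position")
        positions.append(qi)
    p1, p2, p3 = positions
    if not p1 < p2 < p3:
        return MotifNotFound("catalytic positions out of order")
    q = aligned.query
    return MotifCall(p1, p2, p3, q[p1], q[p2], q[p3])


def detect_motif_denovo(
    seq: str,
    spacing_range: tuple[int, int] = (25, 70),
    residue_sets: tuple[Sequence[str], Sequence[str], Sequence[str]] = (
        "D",
        "D",
        "DE",
    ),
) -> list[MotifCall]:
    """Enumerate candidate triads without a profile.

    Returns every position triple (p1, p2, p3) whose residues fall in the
    three allowed sets and whose second interval length lies in
    ``spacing_range`` (inclusive), ordered by position.  The first
    interval is unconstrained, mirroring classification practice.
    """
    lo, hi = spacing_range
    if lo < 0:
        raise ValueError("spacing_range must be non-negative")
    seq = seq.upper()
    set1, set2, set3 = (set(s) for s in residue_sets)
    pos1 = [i for i, ch in enumerate(seq) if ch in set1]
    pos2 = [i for i, ch in enumerate(seq) if ch in set2]
    pos3 = [i for i, ch in enumerate(seq) if ch in set3]
    calls = []
    for p2 in pos2:
        for p3 in pos3:
            if not lo <= p3 - p2 - 1 <= hi:
                continue
            for p1 in pos1:
                if p1 < p2:
                    calls.append(MotifCall(p1, p2, p3, seq[p1], seq[p2], seq[p3]))
    calls.sort(key=lambda c: (c.pos1, c.pos2, c.pos3))
    return calls
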