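"""Synthetic data generators with machine-readable ground truth.

Every stage of the pipeline can be exercised offline on data whose true
structure is known by construction:

* transposase families with a planted D-D-D/E triad at configurable
  spacing — catalytic sites are immutable under simulated divergence, so
  motif ground truth is exact at any divergence;
* nucleotide elements with a planted ORF, TIR pair and TA TSD, mirroring
  the canonical element architecture (flank + TA + TIR + internal ORF +
  inverted TIR + TA + flank);
* per-genome hit tables with copy classes planted inside the census
  identity/coverage bands;
* cophylogeny scenarios where TE evolution tracks a host rank hierarchy
  except for a chosen number of cross-lineage transfer events;
* an HTT screening benchmark of planted transfer, contamination and
  vertical-inheritance cases.

Substitutions are i.i.d. uniform over alternative residues, with no rate
heterogeneity or indels: the simplest model satisfying the assumptions of
the stages under test.  One seed governs all draws; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .element_annotate import revcomp
from .seqio import HitRecord, NucRecord, ProteinRecord, TaxonTable

__all__ = [
    "FamilySpec",
    "ElementSpec",
    "GenomeSpec",
    "CophyloSpec",
    "sim_family",
    "sim_element",
    "sim_hit_table",
    "sim_cophylo",
    "sim_htt_benchmark",
    "HTTCase",
]

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_NO_DE = "".join(c for c in _AA if c not in "DE")
_NT = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _random_protein(rng: np.random.Generator, length: int, alphabet: str = _AA) -> str:
    return "".join(rng.choice(list(alphabet), size=length))


def _random_nt(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_NT), size=length))


# ---------------------------------------------------------------------------
# transposase families

@dataclass(frozen=True)
class FamilySpec:
    """A planted-triad transposase family.

    ``spacing`` counts residues strictly between the second and third
    catalytic positions (so spacing 34 with third residue 'E' is DD34E);
    ``spacing12`` the residues between the first and second.
    """

    name: str = "fam"
    n: int = 10
    length: int = 160
    spacing: int = 34
    spacing12: int = 55
    res3: str = "E"
    res1: str = "D"
    res2: str = "D"
    divergence: float = 0.1
    lead: int = 20  # residues before the first catalytic position

    def positions(self) -> tuple[int, int, int]:
        p1 = self.lead
        p2 = p1 + self.spacing12 + 1
        p3 = p2 + self.spacing + 1
        return p1, p2, p3


@dataclass
class FamilyTruth:
    positions: tuple[int, int, int]
    spacing: int
    signature: str
    ancestor: str


def sim_family(spec: FamilySpec, seed) -> tuple[list[ProteinRecord], FamilyTruth]:
    """Ancestor with a planted triad; descendants by i.i.d. substitution
    at non-catalytic sites only (catalytic sites never mutate)."""
    rng = _rng(seed)
    p1, p2, p3 = spec.positions()
    if p3 >= spec.length:
        raise ValueError("triad geometry does not fit in sequence length")
    if not 0.0 <= spec.divergence <= 1.0:
        raise ValueError("divergence must be a probability")

    # non-catalytic background avoids D/E so no spurious in-band triad can
    # outcompete the planted one at divergence 0
    body = list(_random_protein(rng, spec.length, _AA_NO_DE))
    body[p1], body[p2], body[p3] = spec.res1, spec.res2, spec.res3
    ancestor = "".join(body)

    records = []
    catalytic = {p1, p2, p3}
    for k in range(spec.n):
        seq = list(ancestor)
        for i in range(spec.length):
            if i in catalytic:
                continue
            if rng.random() < spec.divergence:
                alternatives = _AA.replace(seq[i], "")
                seq[i] = alternatives[rng.integers(len(alternatives))]
        records.append(ProteinRecord(f"{spec.name}_{k:03d}", "".join(seq)))
    truth = FamilyTruth(
        positions=(p1, p2, p3),
        spacing=spec.spacing,
        signature=f"{spec.res1}{spec.res2}{spec.spacing}{spec.res3}",
        ancestor=ancestor,
    )
    return records, truth


# ---------------------------------------------------------------------------
# nucleotide elements

@dataclass(frozen=True)
class ElementSpec:
    name: str = "element"
    orf_len_nt: int = 579  # includes the stop codon; divisible by 3
    tir_len: int = 20
    tir_identity_pct: float = 100.0
    tsd: str = "TA"
    internal_len: int = 900  # element length between the TIRs
    flank_len: int = 50

    def __post_init__(self) -> None:
        if self.tir_len < 1:
            raise ValueError("tir_len must be >= 1")
        if self.orf_len_nt % 3 != 0 or self.orf_len_nt < 9:
            raise ValueError("orf_len_nt must be divisible by 3 and >= 9")
        if self.orf_len_nt > self.internal_len:
            raise ValueError("ORF does not fit between the TIRs")


@dataclass
class ElementTruth:
    tir5: tuple[int, int]
    tir3: tuple[int, int]
    tir_len: int
    orf_start: int
    orf_end: int
    tsd: str
    triad_aa: Optional[tuple[int, int, int]] = None


_D_CODON, _E_CODON = "GAT", "GAA"


def _random_orf(
    rng: np.random.Generator, length_nt: int, plant_triad: bool = True
) -> tuple[str, Optional[tuple[int, int, int]]]:
    """ATG + non-stop codons + one stop; no internal in-frame stops.

    When ``plant_triad`` is set and the frame is long enough, a D-D-E
    catalytic triad with the classic 34-residue second interval is
    written into the translation; its amino-acid positions are returned.
    """
    n_mid = length_nt // 3 - 2
    codons = ["ATG"]
    while len(codons) < n_mid + 1:
        c = _random_nt(rng, 3)
        if c not in _STOPS and c != "ATG":
            codons.append(c)
    triad = None
    if plant_triad and n_mid >= 60:
        spacing12 = min(20, n_mid - 42)
        p1 = 2
        p2 = p1 + spacing12 + 1
        p3 = p2 + 35
        codons[p1], codons[p2], codons[p3] = _D_CODON, _D_CODON, _E_CODON
        triad = (p1, p2, p3)
    codons.append("TAA")
    return "".join(codons), triad


def _mutate_nt(rng: np.random.Generator, seq: str, n_mut: int) -> str:
    s = list(seq)
    if n_mut == 0:
        return seq
    pos = rng.choice(len(s), size=min(n_mut, len(s)), replace=False)
    for p in pos:
        alternatives = _NT.replace(s[p], "")
        s[p] = alternatives[rng.integers(3)]
    return "".join(s)


def sim_element(spec: ElementSpec, seed) -> tuple[NucRecord, ElementTruth]:
    """One element: TIR + internal(with ORF) + inverted TIR, TA in flanks.

    The 3' TIR is the reverse complement of the 5' TIR mutated down to
    ``tir_identity_pct``.  Internal sequence outside the ORF is stop-rich
    enough by chance that the planted ORF is recorded in the truth table
    rather than guaranteed unique.
    """
    rng = _rng(seed)
    tir = _random_nt(rng, spec.tir_len)
    n_mut = round((1.0 - spec.tir_identity_pct / 100.0) * spec.tir_len)
    tir3 = _mutate_nt(rng, revcomp(tir), n_mut)

    pad_total = spec.internal_len - spec.orf_len_nt
    if pad_total >= 2:
        pad5 = 1 + int(rng.integers(0, pad_total - 1))
    else:
        pad5 = int(rng.integers(0, pad_total + 1))
    orf, triad = _random_orf(rng, spec.orf_len_nt)
    internal = list(_random_nt(rng, pad5) + orf + _random_nt(rng, pad_total - pad5))
    # break complementarity right inside the element so the TIR boundary is
    # sharp: the first internal base must not pair with the last one
    if pad_total >= 2 and internal[0] == revcomp(internal[-1]):
        choices = [c for c in _NT if c != revcomp(internal[-1])]
        internal[0] = choices[int(rng.integers(len(choices)))]
    internal = "".join(internal)

    bases = tir + internal + tir3
    flank5 = _random_nt(rng, spec.flank_len) + spec.tsd
    flank3 = spec.tsd + _random_nt(rng, spec.flank_len)
    rec = NucRecord(spec.name, bases, flank5=flank5, flank3=flank3)
    orf_start = spec.tir_len + pad5
    truth = ElementTruth(
        tir5=(0, spec.tir_len),
        tir3=(len(bases) - spec.tir_len, len(bases)),
        tir_len=spec.tir_len,
        orf_start=orf_start,
        orf_end=orf_start + spec.orf_len_nt,
        tsd=spec.tsd,
        triad_aa=triad,
    )
    return rec, truth


# ---------------------------------------------------------------------------
# genome hit tables

@dataclass(frozen=True)
class GenomeSpec:
    """Planted copy counts and the identity/coverage band for each class.

    Bands default to the census rules themselves: full-length copies sit
    at identity >= 95 and coverage >= 0.95, partials at identity [80, 95)
    and coverage [0.5, 0.95), non-autonomous at [50, 80) x [0.25, 0.5),
    and MITEs at identity >= 95 over both TIR intervals with tiny total
    coverage.
    """

    n_full: int = 3
    n_partial: int = 2
    n_mite: int = 4
    n_nonaut: int = 1

    def __post_init__(self) -> None:
        if min(self.n_full, self.n_partial, self.n_mite, self.n_nonaut) < 0:
            raise ValueError("copy counts must be >= 0")


def _mk_hit(
    element_id: str,
    subject: str,
    identity: float,
    q_start: int,
    q_end: int,
    s_offset: int = 1000,
) -> HitRecord:
    span = q_end - q_start + 1
    return HitRecord(
        query_id=element_id,
        subject_id=subject,
        pct_identity=round(identity, 1),
        aln_length=span,
        mismatches=int(span * (100.0 - identity) / 100.0),
        gap_opens=0,
        q_start=q_start,
        q_end=q_end,
        s_start=s_offset,
        s_end=s_offset + span - 1,
        evalue=1e-30,
        bitscore=float(span),
    )


def sim_hit_table(
    genome: GenomeSpec,
    element: NucRecord,
    tir: tuple[tuple[int, int], tuple[int, int]],
    seed,
) -> tuple[list[HitRecord], dict[str, int]]:
    """Hit table for one genome with planted copies of each class.

    Each planted copy goes on its own subject scaffold so loci cannot
    merge.  Returns the hits and the truth counts.
    """
    rng = _rng(seed)
    L = len(element.bases)
    (t5_lo, t5_hi), (t3_lo, t3_hi) = tir
    hits: list[HitRecord] = []
    scaffold = 0

    def new_subject() -> str:
        nonlocal scaffold
        scaffold += 1
        return f"scaffold_{scaffold:04d}"

    for _ in range(genome.n_full):
        ident = float(95.0 + rng.random() * 5.0)
        cov = 0.95 + rng.random() * 0.05
        span = max(1, int(round(cov * L)))
        q_start = int(rng.integers(1, L - span + 2))
        hits.append(_mk_hit(element.id, new_subject(), ident, q_start, q_start + span - 1))

    for _ in range(genome.n_partial):
        ident = float(80.0 + rng.random() * 14.9)
        cov = 0.5 + rng.random() * 0.44
        span = max(1, int(round(cov * L)))
        q_start = int(rng.integers(1, L - span + 2))
        hits.append(_mk_hit(element.id, new_subject(), ident, q_start, q_start + span - 1))

    for _ in range(genome.n_nonaut):
        ident = float(50.0 + rng.random() * 29.9)
        cov = 0.25 + rng.random() * 0.24
        span = max(1, int(round(cov * L)))
        q_start = int(rng.integers(1, L - span + 2))
        hits.append(_mk_hit(element.id, new_subject(), ident, q_start, q_start + span - 1))

    for _ in range(genome.n_mite):
        subject = new_subject()
        ident = float(95.0 + rng.random() * 5.0)
        # two hits covering exactly the TIR intervals, close on the subject
        hits.append(_mk_hit(element.id, subject, ident, t5_lo + 1, t5_hi, s_offset=500))
        hits.append(
            _mk_hit(element.id, subject, ident, t3_lo + 1, t3_hi, s_offset=700)
        )

    truth = {
        "full_length": genome.n_full,
        "partial": genome.n_partial,
        "mite": genome.n_mite,
        "non_autonomous": genome.n_nonaut,
        "unclassified": 0,
    }
    return hits, truth


# ---------------------------------------------------------------------------
# cophylogeny scenarios

@dataclass(frozen=True)
class CophyloSpec:
    n_hosts: int = 16
    n_htt_events: int = 0
    seq_len: int = 200
    mut_per_edge: float = 0.04  # per-site substitution probability per level
    levels: int = 4  # depth of the host hierarchy (binary)
    # a deeply diverged unlinked sequence for rooting the TE tree the way
    # the bacterial IS630 group roots the real superfamily phylogeny
    with_outgroup: bool = False

    def __post_init__(self) -> None:
        if self.n_hosts > 2**self.levels:
            raise ValueError("n_hosts exceeds hierarchy capacity")


_RANK_PREFIX = ("k", "p", "c", "o", "f", "g", "s")


def sim_cophylo(
    spec: CophyloSpec, seed
) -> tuple[list[ProteinRecord], TaxonTable, list[tuple[str, str]], int]:
    """Hosts on a balanced binary rank hierarchy; TE sequences evolve down
    the same hierarchy (vertical inheritance), then ``n_htt_events``
    elements take their sequence from a host in the other top-level clade
    (a horizontal transfer), keeping their own host link.

    Returns (TE sequences, taxonomy, links, number of planted events).
    """
    rng = _rng(seed)
    # effective depth: the smallest binary hierarchy holding n_hosts, so the
    # top rank genuinely splits the hosts in two
    levels = min(max(1, (spec.n_hosts - 1).bit_length()), 7)
    hosts = []
    for h in range(spec.n_hosts):
        path = [(h >> (levels - 1 - l)) & 1 for l in range(levels)]
        hosts.append(path)
    table = TaxonTable()
    for h, path in enumerate(hosts):
        ranks = {}
        for l in range(levels):
            prefix = "".join(map(str, path[: l + 1]))
            ranks[_RANK_PREFIX_RANKS[l]] = f"{_RANK_PREFIX[l]}{prefix}"
        for l in range(levels, 7):
            ranks[_RANK_PREFIX_RANKS[l]] = f"{_RANK_PREFIX[l]}{h}"
        table.add(f"host_{h:03d}", **ranks)

    # evolve one protein down the binary hierarchy
    root_seq = _random_protein(rng, spec.seq_len)

    def evolve(seq: str) -> str:
        s = list(seq)
        for i in range(len(s)):
            if rng.random() < spec.mut_per_edge:
                alternatives = _AA.replace(s[i], "")
                s[i] = alternatives[rng.integers(len(alternatives))]
        return "".join(s)

    node_seqs: dict[tuple[int, ...], str] = {(): root_seq}
    for level in range(levels):
        for prefix in sorted({tuple(h[: level + 1]) for h in hosts}):
            node_seqs[prefix] = evolve(node_seqs[prefix[:-1]])

    te_seqs = {h: node_seqs[tuple(hosts[h])] for h in range(spec.n_hosts)}

    # plant transfers: recipient takes (a lightly mutated copy of) the
    # donor's sequence; the host link stays with the recipient's host
    n_events = 0
    if spec.n_htt_events:
        recipients = rng.choice(spec.n_hosts, size=min(spec.n_htt_events, spec.n_hosts), replace=False)
        for r in recipients:
            opposite = [h for h in range(spec.n_hosts) if hosts[h][0] != hosts[r][0]]
            donor = int(opposite[rng.integers(len(opposite))])
            te_seqs[int(r)] = evolve(te_seqs[donor])
            n_events += 1

    records = [
        ProteinRecord(f"te_{h:03d}", te_seqs[h], host_lineage_id=f"host_{h:03d}")
        for h in range(spec.n_hosts)
    ]
    links = [(f"te_{h:03d}", f"host_{h:03d}") for h in range(spec.n_hosts)]
    if spec.with_outgroup:
        og = list(root_seq)
        n_flip = int(0.45 * spec.seq_len)
        flips = rng.choice(spec.seq_len, size=n_flip, replace=False)
        for p in flips:
            alternatives = _AA.replace(og[p], "")
            og[p] = alternatives[rng.integers(len(alternatives))]
        records.append(ProteinRecord("IS630_outgroup", "".join(og)))
    return records, table, links, n_events


_RANK_PREFIX_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


# ---------------------------------------------------------------------------
# HTT screening benchmark

@dataclass
class HTTCase:
    """One benchmark case: a pair of elements + hosts + genome hit tables."""

    kind: str  # transfer | contamination | vertical
    element_a: NucRecord
    element_b: NucRecord
    host_a: str
    host_b: str
    hits_a: list[HitRecord]
    hits_b: list[HitRecord]


def _copies_hits(
    element: NucRecord, n_copies: int, identities: Sequence[float]
) -> list[HitRecord]:
    L = len(element.bases)
    return [
        _mk_hit(element.id, f"{element.id}_scaf{k}", identities[k], 1, L)
        for k in range(n_copies)
    ]


def sim_htt_benchmark(
    n_each: int, seed, element_spec: Optional[ElementSpec] = None
) -> tuple[list[HTTCase], TaxonTable]:
    """Planted transfer, contamination and vertical-inheritance cases.

    * transfer — hosts in different phyla; elements ~97-99% identical at
      the nucleotide level; 3-5 near-identical copies in both genomes;
    * contamination — hosts in different phyla; elements near-identical;
      one genome holds a single copy;
    * vertical — hosts in the same phylum (below the gate rank), any
      identity; never evaluated by the screen.
    """
    rng = _rng(seed)
    spec = element_spec or ElementSpec(internal_len=600, orf_len_nt=450, flank_len=20)
    table = TaxonTable()
    cases: list[HTTCase] = []
    lineage_n = 0

    def add_host(kingdom: str, phylum: str) -> str:
        nonlocal lineage_n
        lid = f"L{lineage_n:04d}"
        lineage_n += 1
        table.add(
            lid,
            kingdom=kingdom,
            phylum=phylum,
            **{r: f"{r[:2]}{lineage_n}" for r in ("class", "order", "family", "genus", "species")},
        )
        return lid

    def safe_positions(truth: ElementTruth, bases: str) -> list[int]:
        """Positions mutable without disturbing the transposase reading
        frame: everything outside the ORF, plus third codon positions of
        codons that cannot mutate into a stop and are not the start, stop
        or a catalytic codon."""
        protected_codons = {0, (truth.orf_end - truth.orf_start) // 3 - 1}
        if truth.triad_aa:
            protected_codons.update(truth.triad_aa)
        pos = [i for i in range(len(bases)) if not truth.orf_start <= i < truth.orf_end]
        for codon_idx in range((truth.orf_end - truth.orf_start) // 3):
            if codon_idx in protected_codons:
                continue
            start = truth.orf_start + 3 * codon_idx
            # third-position change in a TA-/TG-prefixed codon could
            # create a premature stop
            if bases[start : start + 2] in ("TA", "TG"):
                continue
            pos.append(start + 2)
        return sorted(pos)

    def diverged_pair(
        base: NucRecord, truth: ElementTruth, pct: float, tag: str
    ) -> tuple[NucRecord, NucRecord]:
        n_mut = int(round(pct / 100.0 * len(base.bases)))
        allowed = safe_positions(truth, base.bases)
        picks = rng.choice(len(allowed), size=min(n_mut, len(allowed)), replace=False)
        s = list(base.bases)
        for k in picks:
            p = allowed[int(k)]
            alternatives = _NT.replace(s[p], "")
            s[p] = alternatives[rng.integers(3)]
        return (
            NucRecord(f"{base.id}_{tag}a", base.bases, base.flank5, base.flank3),
            NucRecord(f"{base.id}_{tag}b", "".join(s), base.flank5, base.flank3),
        )

    for k in range(n_each):
        base, base_truth = sim_element(
            ElementSpec(
                name=f"el{k:03d}",
                orf_len_nt=spec.orf_len_nt,
                tir_len=spec.tir_len,
                internal_len=spec.internal_len,
                flank_len=spec.flank_len,
            ),
            rng,
        )

        # transfer: distant hosts, recent near-identical pair, multi-copy both
        a, b = diverged_pair(base, base_truth, float(1.0 + rng.random() * 2.0), "t")
        host_a = add_host("metazoa", f"phylT{k}a")
        host_b = add_host("metazoa", f"phylT{k}b")
        n_a, n_b = int(rng.integers(3, 6)), int(rng.integers(3, 6))
        ids_a = [float(96.0 + rng.random() * 3.5) for _ in range(n_a)]
        ids_b = [float(96.0 + rng.random() * 3.5) for _ in range(n_b)]
        cases.append(
            HTTCase(
                "transfer", a, b, host_a, host_b,
                _copies_hits(a, n_a, ids_a), _copies_hits(b, n_b, ids_b),
            )
        )

        # contamination: distant hosts, one genome single-copy
        a, b = diverged_pair(base, base_truth, float(0.5 + rng.random()), "c")
        host_a = add_host("metazoa", f"phylC{k}a")
        host_b = add_host("viridiplantae", f"phylC{k}b")
        ids_a = [float(96.0 + rng.random() * 3.5) for _ in range(4)]
        cases.append(
            HTTCase(
                "contamination", a, b, host_a, host_b,
                _copies_hits(a, 4, ids_a), _copies_hits(b, 1, [99.0]),
            )
        )

        # vertical: same phylum, moderate divergence
        a, b = diverged_pair(base, base_truth, float(5.0 + rng.random() * 10.0), "v")
        phylum = f"phylV{k}"
        host_a = add_host("metazoa", phylum)
        host_b = add_host("metazoa", phylum)
        ids_a = [float(85.0 + rng.random() * 10.0) for _ in range(3)]
        ids_b = [float(85.0 + rng.random() * 10.0) for _ in range(3)]
        cases.append(
            HTTCase(
                "vertical", a, b, host_a, host_b,
                _copies_hits(a, 3, ids_a), _copies_hits(b, 3, ids_b),
            )
        )
    return cases, table
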