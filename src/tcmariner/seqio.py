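"""Readers/writers for the standard formats the pipeline touches.

FASTA for protein and nucleotide sequences, 12-column BLAST tabular
(outfmt 6) hit tables, Newick trees (support values read from internal
node labels) and a flat taxonomy TSV keyed by lineage id.

Internal convention: coordinates are 0-based half-open.  The 1-based
inclusive coordinates of the BLAST dialect exist only in the parsed
:class:`HitRecord` fields; use its ``query_interval`` / ``subject_interval``
properties for interval arithmetic.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Optional, TextIO, Union

import dendropy

from .phylo import PhyloNode, PhyloTree

__all__ = [
    "ProteinRecord",
    "NucRecord",
    "HitRecord",
    "TaxonTable",
    "FormatError",
    "parse_fasta",
    "write_fasta",
    "parse_hit_table",
    "write_hit_table",
    "parse_newick",
    "write_newick",
    "parse_taxonomy",
    "write_taxonomy",
    "TAXONOMY_RANKS",
]

TAXONOMY_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


class FormatError(ValueError):
    """Raised on malformed input in any of the supported text formats."""


@dataclass
class ProteinRecord:
    """An amino-acid transposase sequence, optionally tied to its host."""

    id: str
    residues: str
    host_species: Optional[str] = None
    host_lineage_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"protein record {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class NucRecord:
    """A nucleotide element sequence with optional genomic flanks.

    ``bases`` holds the element itself (conventionally TIR to TIR for a
    full-length transposon); ``flank5``/``flank3`` hold host sequence
    immediately outside the element, used for target-site-duplication
    checks.
    """

    id: str
    bases: str
    flank5: str = ""
    flank3: str = ""

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValueError(f"nucleotide record {self.id!r} has empty sequence")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class HitRecord:
    """One row of a 12-column BLAST tabular hit table.

    Coordinates are 1-based inclusive as printed by BLAST; a subject hit
    with ``s_start > s_end`` is on the minus strand.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: q_start > q_end")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("pct_identity outside [0, 100]")
        if self.aln_length < 1:
            raise ValueError("aln_length must be >= 1")

    @property
    def strand(self) -> str:
        return "-" if self.s_start > self.s_end else "+"

    @property
    def query_interval(self) -> tuple[int, int]:
        """Query span as a 0-based half-open interval."""
        return (self.q_start - 1, self.q_end)

    @property
    def subject_interval(self) -> tuple[int, int]:
        """Subject span as 0-based half-open (min, max), strand-normalized."""
        lo, hi = sorted((self.s_start, self.s_end))
        return (lo - 1, hi)

    @property
    def query_span(self) -> int:
        return self.q_end - self.q_start + 1


@dataclass
class TaxonTable:
    """Host lineages keyed by lineage_id, ranks ordered broad to narrow."""

    rows: dict[str, dict[str, str]] = field(default_factory=dict)

    def add(self, lineage_id: str, **ranks: str) -> None:
        if lineage_id in self.rows:
            raise ValueError(f"duplicate lineage_id {lineage_id!r}")
        self.rows[lineage_id] = {r: ranks.get(r, "") for r in TAXONOMY_RANKS}

    def rank(self, lineage_id: str, rank: str) -> str:
        return self.rows[lineage_id][rank]

    def lineage(self, lineage_id: str) -> tuple[str, ...]:
        row = self.rows[lineage_id]
        return tuple(row[r] for r in TAXONOMY_RANKS)

    def divergence_rank(self, a: str, b: str) -> Optional[str]:
        """Broadest rank at which two lineages differ, or None if identical.

        Empty strings (unknown below the deepest known rank) never count
        as a difference.
        """
        for r in TAXONOMY_RANKS:
            va, vb = self.rows[a][r], self.rows[b][r]
            if va and vb and va != vb:
                return r
        return None

    def differ_at_or_above(self, a: str, b: str, rank: str) -> bool:
        """True if the two lineages differ at ``rank`` or a broader rank."""
        idx = TAXONOMY_RANKS.index(rank)
        for r in TAXONOMY_RANKS[: idx + 1]:
            va, vb = self.rows[a][r], self.rows[b][r]
            if va and vb and va != vb:
                return True
        return False

    def __len__(self) -> int:
        return len(self.rows)

    def __contains__(self, lineage_id: str) -> bool:
        return lineage_id in self.rows


def _as_stream(stream: Union[str, TextIO]) -> TextIO:
    return io.StringIO(stream) if isinstance(stream, str) else stream


def parse_fasta(stream: Union[str, TextIO], kind: str = "protein"):
    """Parse FASTA text into Protein- or NucRecords.

    Sequence lines are concatenated, whitespace-stripped and upper-cased;
    record order is preserved.  ``kind`` is "protein" or "nucleotide".
    """
    cls = ProteinRecord if kind == "protein" else NucRecord
    records = []
    name: Optional[str] = None
    chunks: list[str] = []

    def flush() -> None:
        if name is not None:
            seq = "".join(chunks).upper()
            records.append(
                cls(name, seq) if kind == "protein" else cls(name, seq)
            )

    for line in _as_stream(stream):
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            name = line[1:].split()[0] if line[1:].split() else line[1:]
            chunks = []
        else:
            if name is None:
                raise FormatError("sequence line before any FASTA header")
            chunks.append(line.replace(" ", ""))
    flush()
    return records


def write_fasta(records: Iterable[Union[ProteinRecord, NucRecord]], width: int = 70) -> str:
    out = []
    for rec in records:
        seq = rec.residues if isinstance(rec, ProteinRecord) else rec.bases
        out.append(f">{rec.id}")
        for i in range(0, len(seq), width):
            out.append(seq[i : i + width])
    return "\n".join(out) + "\n" if out else ""


def parse_hit_table(stream: Union[str, TextIO]) -> list[HitRecord]:
    """Parse 12-column BLAST tabular (outfmt 6) text; '#' lines are comments."""
    hits = []
    for lineno, line in enumerate(_as_stream(stream), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 12:
            raise FormatError(
                f"line {lineno}: expected 12 tab-separated columns, got {len(cols)}"
            )
        try:
            hits.append(
                HitRecord(
                    query_id=cols[0],
                    subject_id=cols[1],
                    pct_identity=float(cols[2]),
                    aln_length=int(cols[3]),
                    mismatches=int(cols[4]),
                    gap_opens=int(cols[5]),
                    q_start=int(cols[6]),
                    q_end=int(cols[7]),
                    s_start=int(cols[8]),
                    s_end=int(cols[9]),
                    evalue=float(cols[10]),
                    bitscore=float(cols[11]),
                )
            )
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
    return hits


def write_hit_table(hits: Iterable[HitRecord]) -> str:
    rows = []
    for h in hits:
        rows.append(
            "\t".join(
                [
                    h.query_id,
                    h.subject_id,
                    f"{h.pct_identity:.1f}",
                    str(h.aln_length),
                    str(h.mismatches),
                    str(h.gap_opens),
                    str(h.q_start),
                    str(h.q_end),
                    str(h.s_start),
                    str(h.s_end),
                    f"{h.evalue:.2g}",
                    f"{h.bitscore:.1f}",
                ]
            )
        )
    return "\n".join(rows) + "\n" if rows else ""


def parse_newick(stream: Union[str, TextIO]) -> PhyloTree:
    """Parse one Newick string; numeric internal-node labels become supports."""
    text = _as_stream(stream).read()
    if text.count("(") != text.count(")"):
        raise FormatError("unbalanced parentheses in Newick input")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise FormatError(f"Newick parse error: {exc}") from exc

    def convert(dnode) -> PhyloNode:
        node = PhyloNode()
        if dnode.taxon is not None:
            node.name = dnode.taxon.label
        elif dnode.label is not None:
            try:
                node.support = float(dnode.label)
            except ValueError:
                node.name = dnode.label
        if dnode.edge.length is not None:
            node.length = float(dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return PhyloTree(convert(dtree.seed_node))


def write_newick(tree: PhyloTree) -> str:
    return tree.to_newick()


def parse_taxonomy(stream: Union[str, TextIO]) -> TaxonTable:
    """Parse a taxonomy TSV with header lineage_id + the seven ranks."""
    table = TaxonTable()
    lines = [l.rstrip("\n") for l in _as_stream(stream) if l.strip()]
    if not lines:
        return table
    header = lines[0].split("\t")
    expected = ["lineage_id", *TAXONOMY_RANKS]
    if [h.strip().lower() for h in header] != expected:
        raise FormatError(f"taxonomy header must be {expected}, got {header}")
    for lineno, line in enumerate(lines[1:], start=2):
        cols = line.split("\t")
        if len(cols) != len(expected):
            raise FormatError(f"taxonomy line {lineno}: wrong column count")
        table.add(cols[0], **dict(zip(TAXONOMY_RANKS, cols[1:])))
    return table


def write_taxonomy(table: TaxonTable) -> str:
    out = ["\t".join(["lineage_id", *TAXONOMY_RANKS])]
    for lid in table.rows:
        out.append("\t".join([lid, *table.lineage(lid)]))
    return "\n".join(out) + "\n"
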