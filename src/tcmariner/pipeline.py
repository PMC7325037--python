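"""End-to-end orchestration: filter -> profile-align -> motif/family ->
tree -> clade groups -> tanglegram -> optional census and HTT screen.

Stage boundaries are file-level: every stage writes a TSV (or Newick) so
any stage can be rerun from its predecessor's outputs.  Reruns with an
identical config and inputs are byte-identical — the log carries no
timestamps and every iteration order is deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import cophylogeny, copy_census, element_annotate, homology_filter, motif, phylo, seqio
from .alignment import SeedProfile, align_to_profile

__all__ = ["RunConfig", "run_analysis"]


@dataclass
class RunConfig:
    """Paths, thresholds, seed and stage toggles for one analysis run."""

    out_dir: str
    proteins_fasta: Optional[str] = None
    hits_table: Optional[str] = None
    query_lengths: dict[str, int] = field(default_factory=dict)
    profile_fasta: Optional[str] = None
    catalytic_columns: Optional[tuple[int, int, int]] = None
    tree_newick: Optional[str] = None  # externally computed tree, used as-is
    taxonomy_tsv: Optional[str] = None
    links_tsv: Optional[str] = None
    elements_fasta: Optional[str] = None
    element_hits_table: Optional[str] = None
    outgroup_prefix: Optional[str] = None

    seed: int = 0
    min_identity_pct: float = 50.0
    min_query_coverage: float = 0.5
    bootstrap_reps: int = 100
    min_clade_support: float = 70.0

    run_filter: bool = True
    run_motif: bool = True
    run_tree: bool = True
    run_tanglegram: bool = True
    run_census: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "catalytic_columns" in data and data["catalytic_columns"] is not None:
            data["catalytic_columns"] = tuple(data["catalytic_columns"])
        return cls(**data)


def _load_profile(cfg: RunConfig) -> SeedProfile:
    rows = seqio.parse_fasta(Path(cfg.profile_fasta).read_text(), kind="protein")
    return SeedProfile(
        ids=[r.id for r in rows],
        rows=[r.residues for r in rows],
        catalytic_columns=tuple(cfg.catalytic_columns),
    )


def run_analysis(cfg: RunConfig) -> dict:
    """Execute the enabled stages; returns the summary dict.

    Every stage logs its parameters and input/output counts to
    ``run.log`` in the output directory and writes its table there.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    summary: dict = {"config": {"seed": cfg.seed}}

    def log(msg: str) -> None:
        log_lines.append(msg)

    def fail(stage: str, exc: Exception) -> None:
        log(f"[{stage}] FAILED: {exc}")
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    proteins: list[seqio.ProteinRecord] = []
    if cfg.proteins_fasta:
        proteins = seqio.parse_fasta(Path(cfg.proteins_fasta).read_text(), "protein")
        log(f"[input] proteins={len(proteins)}")

    # -- stage: hit filtering ------------------------------------------------
    if cfg.run_filter and cfg.hits_table:
        try:
            hits = seqio.parse_hit_table(Path(cfg.hits_table).read_text())
            qlens = dict(cfg.query_lengths) or {p.id: len(p) for p in proteins}
            thresholds = homology_filter.RetentionThresholds(
                cfg.min_identity_pct, cfg.min_query_coverage
            )
            kept = homology_filter.filter_hits(hits, qlens, thresholds)
            (out / "filtered_hits.tsv").write_text(seqio.write_hit_table(kept))
            log(
                f"[filter] min_id={cfg.min_identity_pct} min_cov={cfg.min_query_coverage} "
                f"in={len(hits)} kept={len(kept)}"
            )
            summary["filter"] = {"input_hits": len(hits), "retained_hits": len(kept)}
        except Exception as exc:
            fail("filter", exc)

    # -- stage: motif classification ----------------------------------------
    aligned_rows: dict[str, str] = {}
    if cfg.run_motif and proteins and cfg.profile_fasta:
        try:
            profile = _load_profile(cfg)
            rows = ["id\tsignature\tspacing\tcandidates"]
            family_counts: dict[str, int] = {}
            for p in proteins:
                aq = align_to_profile(p.id, p.residues, profile)
                aligned_rows[p.id] = aq.gapped_row(profile)
                call = motif.detect_motif(aq, profile)
                if isinstance(call, motif.MotifNotFound):
                    rows.append(f"{p.id}\tNA\tNA\t{call.reason}")
                    continue
                fam = motif.assign_family(call.signature)
                cands = ",".join(sorted(fam.candidate_families))
                rows.append(f"{p.id}\t{call.signature}\t{call.spacing}\t{cands}")
                for c in fam.candidate_families:
                    family_counts[c] = family_counts.get(c, 0) + 1
            (out / "motifs.tsv").write_text("\n".join(rows) + "\n")
            log(f"[motif] sequences={len(proteins)} calls={len(rows) - 1}")
            summary["motif"] = {"family_counts": dict(sorted(family_counts.items()))}
        except Exception as exc:
            fail("motif", exc)

    # -- stage: tree (import or infer) --------------------------------------
    tree = None
    if cfg.run_tree:
        try:
            if cfg.tree_newick:
                tree = seqio.parse_newick(Path(cfg.tree_newick).read_text())
                log(f"[tree] imported leaves={len(tree.leaves())}")
            elif aligned_rows:
                ids = sorted(aligned_rows)
                aln = [aligned_rows[i] for i in ids]
                tree = phylo.bootstrap_supports(
                    aln, ids, n_reps=cfg.bootstrap_reps, seed=cfg.seed
                )
                log(
                    f"[tree] nj leaves={len(ids)} bootstrap_reps={cfg.bootstrap_reps} "
                    f"seed={cfg.seed}"
                )
            if tree is not None:
                if cfg.outgroup_prefix:
                    og = [
                        n for n in tree.leaf_names() if n.startswith(cfg.outgroup_prefix)
                    ]
                    if og:
                        tree = phylo.root_with_outgroup(tree, og)
                        log(
                            f"[tree] rooted on {len(og)} outgroup leaves "
                            f"monophyletic={tree.outgroup_monophyletic}"
                        )
                (out / "tree.nwk").write_text(seqio.write_newick(tree) + "\n")
                groups, isolated = phylo.extract_supported_clades(
                    tree, cfg.min_clade_support
                )
                rows = ["label\tsupport\tmembers"]
                for g in groups:
                    rows.append(f"{g.label}\t{g.support:.1f}\t{','.join(g.members)}")
                (out / "clades.tsv").write_text("\n".join(rows) + "\n")
                log(f"[clades] groups={len(groups)} isolated={len(isolated)}")
                summary["clades"] = {
                    "n_groups": len(groups),
                    "n_isolated": len(isolated),
                }
        except Exception as exc:
            fail("tree", exc)

    # -- stage: tanglegram ---------------------------------------------------
    if cfg.run_tanglegram and tree is not None and cfg.taxonomy_tsv and cfg.links_tsv:
        try:
            taxonomy = seqio.parse_taxonomy(Path(cfg.taxonomy_tsv).read_text())
            links = cophylogeny.LinkSet(
                [
                    tuple(line.split("\t"))
                    for line in Path(cfg.links_tsv).read_text().splitlines()
                    if line.strip() and not line.startswith("#")
                ]
            )
            host_tree = cophylogeny.host_tree_from_taxonomy(taxonomy)
            result = cophylogeny.minimize_crossings(tree, host_tree, links)
            log(
                f"[tanglegram] links={len(links)} crossings={result.crossings} "
                f"normalized={result.normalized_crossings:.4f}"
            )
            summary["tanglegram"] = {
                "crossings": result.crossings,
                "normalized_crossings": round(result.normalized_crossings, 6),
            }
        except Exception as exc:
            fail("tanglegram", exc)

    # -- stage: copy census --------------------------------------------------
    if cfg.run_census and cfg.elements_fasta and cfg.element_hits_table:
        try:
            elements = seqio.parse_fasta(
                Path(cfg.elements_fasta).read_text(), "nucleotide"
            )
            hits = seqio.parse_hit_table(Path(cfg.element_hits_table).read_text())
            rows = ["element\tfull_length\tmite\tpartial\tnon_autonomous\tunclassified"]
            for el in elements:
                el_hits = [h for h in hits if h.query_id == el.id]
                ann = element_annotate.annotate(el)
                counts = copy_census.census(el_hits, el, ann)
                rows.append(
                    "\t".join(
                        [
                            el.id,
                            *(
                                str(counts[copy_census.CopyClass(c)])
                                for c in (
                                    "full_length",
                                    "mite",
                                    "partial",
                                    "non_autonomous",
                                    "unclassified",
                                )
                            ),
                        ]
                    )
                )
            (out / "census.tsv").write_text("\n".join(rows) + "\n")
            log(f"[census] elements={len(elements)} hits={len(hits)}")
            summary["census"] = {"n_elements": len(elements)}
        except Exception as exc:
            fail("census", exc)

    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    return summary
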