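"""TE-vs-host tanglegram: crossing count and crossing minimization.

The congruence between transposon phylogeny and host phylogeny is
quantified as the number of link crossings in a two-column tanglegram
after both trees' internal nodes have been rotated to minimize crossings
(alternating barycenter sweeps).  Perfect vertical inheritance with
congruent trees yields zero crossings; horizontal transfer introduces
links that no rotation can untangle.

The host tree is built from the taxonomy table as a rank hierarchy
(kingdom down to species), since host relationships enter the analysis at
the rank level, not as a molecular tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .phylo import PhyloNode, PhyloTree
from .seqio import TAXONOMY_RANKS, TaxonTable

__all__ = [
    "LinkSet",
    "TanglegramResult",
    "host_tree_from_taxonomy",
    "count_crossings",
    "minimize_crossings",
]


@dataclass
class LinkSet:
    """Tanglegram links: (TE leaf id, host leaf id), many-to-one allowed."""

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class TanglegramResult:
    left_order: list[str]
    right_order: list[str]
    crossings: int
    n_links: int

    @property
    def normalized_crossings(self) -> float:
        """Crossings over the number of link pairs, in [0, 1]."""
        max_pairs = self.n_links * (self.n_links - 1) // 2
        return self.crossings / max(1, max_pairs)


def host_tree_from_taxonomy(
    table: TaxonTable, deepest_rank: str = "species"
) -> PhyloTree:
    """Rank hierarchy as a tree; leaves are lineage_ids.

    Lineages identical down to ``deepest_rank`` still get distinct leaf
    nodes (one per lineage_id) under the shared taxon node.
    """
    depth = TAXONOMY_RANKS.index(deepest_rank) + 1
    root = PhyloNode(name="eukaryota")
    index: dict[tuple[str, ...], PhyloNode] = {}
    for lid in table.rows:
        path: list[str] = []
        node = root
        for rank in TAXONOMY_RANKS[:depth]:
            value = table.rank(lid, rank)
            if not value:
                break
            path.append(value)
            key = tuple(path)
            if key not in index:
                index[key] = node.add_child(PhyloNode(name=value))
            node = index[key]
        node.add_child(PhyloNode(name=lid))
    return PhyloTree(root)


def count_crossings(
    left_order: Sequence[str],
    right_order: Sequence[str],
    links: LinkSet | Iterable[tuple[str, str]],
) -> int:
    """Number of crossing link pairs.

    Two links (a, b) and (c, d) cross iff their endpoints are in opposite
    relative order on the two sides; links sharing a row on either side
    never cross.  Counted as strict inversions after sorting by
    (left, right), O(n log n).
    """
    lpos = {name: i for i, name in enumerate(left_order)}
    rpos = {name: i for i, name in enumerate(right_order)}
    pts = []
    for te, host in links:
        if te not in lpos:
            raise KeyError(f"link endpoint {te!r} not in left order")
        if host not in rpos:
            raise KeyError(f"link endpoint {host!r} not in right order")
        pts.append((lpos[te], rpos[host]))
    pts.sort()
    rights = [r for _, r in pts]

    # merge-sort inversion count, strict (> only): equal-left pairs are
    # already adjacent with rights ascending and contribute nothing.
    def sort_count(seq: list[int]) -> tuple[list[int], int]:
        if len(seq) <= 1:
            return seq, 0
        mid = len(seq) // 2
        a, ca = sort_count(seq[:mid])
        b, cb = sort_count(seq[mid:])
        merged, i, j, inv = [], 0, 0, 0
        while i < len(a) and j < len(b):
            if a[i] <= b[j]:
                merged.append(a[i])
                i += 1
            else:
                merged.append(b[j])
                j += 1
                inv += len(a) - i
        merged.extend(a[i:])
        merged.extend(b[j:])
        return merged, ca + cb + inv

    _, inv = sort_count(rights)
    return inv


def _leaf_order(root: PhyloNode) -> list[str]:
    return [l.name for l in root.leaves()]


def _barycenter_sweep(
    tree_root: PhyloNode,
    own_links: dict[str, list[str]],
    other_pos: dict[str, int],
) -> None:
    """Rotate children of every internal node by mean linked position on
    the fixed other side (stable; unlinked subtrees keep relative order)."""

    def visit(node: PhyloNode) -> tuple[float, int]:
        """Returns (sum of linked positions, link count) for the subtree."""
        if node.is_leaf:
            targets = own_links.get(node.name, [])
            s = float(sum(other_pos[t] for t in targets if t in other_pos))
            return s, len(targets)
        stats = [visit(c) for c in node.children]
        keyed = []
        for idx, (child, (s, k)) in enumerate(zip(node.children, stats)):
            bary = s / k if k else None
            keyed.append((bary, idx, child))
        linked = [b for b, _, _ in keyed if b is not None]
        fallback = sum(linked) / len(linked) if linked else 0.0
        keyed.sort(key=lambda t: (t[0] if t[0] is not None else fallback, t[1]))
        node.children = [c for _, _, c in keyed]
        return sum(s for s, _ in stats), sum(k for _, k in stats)

    visit(tree_root)


def minimize_crossings(
    te_tree: PhyloTree,
    host_tree: PhyloTree,
    links: LinkSet,
    max_sweeps: int = 20,
) -> TanglegramResult:
    """Alternating barycenter sweeps; never returns more crossings than
    the initial layout.  Trees are not modified (working copies are used).
    """
    from .phylo import _copy_subtree

    te_to_hosts: dict[str, list[str]] = {}
    host_to_tes: dict[str, list[str]] = {}
    for te, host in links:
        te_to_hosts.setdefault(te, []).append(host)
        host_to_tes.setdefault(host, []).append(te)

    def crossings_now(left, right) -> int:
        return count_crossings(_leaf_order(left), _leaf_order(right), links)

    def greedy_swaps(left, right) -> None:
        """Sifting pass: adjacent child swaps kept when they strictly
        reduce crossings; escapes equal-barycenter local optima."""
        improved = True
        rounds = 0
        while improved and rounds < max_sweeps:
            improved = False
            rounds += 1
            for root in (left, right):
                for node in root.preorder():
                    for k in range(len(node.children) - 1):
                        before = crossings_now(left, right)
                        node.children[k], node.children[k + 1] = (
                            node.children[k + 1],
                            node.children[k],
                        )
                        if crossings_now(left, right) < before:
                            improved = True
                        else:
                            node.children[k], node.children[k + 1] = (
                                node.children[k + 1],
                                node.children[k],
                            )

    def run(first_left: bool) -> tuple[int, list[str], list[str]]:
        left = _copy_subtree(te_tree.root)
        right = _copy_subtree(host_tree.root)
        lo, ro = _leaf_order(left), _leaf_order(right)
        best = (count_crossings(lo, ro, links), lo, ro)
        seen = {(tuple(lo), tuple(ro))}
        for _ in range(max_sweeps):
            order = (
                [(left, te_to_hosts, right), (right, host_to_tes, left)]
                if first_left
                else [(right, host_to_tes, left), (left, te_to_hosts, right)]
            )
            for tree_root, own_links, other_root in order:
                other_pos = {n: i for i, n in enumerate(_leaf_order(other_root))}
                _barycenter_sweep(tree_root, own_links, other_pos)
            lo, ro = _leaf_order(left), _leaf_order(right)
            cross = count_crossings(lo, ro, links)
            if cross < best[0]:
                best = (cross, lo, ro)
            key = (tuple(lo), tuple(ro))
            if key in seen:
                break  # layout cycle: no further progress possible
            seen.add(key)
        greedy_swaps(left, right)
        lo, ro = _leaf_order(left), _leaf_order(right)
        cross = count_crossings(lo, ro, links)
        if cross < best[0]:
            best = (cross, lo, ro)
        return best

    best_cross, best_l, best_r = min(run(True), run(False), key=lambda t: t[0])
    return TanglegramResult(best_l, best_r, best_cross, len(links))
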