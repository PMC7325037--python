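"""Desk-scale tree inference and manipulation.

Distance matrices (p-distance with pairwise gap deletion), canonical
neighbor-joining with deterministic tie-breaking, nonparametric bootstrap
supports, outgroup rooting and support-thresholded clade extraction.
Externally computed trees enter through :func:`tcmariner.seqio.parse_newick`
and are first-class inputs to every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "PhyloNode",
    "PhyloTree",
    "CladeGroup",
    "p_distance_matrix",
    "nj_tree",
    "bootstrap_supports",
    "root_with_outgroup",
    "extract_supported_clades",
]


class PhyloNode:
    """A tree node: children, optional name, branch length, support."""

    __slots__ = ("name", "length", "support", "children", "parent")

    def __init__(
        self,
        name: Optional[str] = None,
        length: Optional[float] = None,
        support: Optional[float] = None,
    ) -> None:
        self.name = name
        self.length = length
        self.support = support
        self.children: list[PhyloNode] = []
        self.parent: Optional[PhyloNode] = None

    def add_child(self, child: "PhyloNode") -> "PhyloNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["PhyloNode"]:
        if self.is_leaf:
            return [self]
        out = []
        stack = [self]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n)
            else:
                stack.extend(reversed(n.children))
        return out

    def preorder(self):
        stack = [self]
        while stack:
            n = stack.pop()
            yield n
            stack.extend(reversed(n.children))

    def _newick(self) -> str:
        if self.is_leaf:
            label = self.name or ""
        else:
            inner = ",".join(c._newick() for c in self.children)
            if self.support is not None:
                sup = self.support
                label = f"({inner}){sup:g}"
            else:
                label = f"({inner}){self.name or ''}"
        if self.length is not None:
            label += f":{self.length:g}"
        return label


class PhyloTree:
    """A (rooted or unrooted-with-trifurcation) phylogenetic tree."""

    def __init__(self, root: PhyloNode) -> None:
        self.root = root
        self.outgroup_monophyletic: Optional[bool] = None

    def leaves(self) -> list[PhyloNode]:
        return self.root.leaves()

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def preorder(self):
        return self.root.preorder()

    def to_newick(self) -> str:
        return self.root._newick() + ";"

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial leaf bipartitions, each as the smaller-side-canonical
        frozenset pair; used for topology comparison and bootstrap counting."""
        all_leaves = frozenset(self.leaf_names())
        parts: set[frozenset[frozenset[str]]] = set()
        for node in self.preorder():
            if node is self.root or node.is_leaf:
                continue
            side = frozenset(l.name for l in node.leaves())
            if 1 < len(side) < len(all_leaves) - 1:
                parts.add(frozenset((side, all_leaves - side)))
        return parts  # type: ignore[return-value]

    def find(self, name: str) -> PhyloNode:
        for leaf in self.leaves():
            if leaf.name == name:
                return leaf
        raise KeyError(f"leaf {name!r} not in tree")


@dataclass
class CladeGroup:
    """A supported clade: its member leaves, support and a label."""

    members: tuple[str, ...]
    support: float
    label: str = ""


def p_distance_matrix(
    aln: Sequence[str], ids: Optional[Sequence[str]] = None
) -> tuple[np.ndarray, list[str]]:
    """Pairwise p-distances with pairwise deletion of gap columns.

    ``aln`` is a list of equal-length gapped sequences.  d(i,j) =
    mismatches / compared columns where a column is compared iff neither
    row holds a gap ('-' or '.').  A pair with zero comparable columns is
    an error naming the pair.
    """
    if len(aln) < 2:
        raise ValueError("need at least 2 sequences")
    length = len(aln[0])
    if any(len(s) != length for s in aln):
        raise ValueError("aligned sequences must have equal length")
    ids = list(ids) if ids is not None else [f"seq{i}" for i in range(len(aln))]

    arr = np.frombuffer("".join(s.upper() for s in aln).encode(), dtype="S1").reshape(
        len(aln), length
    )
    gap = (arr == b"-") | (arr == b".")
    n = len(aln)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            m = int(ok.sum())
            if m == 0:
                raise ValueError(f"no comparable columns between {ids[i]} and {ids[j]}")
            mism = int((arr[i, ok] != arr[j, ok]).sum())
            d[i, j] = d[j, i] = mism / m
    return d, ids


def nj_tree(d: np.ndarray, ids: Sequence[str]) -> PhyloTree:
    """Canonical neighbor-joining (Saitou & Nei, Q-criterion).

    Ties in Q broken by the smallest (i, j) index pair over the original
    taxon ordering; negative branch lengths are clamped to zero with the
    deficit moved to the sister branch.  The returned tree is unrooted,
    represented with a trifurcating root.
    """
    d = np.asarray(d, dtype=float)
    n = d.shape[0]
    if d.shape != (n, n) or n < 3:
        raise ValueError("need a square matrix over >= 3 taxa")
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")

    nodes = [PhyloNode(name) for name in ids]
    active = list(range(n))
    dm = d.copy()

    while len(active) > 3:
        m = len(active)
        sums = {i: sum(dm[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dm[i, j] - sums[i] - sums[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        vi = 0.5 * dm[i, j] + (sums[i] - sums[j]) / (2 * (m - 2))
        vj = dm[i, j] - vi
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        parent = PhyloNode()
        nodes[i].length = vi
        nodes[j].length = vj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # reuse slot i for the new node
        for k in active:
            if k in (i, j):
                continue
            dm[i, k] = dm[k, i] = 0.5 * (dm[i, k] + dm[j, k] - dm[i, j])
        nodes[i] = parent
        active.remove(j)

    i, j, k = active
    root = PhyloNode()
    li = 0.5 * (dm[i, j] + dm[i, k] - dm[j, k])
    lj = 0.5 * (dm[i, j] + dm[j, k] - dm[i, k])
    lk = 0.5 * (dm[i, k] + dm[j, k] - dm[i, j])
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(ln, 0.0)
        root.add_child(nodes[idx])
    return PhyloTree(root)


def bootstrap_supports(
    aln: Sequence[str],
    ids: Sequence[str],
    n_reps: int,
    seed: int,
) -> PhyloTree:
    """NJ tree on the full alignment with bootstrap supports.

    Columns are resampled with replacement per replicate with one seeded
    generator; the support of an internal edge is the percentage of
    replicate trees containing the same bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    length = len(aln[0])
    if length < 2:
        raise ValueError("alignment must have at least 2 columns")
    rng = np.random.default_rng(seed)

    d, _ = p_distance_matrix(aln, ids)
    tree = nj_tree(d, ids)

    counts: dict[frozenset, int] = {}
    cols = [[s[c] for s in aln] for c in range(length)]
    for _ in range(n_reps):
        pick = rng.integers(0, length, size=length)
        rep = ["".join(cols[c][r] for c in pick) for r in range(len(aln))]
        try:
            dr, _ = p_distance_matrix(rep, ids)
            rep_tree = nj_tree(dr, ids)
        except ValueError:
            continue  # replicate with an incomparable pair carries no signal
        for bp in rep_tree.bipartitions():
            counts[bp] = counts.get(bp, 0) + 1

    all_leaves = frozenset(ids)
    for node in tree.preorder():
        if node is tree.root or node.is_leaf:
            continue
        side = frozenset(l.name for l in node.leaves())
        if 1 < len(side) < len(all_leaves) - 1:
            bp = frozenset((side, all_leaves - side))
            node.support = 100.0 * counts.get(bp, 0) / n_reps
    return tree


def _copy_subtree(node: PhyloNode, skip: Optional[PhyloNode] = None) -> PhyloNode:
    new = PhyloNode(node.name, node.length, node.support)
    for c in node.children:
        if c is skip:
            continue
        new.add_child(_copy_subtree(c, skip))
    return new


def _reroot_at_edge(tree: PhyloTree, child: PhyloNode) -> PhyloTree:
    """Root on the edge above ``child``, bisecting its branch length.

    Edge attributes (length, support) are stored on the child side of an
    edge; when the tree is re-hung the node standing in for the old parent
    takes the attributes of the edge it is now reached through.
    """
    half = (child.length or 0.0) / 2.0

    def rehang(node: PhyloNode, coming_from: PhyloNode) -> PhyloNode:
        # `new` represents `node`, reached through the old edge
        # node<->coming_from whose attributes sat on coming_from.
        new = PhyloNode(node.name, coming_from.length, coming_from.support)
        for c in node.children:
            if c is not coming_from:
                new.add_child(_copy_subtree(c))
        if node.parent is not None:
            new.add_child(rehang(node.parent, node))
        return new

    root = PhyloNode()
    top = _copy_subtree(child)
    top.length = half
    root.add_child(top)
    below = rehang(child.parent, child)
    below.length = half
    below.support = child.support
    root.add_child(below)
    _suppress_unary(root)
    return PhyloTree(root)


def _suppress_unary(root: PhyloNode) -> None:
    """Collapse internal nodes with a single child (lengths add up)."""
    for node in list(root.preorder()):
        while len(node.children) == 1 and node is not root:
            only = node.children[0]
            node.name = only.name
            node.support = node.support if only.support is None else only.support
            if only.length is not None or node.length is not None:
                node.length = (node.length or 0.0) + (only.length or 0.0)
            node.children = only.children
            for c in node.children:
                c.parent = node
    while len(root.children) == 1 and root.children[0].children:
        only = root.children[0]
        root.children = only.children
        for c in root.children:
            c.parent = root


def root_with_outgroup(tree: PhyloTree, outgroup_ids: Iterable[str]) -> PhyloTree:
    """Root on the edge separating the outgroup from the ingroup.

    If the outgroup is not monophyletic in the unrooted tree, the root is
    placed on the edge maximizing the outgroup fraction on the outgroup
    side and the result is flagged (``outgroup_monophyletic = False``).
    """
    og = set(outgroup_ids)
    if not og:
        raise ValueError("outgroup_ids must be nonempty")
    names = set(tree.leaf_names())
    unknown = og - names
    if unknown:
        raise KeyError(f"outgroup ids not in tree: {sorted(unknown)}")
    n_total = len(names)

    best = None  # (is_perfect, og_fraction, og_count, -side_size, node)
    for node in tree.preorder():
        if node is tree.root:
            continue
        side = set(l.name for l in node.leaves())
        for candidate, size in ((side, len(side)), (names - side, n_total - len(side))):
            if size == 0 or size == n_total:
                continue
            og_in = len(og & candidate)
            if og_in == 0:
                continue
            perfect = og_in == len(og) and size == len(og)
            frac = og_in / size
            key = (perfect, frac, og_in, -size)
            if best is None or key > best[0]:
                best = (key, node)
    key, node = best
    rooted = _reroot_at_edge(tree, node)
    rooted.outgroup_monophyletic = bool(key[0]) or (
        key[1] == 1.0 and key[2] == len(og)
    )
    return rooted


def extract_supported_clades(
    tree: PhyloTree, min_support: float = 70.0
) -> tuple[list[CladeGroup], list[str]]:
    """Maximal clades with support >= min_support, plus isolated leaves.

    Top-down: a node with qualifying support becomes one group and its
    interior is not descended into, so every leaf belongs to at most one
    group.  Leaves in no supported clade are returned separately.
    """
    groups: list[CladeGroup] = []
    grouped: set[str] = set()

    def visit(node: PhyloNode) -> None:
        for child in node.children:
            if child.is_leaf:
                continue
            if child.support is not None and child.support >= min_support:
                members = tuple(sorted(l.name for l in child.leaves()))
                groups.append(
                    CladeGroup(members, float(child.support), f"group_{len(groups) + 1}")
                )
                grouped.update(members)
            else:
                visit(child)

    visit(tree.root)
    isolated = sorted(set(tree.leaf_names()) - grouped)
    return groups, isolated
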