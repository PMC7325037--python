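"""Distance matrices, neighbor-joining, bootstrap, rooting and clade
extraction, cross-checked against closed forms and scikit-bio."""

import numpy as np
import pytest

from tcmariner.phylo import (
    bootstrap_supports,
    extract_supported_clades,
    nj_tree,
    p_distance_matrix,
    root_with_outgroup,
)


def random_additive(rng, n):
    """Random binary tree -> (distance matrix, set of bipartitions)."""
    parentof, edges = {}, {}
    avail, nid = list(range(n)), n
    while len(avail) > 1:
        i, j = sorted(rng.choice(len(avail), size=2, replace=False))
        a, b = avail[j], avail[i]
        edges[a], edges[b] = rng.uniform(0.1, 1.0), rng.uniform(0.1, 1.0)
        parentof[a], parentof[b] = nid, nid
        avail = [x for x in avail if x not in (a, b)] + [nid]
        nid += 1

    def path(x):
        p = {}
        while x in parentof:
            p[x] = edges[x]
            x = parentof[x]
        return p

    d = np.zeros((n, n))
    for x in range(n):
        for y in range(x + 1, n):
            px, py = path(x), path(y)
            dist = sum(v for k, v in px.items() if k not in py) + sum(
                v for k, v in py.items() if k not in px
            )
            d[x, y] = d[y, x] = dist

    # bipartitions: leaves below each internal edge
    below = {i: {i} for i in range(n)}
    for node in sorted(parentof.values()):
        below[node] = set()
    for child, par in parentof.items():
        pass
    children = {}
    for child, par in parentof.items():
        children.setdefault(par, []).append(child)

    def leaves_below(x):
        if x < n:
            return {x}
        out = set()
        for c in children[x]:
            out |= leaves_below(c)
        return out

    all_leaves = frozenset(f"L{i}" for i in range(n))
    parts = set()
    for x in children:
        side = frozenset(f"L{i}" for i in leaves_below(x))
        if 1 < len(side) < n - 1:
            parts.add(frozenset((side, all_leaves - side)))
    return d, parts


def tree_distances(tree):
    names = sorted(tree.leaf_names())
    idx = {n: i for i, n in enumerate(names)}
    dm = np.zeros((len(names), len(names)))
    leaves = {l.name: l for l in tree.leaves()}

    def ancestors(node):
        out = []
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            anc_b = {id(x) for x in ancestors(leaves[b])}
            da, node = 0.0, leaves[a]
            while id(node) not in anc_b:
                da += node.length or 0.0
                node = node.parent
            lca = node
            db, node = 0.0, leaves[b]
            while node is not lca:
                db += node.length or 0.0
                node = node.parent
            dm[idx[a], idx[b]] = dm[idx[b], idx[a]] = da + db
    return dm, names


class TestPDistance:
    def test_identical_rows_zero(self):
        d, _ = p_distance_matrix(["ACGT", "ACGT", "ACGT"])
        assert np.all(d == 0)

    def test_simple_arithmetic(self):
        d, _ = p_distance_matrix(["AAAA", "AAAT"])
        assert d[0, 1] == 0.25

    def test_pairwise_deletion(self):
        d, _ = p_distance_matrix(["A-GT", "ACGA"])
        assert d[0, 1] == pytest.approx(1 / 3)

    def test_no_comparable_columns_names_pair(self):
        with pytest.raises(ValueError, match="x.*y|y.*x"):
            p_distance_matrix(["A---", "-CGT"], ids=["x", "y"])

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            n, L = int(rng.integers(2, 6)), int(rng.integers(4, 30))
            aln = [
                "".join(rng.choice(list("ACGT-"), size=L, p=[0.22, 0.22, 0.22, 0.22, 0.12]))
                for _ in range(n)
            ]
            try:
                d, _ = p_distance_matrix(aln)
            except ValueError:
                continue
            for i in range(n):
                for j in range(n):
                    comp = [
                        (x, y)
                        for x, y in zip(aln[i], aln[j])
                        if x not in "-." and y not in "-."
                    ]
                    expect = sum(1 for x, y in comp if x != y) / len(comp)
                    assert d[i, j] == pytest.approx(expect)


class TestNJ:
    def test_three_taxon_closed_form(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = nj_tree(d, ["a", "b", "c"])
        lengths = {l.name: l.length for l in tree.leaves()}
        assert lengths["a"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["b"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["c"] == pytest.approx((4 + 5 - 3) / 2)

    def test_four_taxon_additive_recovery(self):
        rng = np.random.default_rng(2)
        d, parts = random_additive(rng, 4)
        tree = nj_tree(d, [f"L{i}" for i in range(4)])
        assert tree.bipartitions() == parts
        dm, names = tree_distances(tree)
        order = [names.index(f"L{i}") for i in range(4)]
        assert np.allclose(dm[np.ix_(order, order)], d, atol=1e-9)

    def test_six_taxon_additive_topology_recovery(self):
        """NJ is consistent on additive input: 50/50 random trees."""
        rng = np.random.default_rng(3)
        for _ in range(50):
            d, parts = random_additive(rng, 6)
            tree = nj_tree(d, [f"L{i}" for i in range(6)])
            assert tree.bipartitions() == parts

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0, 1, 2], [9, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError):
            nj_tree(d, list("abc"))

    def test_agrees_with_scikit_bio_topology(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(4)
        for _ in range(10):
            n = int(rng.integers(5, 9))
            d, _ = random_additive(rng, n)
            ids = [f"L{i}" for i in range(n)]
            mine = nj_tree(d, ids)
            other = skbio_nj(DistanceMatrix(d, ids))
            full = frozenset(ids)
            theirs = set()
            for node in other.non_tips():
                side = frozenset(t.name for t in node.tips())
                if 1 < len(side) < n - 1:
                    theirs.add(frozenset((side, full - side)))
            assert mine.bipartitions() == theirs


class TestBootstrap:
    def _aln(self, rng, n_per_clade=4, L=120, frac=0.5):
        """Two clades differing at a fraction of columns."""
        base = rng.choice(list("ACGT"), size=L)
        alt = base.copy()
        flip = rng.choice(L, size=int(L * frac), replace=False)
        for c in flip:
            alt[c] = "ACGT"[("ACGT".index(alt[c]) + 1) % 4]
        rows, ids = [], []
        for k in range(n_per_clade):
            rows.append("".join(base))
            ids.append(f"a{k}")
        for k in range(n_per_clade):
            rows.append("".join(alt))
            ids.append(f"b{k}")
        return rows, ids

    def test_strong_signal_high_support(self):
        rng = np.random.default_rng(10)
        rows, ids = self._aln(rng)
        tree = bootstrap_supports(rows, ids, n_reps=100, seed=1)
        full = frozenset(ids)
        focal = frozenset({frozenset(f"a{k}" for k in range(4)), frozenset(f"b{k}" for k in range(4))})
        supports = {}
        for node in tree.preorder():
            if node.is_leaf or node is tree.root or node.support is None:
                continue
            side = frozenset(l.name for l in node.leaves())
            supports[frozenset((side, full - side))] = node.support
        assert supports.get(focal, 0) >= 99

    def test_single_rep_supports_binary(self):
        rng = np.random.default_rng(12)
        rows, ids = self._aln(rng, n_per_clade=3)
        tree = bootstrap_supports(rows, ids, n_reps=1, seed=5)
        sups = [n.support for n in tree.preorder() if n.support is not None]
        assert sups and all(s in (0.0, 100.0) for s in sups)

    def test_seed_determinism(self):
        rng = np.random.default_rng(13)
        rows, ids = self._aln(rng, frac=0.1)
        t1 = bootstrap_supports(rows, ids, n_reps=30, seed=7)
        t2 = bootstrap_supports(rows, ids, n_reps=30, seed=7)
        s1 = sorted(n.support for n in t1.preorder() if n.support is not None)
        s2 = sorted(n.support for n in t2.preorder() if n.support is not None)
        assert s1 == s2


class TestRooting:
    def test_single_leaf_outgroup_bisects_pendant_edge(self):
        rng = np.random.default_rng(14)
        d, _ = random_additive(rng, 4)
        tree = nj_tree(d, list("abcd"))
        rooted = root_with_outgroup(tree, {"a"})
        kids = rooted.root.children
        assert len(kids) == 2
        (og,) = [k for k in kids if k.is_leaf and k.name == "a"]
        other = [k for k in kids if k is not og][0]
        assert og.length == pytest.approx(other.length)

    def test_monophyletic_outgroup_makes_ingroup_a_clade(self):
        rng = np.random.default_rng(15)
        for _ in range(10):
            d, _ = random_additive(rng, 6)
            ids = [f"L{i}" for i in range(6)]
            tree = nj_tree(d, ids)
            # pick a cherry as outgroup so it is monophyletic
            cherry = None
            for node in tree.preorder():
                if not node.is_leaf and len(node.children) == 2 and all(
                    c.is_leaf for c in node.children
                ):
                    cherry = {c.name for c in node.children}
                    break
            if cherry is None:
                continue
            rooted = root_with_outgroup(tree, cherry)
            assert rooted.outgroup_monophyletic
            sides = [set(l.name for l in k.leaves()) for k in rooted.root.children]
            assert cherry in sides

    def test_rerooting_preserves_bipartitions(self):
        rng = np.random.default_rng(16)
        for _ in range(10):
            n = int(rng.integers(6, 21))
            d, _ = random_additive(rng, n)
            ids = [f"L{i}" for i in range(n)]
            tree = nj_tree(d, ids)
            og = {f"L{int(rng.integers(0, n))}"}
            rooted = root_with_outgroup(tree, og)
            assert rooted.bipartitions() == tree.bipartitions()

    def test_unknown_outgroup_id(self):
        rng = np.random.default_rng(17)
        d, _ = random_additive(rng, 4)
        tree = nj_tree(d, list("abcd"))
        with pytest.raises(KeyError):
            root_with_outgroup(tree, {"zzz"})


class TestSupportedClades:
    def _supported_tree(self, supports):
        """Fixed 6-leaf rooted tree: ((a,b)s0,(c,(d,e)s2)s1,f)."""
        from tcmariner.seqio import parse_newick

        s0, s1, s2 = supports
        return parse_newick(f"((a,b){s0},(c,(d,e){s2}){s1},f);")

    def test_all_high_supports_one_group_per_root_child(self):
        tree = self._supported_tree((100, 100, 100))
        groups, isolated = extract_supported_clades(tree, 70)
        members = sorted(g.members for g in groups)
        assert members == [("a", "b"), ("c", "d", "e")]
        assert isolated == ["f"]

    def test_zero_supports_all_isolated(self):
        tree = self._supported_tree((0, 0, 0))
        groups, isolated = extract_supported_clades(tree, 70)
        assert groups == [] and isolated == ["a", "b", "c", "d", "e", "f"]

    def test_nested_supported_clade_not_split(self):
        """A supported clade inside a supported parent stays inside it."""
        tree = self._supported_tree((80, 90, 95))
        groups, _ = extract_supported_clades(tree, 70)
        assert sorted(g.members for g in groups) == [("a", "b"), ("c", "d", "e")]

    def test_weak_parent_strong_child(self):
        tree = self._supported_tree((80, 40, 95))
        groups, isolated = extract_supported_clades(tree, 70)
        assert sorted(g.members for g in groups) == [("a", "b"), ("d", "e")]
        assert isolated == ["c", "f"]

    def test_planted_two_family_recovery(self):
        """Bootstrap on a two-family alignment recovers the two planted
        families as the supported groups."""
        rng = np.random.default_rng(20)
        from tcmariner.synthetic_data import FamilySpec, sim_family

        fam_a, _ = sim_family(FamilySpec(name="fa", n=4, divergence=0.05), 31)
        fam_b, _ = sim_family(FamilySpec(name="fb", n=4, divergence=0.05), 32)
        rows = [r.residues for r in fam_a + fam_b]
        ids = [r.id for r in fam_a + fam_b]
        tree = bootstrap_supports(rows, ids, n_reps=50, seed=9)
        rooted = root_with_outgroup(tree, {ids[0]})
        groups, _ = extract_supported_clades(rooted, 70)
        family_sets = {tuple(sorted(g.members)) for g in groups}
        # the non-outgroup family must appear as one supported group
        assert tuple(sorted(r.id for r in fam_b)) in family_sets
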