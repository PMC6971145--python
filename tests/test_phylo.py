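"""Neighbour joining, bootstrap support and newick output.

The NJ oracle enumerates every unrooted topology (15 for five taxa, 105 for
six), fits branch lengths to the distance matrix by non-negative least
squares over the path-indicator system, and picks the topology with zero
residual — unique for an additive matrix. skbio's independent NJ is a second
cross-check.
"""

import copy
import io
import itertools

import numpy as np
import pytest
from scipy.optimize import nnls

from bfbl.distances import AlignedBlock, DistanceMatrix
from bfbl.phylo import TreeConfig, bipartitions, bootstrap, nj, root_with_outgroup, to_newick
from bfbl.seqio import RegionSpec

# ---------------------------------------------------------------------------
# oracle machinery (nested-list trees; a virtual root with >= 3 children)


def _topologies(labels):
    base = list(labels[:3])
    trees = [base]
    for label in labels[3:]:
        grown = []
        for t in trees:
            for t2, slots in _edge_slots(t):
                parent, idx = slots
                tnew = copy.deepcopy(t2)
                node = _locate(tnew, parent)
                node[idx] = [node[idx], label]
                grown.append(tnew)
        trees = grown
    return trees


def _edge_slots(tree):
    # yields (tree, (path, index)) for every child edge
    out = []

    def walk(node, path):
        for i, child in enumerate(node):
            out.append((tree, (tuple(path), i)))
            if isinstance(child, list):
                walk(child, path + [i])

    walk(tree, [])
    return out


def _locate(tree, path):
    node = tree
    for i in path:
        node = node[i]
    return node


def _leaves(node):
    if isinstance(node, str):
        return frozenset([node])
    return frozenset().union(*(_leaves(c) for c in node))


def _splits(tree, all_leaves):
    splits = set()

    def walk(node):
        for child in node:
            if isinstance(child, list):
                side = _leaves(child)
                other = all_leaves - side
                if len(side) >= 2 and len(other) >= 2:
                    splits.add(min(side, other, key=lambda s: (len(s), tuple(sorted(s)))))
                walk(child)

    walk(tree)
    return splits


def _edges(tree):
    edges = []

    def walk(node, path):
        for i, child in enumerate(node):
            edges.append((_leaves(child), tuple(path) + (i,)))
            if isinstance(child, list):
                walk(child, path + [i])

    walk(tree, [])
    return edges


def _lsq_residual(tree, labels, D):
    edges = _edges(tree)
    pairs = list(itertools.combinations(range(len(labels)), 2))
    A = np.zeros((len(pairs), len(edges)))
    d = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        d[row] = D[i, j]
        for col, (side, _) in enumerate(edges):
            # edge is on the path iff it separates i from j
            if (labels[i] in side) != (labels[j] in side):
                A[row, col] = 1.0
    _, res = nnls(A, d)
    return res


def _random_additive(labels, rng):
    topo = _topologies(labels)[rng.integers(0, len(_topologies(labels)))]
    edges = _edges(topo)
    lengths = {path: int(rng.integers(1, 9)) for _, path in edges}
    n = len(labels)
    D = np.zeros((n, n), dtype=int)
    for i, j in itertools.combinations(range(n), 2):
        total = sum(
            l for (side, path), l in zip(edges, lengths.values())
            if (labels[i] in side) != (labels[j] in side)
        )
        D[i, j] = D[j, i] = total
    return topo, D


def _tree_splits(tree):
    return bipartitions(tree)


# ---------------------------------------------------------------------------


class TestNJ:
    def test_three_taxa_closed_form(self):
        dm = DistanceMatrix(("A", "B", "C"), np.array([[0, 2, 4], [2, 0, 6], [4, 6, 0]]), "aa")
        tree = nj(dm)
        lengths = {n.name: n.length for n in tree.leaves()}
        assert lengths == {"A": 0.0, "B": 2.0, "C": 4.0}
        assert to_newick(tree) == "(A:0,B:2,C:4);"

    def test_fewer_than_three_taxa_rejected(self):
        dm = DistanceMatrix(("A", "B"), np.array([[0, 1], [1, 0]]), "aa")
        with pytest.raises(Exception):
            nj(dm)

    @pytest.mark.parametrize("n_taxa", [5, 6])
    def test_additive_matrices_match_exhaustive_oracle(self, n_taxa):
        labels = [f"t{i}" for i in range(n_taxa)]
        rng = np.random.default_rng(42 + n_taxa)
        topos = _topologies(labels)
        for _ in range(8):
            _, D = _random_additive(labels, rng)
            residuals = [_lsq_residual(t, labels, D.astype(float)) for t in topos]
            best = topos[int(np.argmin(residuals))]
            assert min(residuals) < 1e-8
            tree = nj(DistanceMatrix(tuple(labels), D, "aa"))
            assert _tree_splits(tree) == _splits(best, frozenset(labels))

    def test_additive_branch_lengths_recovered(self):
        labels = ["A", "B", "C", "D", "E"]
        rng = np.random.default_rng(9)
        topo, D = _random_additive(labels, rng)
        tree = nj(DistanceMatrix(tuple(labels), D, "aa"))
        # the NJ tree's own topology must carry the matrix exactly (additivity)
        res = _lsq_residual_from_node(tree, labels, D.astype(float))
        assert res < 1e-8

    def test_row_order_invariance(self):
        labels = ["A", "B", "C", "D", "E", "F"]
        rng = np.random.default_rng(17)
        _, D = _random_additive(labels, rng)
        tree1 = nj(DistanceMatrix(tuple(labels), D, "aa"))
        perm = [3, 0, 5, 1, 4, 2]
        labels2 = [labels[i] for i in perm]
        D2 = D[np.ix_(perm, perm)]
        tree2 = nj(DistanceMatrix(tuple(labels2), D2, "aa"))
        assert _tree_splits(tree1) == _tree_splits(tree2)
        l1 = {n.name: round(n.length, 9) for n in tree1.leaves()}
        l2 = {n.name: round(n.length, 9) for n in tree2.leaves()}
        assert l1 == l2

    def test_matches_skbio_nj(self):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkDM
        from skbio.tree import nj as sk_nj

        labels = ["A", "B", "C", "D", "E", "F"]
        rng = np.random.default_rng(23)
        for _ in range(5):
            _, D = _random_additive(labels, rng)
            ours = nj(DistanceMatrix(tuple(labels), D, "aa"))
            theirs = sk_nj(SkDM(D.astype(float), ids=labels))
            their_splits = set()
            all_leaves = frozenset(labels)
            for node in theirs.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                other = all_leaves - side
                if len(side) >= 2 and len(other) >= 2:
                    their_splits.add(min(side, other, key=lambda s: (len(s), tuple(sorted(s)))))
            assert _tree_splits(ours) == their_splits


def _lsq_residual_from_node(tree, labels, D):
    """Least-squares residual of the NJ tree's own topology against D."""
    edge_sides = []

    def walk(node):
        for child in node.children:
            edge_sides.append(frozenset(l.name for l in child.leaves()))
            walk(child)

    walk(tree)
    pairs = list(itertools.combinations(range(len(labels)), 2))
    A = np.zeros((len(pairs), len(edge_sides)))
    d = np.zeros(len(pairs))
    for row, (i, j) in enumerate(pairs):
        d[row] = D[i, j]
        for col, side in enumerate(edge_sides):
            if (labels[i] in side) != (labels[j] in side):
                A[row, col] = 1.0
    _, res = nnls(A, d)
    return res


def _two_clade_block(seed=0, n_per=3, length=120, between=30, within=2):
    rng = np.random.default_rng(seed)
    aas = list("ACDEFGHIKLMNPQRSTVWY")
    base1 = "".join(rng.choice(aas, length))
    base2 = list(base1)
    for p in rng.choice(length, between, replace=False):
        base2[p] = "W" if base2[p] != "W" else "Y"
    base2 = "".join(base2)

    def variants(base, prefix):
        out = [(f"{prefix}1", base)]
        for k in range(2, n_per + 1):
            s = list(base)
            for p in rng.choice(length, within, replace=False):
                s[p] = "M" if s[p] != "M" else "L"
            out.append((f"{prefix}{k}", "".join(s)))
        return out

    named = variants(base1, "a") + variants(base2, "b")
    return AlignedBlock(
        RegionSpec("BLB", "beta1", "none", "aa"),
        tuple(n for n, _ in named),
        tuple(s for _, s in named),
    )


class TestBootstrap:
    def test_separated_clades_get_high_support(self):
        block = _two_clade_block(seed=3)
        tree = bootstrap(block, TreeConfig(bootstrap_reps=500, seed=5))
        split = frozenset({"a1", "a2", "a3"})
        complement = frozenset(block.labels) - split
        supports = {
            frozenset(l.name for l in n.leaves()): n.support
            for n in tree.walk()
            if n.support is not None
        }
        matching = [s for side, s in supports.items() if side in (split, complement)]
        assert matching and matching[0] >= 90.0

    def test_zero_reps_means_no_supports(self):
        block = _two_clade_block(seed=3)
        tree = bootstrap(block, TreeConfig(bootstrap_reps=0))
        assert all(n.support is None for n in tree.walk())

    def test_same_seed_reproduces_supports(self):
        block = _two_clade_block(seed=3)
        t1 = bootstrap(block, TreeConfig(bootstrap_reps=50, seed=9))
        t2 = bootstrap(block, TreeConfig(bootstrap_reps=50, seed=9))
        assert to_newick(t1) == to_newick(t2)


class TestNewick:
    def test_reparse_is_isomorphic(self):
        skbio = pytest.importorskip("skbio")
        from skbio import TreeNode

        labels = [f"x{i}" for i in range(6)]
        rng = np.random.default_rng(31)
        for _ in range(20):
            _, D = _random_additive(labels, rng)
            tree = nj(DistanceMatrix(tuple(labels), D, "aa"))
            parsed = TreeNode.read(io.StringIO(to_newick(tree)))
            all_leaves = frozenset(labels)
            parsed_splits = set()
            for node in parsed.non_tips(include_self=False):
                side = frozenset(t.name for t in node.tips())
                other = all_leaves - side
                if len(side) >= 2 and len(other) >= 2:
                    parsed_splits.add(
                        min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
                    )
            assert parsed_splits == _tree_splits(tree)

    def test_reserved_characters_are_quoted(self):
        dm = DistanceMatrix(
            ("B19 var1", "B", "C"), np.array([[0, 2, 4], [2, 0, 6], [4, 6, 0]]), "aa"
        )
        text = to_newick(nj(dm))
        assert "'B19 var1'" in text

    def test_outgroup_rooting_keeps_leaves(self):
        labels = ["A", "B", "C", "D", "E"]
        rng = np.random.default_rng(13)
        _, D = _random_additive(labels, rng)
        tree = nj(DistanceMatrix(tuple(labels), D, "aa"))
        rooted = root_with_outgroup(tree, "E")
        assert rooted.leaf_names() == tuple(sorted(labels))
        assert len(rooted.children) == 2
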