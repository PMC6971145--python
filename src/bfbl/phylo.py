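"""Neighbour-joining trees with bootstrap support.

Trees are advisory: they help curators see clades, but grouping decisions are
made by the distance-matrix thresholds (matrix precedence). The
implementation is the standard Saitou-Nei agglomeration on count distances
normalised by sequence length, with an optional Poisson correction.
Determinism is pinned down: ties in the Q criterion are broken by the
lexicographically smallest pair of subtree keys (the smallest leaf label
under each node), so the output is invariant to input row order.

Negative branch lengths produced by the NJ formulas are clamped to zero and
the clamp is logged. Bootstrap support resamples alignment columns with
replacement, rebuilds the tree per replicate, and reports the percentage of
replicates containing each bipartition of the point-estimate tree.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .distances import AlignedBlock, DistanceMatrix, _pair_counts
from .seqio import CurationError

logger = logging.getLogger("bfbl")


@dataclass(frozen=True)
class TreeConfig:
    bootstrap_reps: int = 500
    seed: int = 0
    outgroup_labels: tuple[str, ...] = ()
    distance_model: str = "count"  # count | poisson_corrected

    def __post_init__(self) -> None:
        if self.bootstrap_reps < 0:
            raise ValueError("bootstrap_reps must be >= 0")
        if self.distance_model not in ("count", "poisson_corrected"):
            raise ValueError(f"unknown distance model {self.distance_model!r}")


@dataclass
class Node:
    """Tree node; leaves carry a name, internal nodes may carry support (%)."""

    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out: list[Node] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> tuple[str, ...]:
        return tuple(sorted(n.name or "" for n in self.leaves()))

    def walk(self) -> Iterable["Node"]:
        yield self
        for c in self.children:
            yield from c.walk()


def _normalised(dm: DistanceMatrix, model: str) -> np.ndarray:
    d = dm.counts.astype(float)
    if dm.ncols:
        d = d / dm.ncols
        if model == "poisson_corrected":
            p = np.clip(d, 0.0, 1.0 - 1e-9)
            d = -np.log(1.0 - p)
    return d


def _clamp(x: float, context: str) -> float:
    if x < 0:
        logger.info("clamped negative branch length %.4g to 0 (%s)", x, context)
        return 0.0
    return x


def nj(dm: DistanceMatrix, model: str = "count") -> Node:
    """Neighbour-joining tree from a distance matrix (n >= 3 taxa).

    Counts are divided by the number of compared columns when the matrix
    records it (``ncols``); matrices built directly from counts are used as
    is. The result is unrooted, represented with a trifurcating root.
    """
    n = len(dm.labels)
    if n < 3:
        raise CurationError(f"neighbour joining requires at least 3 taxa, got {n}")
    D = _normalised(dm, model)

    nodes: list[Node] = [Node(name=l) for l in dm.labels]
    keys: list[str] = list(dm.labels)  # smallest leaf label under each active node
    active = list(range(n))
    dist = {(i, j): D[i, j] for i in range(n) for j in range(n) if i < j}

    def d(i: int, j: int) -> float:
        return dist[(i, j) if i < j else (j, i)]

    while len(active) > 3:
        r = len(active)
        row_sum = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best: tuple[float, str, str, int, int] | None = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                q = (r - 2) * d(i, j) - row_sum[i] - row_sum[j]
                ki, kj = sorted((keys[i], keys[j]))
                cand = (q, ki, kj, i, j)
                if best is None or cand[0] < best[0] - 1e-12 or (
                    abs(cand[0] - best[0]) <= 1e-12 and (ki, kj) < (best[1], best[2])
                ):
                    best = cand
        assert best is not None
        _, _, _, i, j = best
        dij = d(i, j)
        li = _clamp(dij / 2 + (row_sum[i] - row_sum[j]) / (2 * (r - 2)), keys[i])
        lj = _clamp(dij - (dij / 2 + (row_sum[i] - row_sum[j]) / (2 * (r - 2))), keys[j])
        u = Node(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        nodes.append(u)
        keys.append(min(keys[i], keys[j]))
        ui = len(nodes) - 1
        for k in active:
            if k in (i, j):
                continue
            dist[(k, ui) if k < ui else (ui, k)] = (d(i, k) + d(j, k) - dij) / 2
        active = [k for k in active if k not in (i, j)] + [ui]

    # three-point resolution for the final three nodes
    a, b, c = sorted(active, key=lambda k: keys[k])
    dab, dac, dbc = d(a, b), d(a, c), d(b, c)
    nodes[a].length = _clamp((dab + dac - dbc) / 2, keys[a])
    nodes[b].length = _clamp((dab + dbc - dac) / 2, keys[b])
    nodes[c].length = _clamp((dac + dbc - dab) / 2, keys[c])
    root = Node(children=[nodes[a], nodes[b], nodes[c]])
    return root


def bipartitions(tree: Node) -> set[frozenset[str]]:
    """Non-trivial splits of an unrooted tree, as canonical leaf-name sets.

    Each split is represented by the smaller side (ties: lexicographically
    smaller), so splits compare equal across differently rooted trees.
    """
    all_leaves = frozenset(tree.leaf_names())
    splits: set[frozenset[str]] = set()
    for node in tree.walk():
        if node is tree or node.is_leaf:
            continue
        side = frozenset(n.name or "" for n in node.leaves())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        splits.add(canon)
    return splits


def _resampled_matrix(block: AlignedBlock, idx: np.ndarray) -> DistanceMatrix:
    arr = np.array([list(s) for s in block.strings], dtype="U1")[:, idx]
    if block.region.level == "aa":
        maskable = arr == "X"
    else:
        maskable = ~np.isin(arr, list("ACGT"))
    counts, masked = _pair_counts(arr, maskable)
    return DistanceMatrix(block.labels, counts, block.region.level, len(idx), masked)


def bootstrap(block: AlignedBlock, config: TreeConfig = TreeConfig()) -> Node:
    """Point-estimate NJ tree with bootstrap supports on internal nodes.

    Columns are resampled with replacement ``bootstrap_reps`` times; support
    for each bipartition of the point tree is the percentage of replicate
    trees containing it. Reproducible for a fixed seed; reps=0 returns the
    point tree without supports.
    """
    from .distances import matrix as _matrix

    point = nj(_matrix(block), config.distance_model)
    if config.outgroup_labels:
        point = root_with_outgroup(point, config.outgroup_labels[0])
    if config.bootstrap_reps == 0:
        return point

    rng = np.random.default_rng(config.seed)
    ncols = block.ncols
    hits: dict[frozenset[str], int] = {s: 0 for s in bipartitions(point)}
    for _ in range(config.bootstrap_reps):
        idx = rng.integers(0, ncols, size=ncols)
        rep_tree = nj(_resampled_matrix(block, idx), config.distance_model)
        rep_splits = bipartitions(rep_tree)
        for s in hits:
            if s in rep_splits:
                hits[s] += 1

    all_leaves = frozenset(point.leaf_names())
    for node in point.walk():
        if node is point or node.is_leaf:
            continue
        side = frozenset(n.name or "" for n in node.leaves())
        other = all_leaves - side
        if len(side) < 2 or len(other) < 2:
            continue
        canon = min(side, other, key=lambda s: (len(s), tuple(sorted(s))))
        node.support = 100.0 * hits[canon] / config.bootstrap_reps
    return point


def root_with_outgroup(tree: Node, outgroup: str) -> Node:
    """Reroot on the pendant edge of ``outgroup`` (edge split in half)."""
    parents: dict[int, Node] = {}

    def walk(n: Node) -> None:
        for c in n.children:
            parents[id(c)] = n
            walk(c)

    walk(tree)
    leaf = next((n for n in tree.walk() if n.is_leaf and n.name == outgroup), None)
    if leaf is None:
        raise CurationError(f"outgroup label {outgroup!r} not in tree")
    parent = parents.get(id(leaf))
    if parent is None:
        return tree
    parent.children.remove(leaf)
    half = leaf.length / 2.0
    leaf.length = half
    new_root = Node(children=[leaf, parent])
    node, edge_len = parent, half
    while True:
        up = parents.get(id(node))
        orig_len = node.length
        node.length = edge_len
        if up is None:
            break
        up.children.remove(node)
        node.children.append(up)
        edge_len = orig_len
        node = up
    _splice_single_children(new_root)
    return new_root


def _splice_single_children(node: Node) -> None:
    i = 0
    while i < len(node.children):
        c = node.children[i]
        if not c.is_leaf and len(c.children) == 1:
            only = c.children[0]
            only.length += c.length
            node.children[i] = c = only
            continue
        _splice_single_children(c)
        i += 1


_NEEDS_QUOTE = re.compile(r"[\s():;,\[\]']")


def _quote(name: str) -> str:
    if _NEEDS_QUOTE.search(name):
        return "'" + name.replace("'", "''") + "'"
    return name


def _fmt_len(x: float) -> str:
    return f"{x:.6g}"


def to_newick(tree: Node) -> str:
    """Newick with branch lengths; integer supports as internal-node labels."""

    def fmt(n: Node) -> str:
        if n.is_leaf:
            return f"{_quote(n.name or '')}:{_fmt_len(n.length)}"
        inner = ",".join(fmt(c) for c in n.children)
        label = "" if n.support is None else str(int(round(n.support)))
        return f"({inner}){label}:{_fmt_len(n.length)}"

    inner = ",".join(fmt(c) for c in tree.children)
    label = "" if tree.support is None else str(int(round(tree.support)))
    return f"({inner}){label};"
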