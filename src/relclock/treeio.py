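"""Rooted binary time trees: array representation, newick I/O, tree metrics.

Nodes are indexed ``0 .. 2N-2``: leaves ``0 .. N-1`` in input order, internal
nodes ``N .. 2N-2`` in post-order of the source tree. Each node carries a
height (time before the most recent tip; tips of an ultrametric tree sit at
height 0, the root is maximal). The parental branch length of non-root node
``i`` is ``height[parent[i]] - height[i]`` and must be strictly positive.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import dendropy

NO_PARENT = -1


class TreeError(ValueError):
    pass


@dataclass
class TimeTree:
    """Binary rooted time tree over ``N`` labelled tips.

    Attributes
    ----------
    labels : list of str
        Tip labels, position = node index of the leaf.
    parent : ndarray (2N-1,)
        Parent index per node, ``NO_PARENT`` for the root.
    children : ndarray (2N-1, 2)
        Child indices per node, ``NO_PARENT`` entries for leaves.
    heights : ndarray (2N-1,)
        Node heights in time units.
    """

    labels: list
    parent: np.ndarray
    children: np.ndarray
    heights: np.ndarray
    root: int = field(default=-1)
    _postorder: list = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.root < 0:
            (roots,) = np.where(self.parent == NO_PARENT)
            if len(roots) != 1:
                raise TreeError(f"tree must have exactly one root, found {len(roots)}")
            self.root = int(roots[0])

    # -- basic structure ---------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def n_nodes(self) -> int:
        return len(self.heights)

    def is_leaf(self, i: int) -> bool:
        return i < self.n_taxa

    def branch_length(self, i: int) -> float:
        if i == self.root:
            raise TreeError("root has no parental branch")
        return float(self.heights[self.parent[i]] - self.heights[i])

    def internal_nodes(self, include_root: bool = True):
        nodes = range(self.n_taxa, self.n_nodes)
        return [i for i in nodes if include_root or i != self.root]

    def postorder(self):
        """Internal node indices ordered so children precede parents.

        Cached; mutating the topology must call :meth:`invalidate_topology`.
        """
        if self._postorder is None:
            order = []
            stack = [self.root]
            while stack:
                i = stack.pop()
                order.append(i)
                if not self.is_leaf(i):
                    stack.extend(int(c) for c in self.children[i])
            self._postorder = [i for i in reversed(order) if not self.is_leaf(i)]
        return self._postorder

    def invalidate_topology(self):
        self._postorder = None

    def copy(self) -> "TimeTree":
        return TimeTree(self.labels, self.parent.copy(), self.children.copy(),
                        self.heights.copy(), self.root, self._postorder)

    def validate(self):
        N = self.n_taxa
        if self.n_nodes != 2 * N - 1:
            raise TreeError("node count is not 2N-1: tree is not binary")
        for i in range(self.n_nodes):
            if i == self.root:
                continue
            if self.heights[i] >= self.heights[self.parent[i]]:
                raise TreeError(f"node {i} is not strictly below its parent")

    def clades(self, include_root: bool = False):
        """Frozenset of tip labels below each internal node."""
        below = {i: frozenset([self.labels[i]]) for i in range(self.n_taxa)}
        out = set()
        for i in self.postorder():
            below[i] = below[int(self.children[i, 0])] | below[int(self.children[i, 1])]
            if include_root or i != self.root:
                out.add(below[i])
        return out

    # -- conversions -------------------------------------------------------
    def __repr__(self):
        return f"TimeTree(N={self.n_taxa}, root_height={self.heights[self.root]:.4g})"


def parse_newick(text: str) -> TimeTree:
    """Parse a newick string with branch lengths into a :class:`TimeTree`.

    Heights are derived from root-to-node path lengths: the root sits at the
    maximum tip depth and every node at (max tip depth - its depth), so an
    ultrametric input puts all tips at height 0.

    Raises
    ------
    TreeError
        On non-binary nodes, missing branch lengths, or negative lengths.
    """
    dt = dendropy.Tree.get(data=text, schema="newick",
                           suppress_internal_node_taxa=True)
    dnodes = list(dt.preorder_node_iter())
    droot = dt.seed_node
    leaves = [nd for nd in dnodes if nd.is_leaf()]
    N = len(leaves)
    if N < 2:
        raise TreeError("tree must have at least 2 taxa")
    for nd in dnodes:
        k = len(nd.child_nodes())
        if k not in (0, 2):
            name = nd.taxon.label if nd.taxon else f"internal node with {k} children"
            raise TreeError(f"non-binary node: {name}")
        if nd is not droot:
            if nd.edge.length is None:
                raise TreeError("branch length missing")
            if nd.edge.length < 0:
                raise TreeError(f"negative branch length {nd.edge.length}")

    # depth = path length from root
    depth = {droot: 0.0}
    for nd in dt.preorder_node_iter():
        if nd is not droot:
            depth[nd] = depth[nd.parent_node] + nd.edge.length
    max_depth = max(depth[nd] for nd in leaves)

    labels = [nd.taxon.label for nd in leaves]
    index = {nd: i for i, nd in enumerate(leaves)}
    nxt = N
    for nd in dt.postorder_node_iter():
        if not nd.is_leaf():
            index[nd] = nxt
            nxt += 1

    M = 2 * N - 1
    parent = np.full(M, NO_PARENT, dtype=np.int64)
    children = np.full((M, 2), NO_PARENT, dtype=np.int64)
    heights = np.zeros(M)
    for nd, i in index.items():
        heights[i] = max_depth - depth[nd]
        for slot, ch in enumerate(nd.child_nodes()):
            children[i, slot] = index[ch]
            parent[index[ch]] = i
    tree = TimeTree(labels, parent, children, heights)
    tree.validate()
    return tree


def write_newick(tree: TimeTree, precision: int = 12) -> str:
    """Serialise a :class:`TimeTree` to newick with branch lengths."""
    buf = io.StringIO()

    def rec(i: int):
        if tree.is_leaf(i):
            buf.write(tree.labels[i])
        else:
            buf.write("(")
            rec(int(tree.children[i, 0]))
            buf.write(",")
            rec(int(tree.children[i, 1]))
            buf.write(")")
        if i != tree.root:
            buf.write(f":{tree.branch_length(i):.{precision}g}")

    rec(tree.root)
    buf.write(";")
    return buf.getvalue()


def robinson_foulds(a: TimeTree, b: TimeTree) -> int:
    """Robinson-Foulds distance: clades present in exactly one tree, over 2.

    The one-sided convention (symmetric clade-set difference halved) makes a
    single narrow-exchange move distance exactly 1.
    """
    if set(a.labels) != set(b.labels):
        raise TreeError("leaf label sets differ")
    diff = a.clades() ^ b.clades()
    return len(diff) // 2


def tree_length(tree: TimeTree) -> float:
    """Sum of all branch lengths (time units)."""
    mask = np.ones(tree.n_nodes, dtype=bool)
    mask[tree.root] = False
    return float(np.sum(tree.heights[tree.parent[mask]] - tree.heights[mask]))


def nexus_tree_block(trees, states) -> str:
    """NEXUS-style tree log: one TREE line per sampled state."""
    lines = ["#NEXUS", "Begin trees;"]
    for s, t in zip(states, trees):
        nw = t if isinstance(t, str) else write_newick(t)
        lines.append(f"tree STATE_{s} = {nw}")
    lines.append("End;")
    return "\n".join(lines) + "\n"
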