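"""Light-weight phylogenetic trees shared across the package.

The iterative search builds and consumes thousands of small gene trees,
so the container is deliberately minimal: slotted nodes, explicit
traversals, and numpy edge-count distance matrices.  Newick text is
parsed with dendropy and converted; writing is a direct recursion.

A tree whose root has three (or more) children is treated as unrooted;
a two-child root is a rooting point and is suppressed whenever an
unrooted view (bipartitions, leaf distances) is required.
"""

from __future__ import annotations

from typing import Callable, Iterable, Iterator, Sequence

import dendropy
import numpy as np

__all__ = [
    "Node",
    "Tree",
    "TreeError",
    "tree_from_newick",
    "bipartitions",
    "robinson_foulds",
    "topo_distance_matrix",
    "weighted_distance_matrix",
    "root_with_outgroup",
    "midpoint_root",
    "contract_low_support",
]


class TreeError(ValueError):
    pass


class Node:
    __slots__ = ("children", "parent", "label", "length", "support")

    def __init__(
        self,
        label: str | None = None,
        length: float | None = None,
        support: float | None = None,
    ) -> None:
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.label = label
        self.length = length
        self.support = support

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, n_children={len(self.children)})"


class Tree:
    """A rooted container with unrooted semantics when the root is a
    trifurcation (the convention for neighbor-joining output)."""

    def __init__(self, root: Node) -> None:
        self.root = root

    # -- traversal

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def find_leaf(self, label: str) -> Node:
        for n in self.leaves():
            if n.label == label:
                return n
        raise TreeError(f"leaf {label!r} not in tree")

    def leafset(self, node: Node) -> frozenset[str]:
        stack, labels = [node], []
        while stack:
            n = stack.pop()
            if n.is_leaf:
                labels.append(n.label)
            else:
                stack.extend(n.children)
        return frozenset(labels)

    def copy(self) -> "Tree":
        def clone(node: Node) -> Node:
            new = Node(node.label, node.length, node.support)
            for c in node.children:
                new.add(clone(c))
            return new

        return Tree(clone(self.root))

    # -- unrooted view

    def adjacency(self) -> tuple[dict[Node, list[Node]], dict[frozenset, float]]:
        """Unrooted adjacency with degree-2 nodes (rooting points)
        suppressed; edge lengths keyed by frozenset of node ids."""
        adj: dict[Node, list[Node]] = {}
        elen: dict[frozenset, float] = {}

        def connect(a: Node, b: Node, length: float) -> None:
            adj.setdefault(a, []).append(b)
            adj.setdefault(b, []).append(a)
            elen[frozenset((id(a), id(b)))] = length

        for node in self.preorder():
            for c in node.children:
                connect(node, c, c.length if c.length is not None else 1.0)

        changed = True
        while changed:
            changed = False
            for node, nbrs in list(adj.items()):
                if len(nbrs) == 2 and not node.is_leaf:
                    a, b = nbrs
                    la = elen.pop(frozenset((id(node), id(a))))
                    lb = elen.pop(frozenset((id(node), id(b))))
                    adj[a] = [x if x is not node else b for x in adj[a]]
                    adj[b] = [x if x is not node else a for x in adj[b]]
                    elen[frozenset((id(a), id(b)))] = la + lb
                    del adj[node]
                    changed = True
        return adj, elen

    # -- output

    def newick(self, include_support: bool = True, include_lengths: bool = True) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                s = node.label or ""
            else:
                s = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if include_support and node.support is not None:
                    s += f"{node.support:g}"
            if include_lengths and node.length is not None and node.parent is not None:
                s += f":{node.length:g}"
            return s

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree({len(self.leaves())} leaves)"


def tree_from_newick(text: str) -> Tree:
    """Parse a Newick string (support values read from internal-node
    labels, the common gene-tree dialect)."""
    dtree = dendropy.Tree.get(data=text, schema="newick", preserve_underscores=True)

    def convert(dnode) -> Node:
        label = None
        support = None
        if dnode.is_leaf():
            label = dnode.taxon.label if dnode.taxon else dnode.label
        elif dnode.label is not None:
            try:
                support = float(dnode.label)
            except ValueError:
                label = dnode.label
        node = Node(label=label, length=dnode.edge.length, support=support)
        for child in dnode.child_nodes():
            node.add(convert(child))
        return node

    return Tree(convert(dtree.seed_node))


# --- bipartitions and tree distance -------------------------------------


def bipartitions(tree: Tree) -> frozenset[frozenset[str]]:
    """Non-trivial bipartitions of the unrooted tree, each canonicalised
    as the side not containing the lexicographically smallest leaf."""
    all_leaves = frozenset(tree.leaf_labels)
    if len(all_leaves) < 4:
        return frozenset()
    anchor = min(all_leaves)
    adj, _ = tree.adjacency()
    out: set[frozenset[str]] = set()

    for node in tree.preorder():
        if node.parent is None or node.is_leaf or node not in adj:
            continue
        side = tree.leafset(node)
        if side == all_leaves:
            continue
        if anchor in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(side)
    return frozenset(out)


def internal_edge_supports(tree: Tree) -> dict[frozenset[str], float | None]:
    """Canonical bipartition -> support for each internal edge."""
    all_leaves = frozenset(tree.leaf_labels)
    anchor = min(all_leaves)
    adj, _ = tree.adjacency()
    out: dict[frozenset[str], float | None] = {}
    for node in tree.preorder():
        if node.parent is None or node.is_leaf or node not in adj:
            continue
        side = tree.leafset(node)
        if anchor in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            out[side] = node.support
    return out


def robinson_foulds(t1: Tree, t2: Tree, normalized: bool = True) -> float:
    """(Normalised) Robinson-Foulds distance between two unrooted trees
    on the same leaf set."""
    if frozenset(t1.leaf_labels) != frozenset(t2.leaf_labels):
        raise TreeError("RF distance requires identical leaf sets")
    b1, b2 = bipartitions(t1), bipartitions(t2)
    d = len(b1 ^ b2)
    if not normalized:
        return float(d)
    denom = len(b1) + len(b2)
    return d / denom if denom else 0.0


# --- distances -----------------------------------------------------------


def _distance_matrix(tree: Tree, labels: Sequence[str], weighted: bool) -> np.ndarray:
    adj, elen = tree.adjacency()
    leaf_nodes = {n.label: n for n in tree.leaves()}
    missing = [l for l in labels if l not in leaf_nodes]
    if missing:
        raise TreeError(f"labels not in tree: {missing}")
    n = len(labels)
    D = np.zeros((n, n), dtype=float)
    for i, lab in enumerate(labels):
        start = leaf_nodes[lab]
        dist: dict[Node, float] = {start: 0.0}
        stack = [start]
        while stack:
            node = stack.pop()
            for nbr in adj.get(node, []):
                if nbr not in dist:
                    step = elen[frozenset((id(node), id(nbr)))] if weighted else 1.0
                    dist[nbr] = dist[node] + step
                    stack.append(nbr)
        for j, lab2 in enumerate(labels):
            D[i, j] = dist.get(leaf_nodes[lab2], np.nan)
    return D


def topo_distance_matrix(tree: Tree, labels: Sequence[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Edge-count (internode) distances between leaves."""
    labels = list(labels) if labels is not None else sorted(tree.leaf_labels)
    return _distance_matrix(tree, labels, weighted=False), labels


def weighted_distance_matrix(tree: Tree, labels: Sequence[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Branch-length (patristic) distances between leaves."""
    labels = list(labels) if labels is not None else sorted(tree.leaf_labels)
    return _distance_matrix(tree, labels, weighted=True), labels


# --- rooting -------------------------------------------------------------


def _orient(node: Node, prev: Node | None, adj, elen) -> Node:
    new = Node(node.label, None, node.support)
    if prev is not None:
        new.length = elen[frozenset((id(node), id(prev)))]
    for nbr in adj.get(node, []):
        if nbr is not prev:
            new.add(_orient(nbr, node, adj, elen))
    return new


def root_with_outgroup(tree: Tree, outgroup: str) -> Tree:
    """Return a copy rooted so that the outgroup leaf is one child of a
    bifurcating root."""
    adj, elen = tree.adjacency()
    og = tree.find_leaf(outgroup)
    nbrs = adj.get(og)
    if not nbrs:
        raise TreeError("cannot root a <3-leaf tree")
    u = nbrs[0]
    length = elen[frozenset((id(og), id(u)))]
    root = Node()
    og_new = Node(og.label, length / 2.0)
    root.add(og_new)
    ingroup = _orient(u, og, adj, elen)
    ingroup.length = length / 2.0
    root.add(ingroup)
    return Tree(root)


def midpoint_root(tree: Tree) -> Tree:
    """Root a copy at the midpoint of the longest leaf-to-leaf path."""
    labels = sorted(tree.leaf_labels)
    D, _ = weighted_distance_matrix(tree, labels)
    i, j = np.unravel_index(np.argmax(D), D.shape)
    if i == j:
        return tree.copy()
    adj, elen = tree.adjacency()
    leaf_nodes = {n.label: n for n in tree.leaves()}
    start, goal = leaf_nodes[labels[i]], leaf_nodes[labels[j]]
    # recover the path
    parent_of: dict[Node, Node] = {}
    stack = [start]
    seen = {start}
    while stack:
        node = stack.pop()
        for nbr in adj.get(node, []):
            if nbr not in seen:
                seen.add(nbr)
                parent_of[nbr] = node
                stack.append(nbr)
    path = [goal]
    while path[-1] is not start:
        path.append(parent_of[path[-1]])
    path.reverse()
    half = D[i, j] / 2.0
    acc = 0.0
    for a, b in zip(path, path[1:]):
        step = elen[frozenset((id(a), id(b)))]
        if acc + step >= half:
            root = Node()
            left = _orient(a, b, adj, elen)
            right = _orient(b, a, adj, elen)
            left.length = half - acc
            right.length = step - (half - acc)
            root.add(left)
            root.add(right)
            return Tree(root)
        acc += step
    return tree.copy()  # pragma: no cover - degenerate lengths


# --- contraction ---------------------------------------------------------


def contract_low_support(tree: Tree, threshold: float) -> Tree:
    """Collapse internal edges whose support is <= ``threshold`` (in %),
    producing polytomies.  Leaves are never removed."""
    out = tree.copy()
    for node in list(out.postorder()):
        if node.parent is None or node.is_leaf:
            continue
        if node.support is not None and node.support <= threshold:
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx : idx + 1] = node.children
            for c in node.children:
                c.parent = parent
    return out


def contract_edges(tree: Tree, predicate: Callable[[Node], bool]) -> Tree:
    """Collapse internal edges for which ``predicate(child_node)`` holds."""
    out = tree.copy()
    for node in list(out.postorder()):
        if node.parent is None or node.is_leaf:
            continue
        if predicate(node):
            parent = node.parent
            idx = parent.children.index(node)
            parent.children[idx : idx + 1] = node.children
            for c in node.children:
                c.parent = parent
    return out
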