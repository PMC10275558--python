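"""Backbone species-tree estimation and quartet placement of the
polarized polyploid.

The backbone (the bifurcating tree over all non-focal taxa) is estimated
by neighbor joining on internode distances averaged over gene trees, a
procedure that is statistically consistent under the multispecies
coalescent.  The polarized tetraploid is then attached to the backbone
edge that maximises agreement with gene-tree quartets containing it --
the same quartet objective a coalescent-aware supertree method
optimises, restricted to the single placement decision the protocol
needs.  Branch support is reported as the three normalised quartet
frequencies q1/q2/q3 around the attachment branch.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .genetrees import neighbor_joining
from .trees import (
    Node,
    Tree,
    TreeError,
    midpoint_root,
    root_with_outgroup,
    topo_distance_matrix,
)

__all__ = [
    "BranchSupport",
    "PlacementResult",
    "average_distance_backbone",
    "quartet_topology",
    "place_by_quartets",
    "branch_quartet_support",
    "attach_polyploid",
    "pairing_frequencies",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BranchSupport:
    """Normalised quartet frequencies around a branch; q1 is the
    frequency of the topology displayed in the species tree."""

    q1: float
    q2: float
    q3: float


@dataclass(frozen=True)
class PlacementResult:
    """Attachment of the polyploid on the backbone.

    ``attachment_edge`` and ``sister_group`` are the leaf set cut off by
    the attachment edge on the polyploid's side.
    """

    attachment_edge: frozenset[str]
    sister_group: frozenset[str]
    support: BranchSupport | None
    n_gene_trees: int


# --- backbone ------------------------------------------------------------


def average_distance_backbone(gene_trees: Sequence[Tree]) -> Tree:
    """NJ backbone on mean internode (edge-count) distances, averaged
    over the gene trees containing each pair of taxa."""
    gene_trees = list(gene_trees)
    if not gene_trees:
        raise ValueError("at least one gene tree is required")
    taxa = sorted(set().union(*(set(t.leaf_labels) for t in gene_trees)))
    idx = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    total = np.zeros((n, n))
    count = np.zeros((n, n))
    for tree in gene_trees:
        present = sorted(l for l in tree.leaf_labels if l in idx)
        D, _ = topo_distance_matrix(tree, present)
        ii = np.array([idx[l] for l in present])
        total[np.ix_(ii, ii)] += D
        count[np.ix_(ii, ii)] += 1
    off = ~np.eye(n, dtype=bool)
    if (count[off] == 0).any():
        i, j = np.argwhere((count == 0) & off)[0]
        raise ValueError(f"taxa {taxa[i]!r} and {taxa[j]!r} never co-occur")
    mean = np.zeros((n, n))
    mean[off] = total[off] / count[off]
    return neighbor_joining(mean, taxa)


# --- quartets ------------------------------------------------------------


def _four_point(dab_cd: float, dac_bd: float, dad_bc: float) -> int:
    """0/1/2 for the minimal pairing, -1 when the minimum is tied."""
    sums = (dab_cd, dac_bd, dad_bc)
    m = min(sums)
    if sums.count(m) != 1:
        return -1
    return sums.index(m)


def quartet_topology(
    tree: Tree, taxa: Sequence[str]
) -> frozenset[frozenset[str]] | None:
    """Unrooted quartet topology induced on four leaves.

    Returns the split as ``{{a,b},{c,d}}`` or None when the restriction
    is a star (the four leaves meet at a polytomy).
    """
    a, b, c, d = taxa
    D, labels = topo_distance_matrix(tree, [a, b, c, d])
    k = _four_point(D[0, 1] + D[2, 3], D[0, 2] + D[1, 3], D[0, 3] + D[1, 2])
    if k == -1:
        return None
    pairs = (((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c)))[k]
    return frozenset(frozenset(p) for p in pairs)


def _edge_list(tree: Tree) -> list[tuple[Node, Node]]:
    adj, _ = tree.adjacency()
    edges, seen = [], set()
    for u, nbrs in adj.items():
        for v in nbrs:
            key = frozenset((id(u), id(v)))
            if key not in seen:
                seen.add(key)
                edges.append((u, v))
    return edges


def _node_leaf_distances(tree: Tree, labels: Sequence[str]):
    """Edge-count distance from every node of the unrooted tree to every
    leaf in ``labels``; returns (node->row index map, matrix)."""
    adj, _ = tree.adjacency()
    nodes = list(adj)
    node_idx = {n: i for i, n in enumerate(nodes)}
    leaf_nodes = {n.label: n for n in tree.leaves()}
    dist = np.full((len(nodes), len(labels)), np.nan)
    for j, lab in enumerate(labels):
        start = leaf_nodes[lab]
        dist[node_idx[start], j] = 0.0
        stack = [start]
        while stack:
            node = stack.pop()
            d = dist[node_idx[node], j]
            for nbr in adj[node]:
                k = node_idx[nbr]
                if np.isnan(dist[k, j]):
                    dist[k, j] = d + 1.0
                    stack.append(nbr)
    return node_idx, dist


def _gene_quartet_codes(
    gene_trees: Sequence[Tree],
    polyploid_taxon: str,
    backbone_labels: Sequence[str],
    triples: np.ndarray,
) -> np.ndarray:
    """Counts N[k, q]: over gene trees, how often quartet q (polyploid +
    triple of backbone taxa) shows the polyploid paired with member k of
    the triple.  Unresolved or incomputable quartets count nowhere."""
    M = triples.shape[0]
    N = np.zeros((3, M), dtype=np.int64)
    for tree in gene_trees:
        present = set(tree.leaf_labels)
        if polyploid_taxon not in present:
            continue
        labels = [polyploid_taxon] + [l for l in backbone_labels if l in present]
        D, _ = topo_distance_matrix(tree, labels)
        pos = np.full(len(backbone_labels), -1, dtype=np.int64)
        for c, l in enumerate(labels[1:]):
            pos[backbone_labels.index(l)] = c + 1
        px, py, pz = pos[triples[:, 0]], pos[triples[:, 1]], pos[triples[:, 2]]
        ok = (px >= 0) & (py >= 0) & (pz >= 0)
        dp = D[0]
        s = np.full((3, M), np.inf)
        s[0, ok] = dp[px[ok]] + D[py[ok], pz[ok]]
        s[1, ok] = dp[py[ok]] + D[px[ok], pz[ok]]
        s[2, ok] = dp[pz[ok]] + D[px[ok], py[ok]]
        mins = s.min(axis=0)
        resolved = ok & ((s == mins).sum(axis=0) == 1)
        code = np.argmin(s, axis=0)
        for k in range(3):
            N[k] += resolved & (code == k)
    return N


def place_by_quartets(
    backbone: Tree,
    gene_trees: Sequence[Tree],
    polyploid_taxon: str,
    outgroup: str | None = None,
    compute_support: bool = True,
    max_exhaustive: int = 10**6,
    subsample: int = 10**5,
    seed: int = 0,
) -> PlacementResult:
    """Attach the polyploid to the backbone edge maximising gene-tree
    quartet agreement.

    Ties are broken toward the smallest sister group, then
    lexicographically.  Gene trees missing the polyploid are skipped.
    When the total number of (gene tree, quartet) evaluations exceeds
    ``max_exhaustive`` a seeded uniform subsample of ``subsample``
    quartet triples is scored instead.
    """
    gene_trees = [t for t in gene_trees if polyploid_taxon in set(t.leaf_labels)]
    if not gene_trees:
        raise ValueError("no gene trees contain the polyploid")
    backbone_labels = sorted(backbone.leaf_labels)
    if polyploid_taxon in backbone_labels:
        raise ValueError("backbone must not contain the polyploid")
    n = len(backbone_labels)
    if n < 3:
        raise ValueError("backbone too small for quartet placement")

    triples = np.array(list(itertools.combinations(range(n), 3)), dtype=np.int64)
    if triples.shape[0] * len(gene_trees) > max_exhaustive:
        rng = np.random.default_rng(seed)
        keep = max(1, subsample // len(gene_trees))
        sel = rng.choice(triples.shape[0], size=min(keep, triples.shape[0]), replace=False)
        triples = triples[np.sort(sel)]

    N = _gene_quartet_codes(gene_trees, polyploid_taxon, backbone_labels, triples)

    node_idx, node_dist = _node_leaf_distances(backbone, backbone_labels)
    leaf_nodes = {n.label: n for n in backbone.leaves()}
    leaf_rows = np.array([node_idx[leaf_nodes[l]] for l in backbone_labels])
    Dbb = node_dist[leaf_rows]  # leaf-leaf edge-count distances
    all_leaves = frozenset(backbone_labels)
    x, y, z = triples[:, 0], triples[:, 1], triples[:, 2]
    best = None
    for u, v in _edge_list(backbone):
        du = node_dist[node_idx[u]]
        dv = node_dist[node_idx[v]]
        dp = 0.5 + np.minimum(du, dv)
        s0 = dp[x] + Dbb[y, z]
        s1 = dp[y] + Dbb[x, z]
        s2 = dp[z] + Dbb[x, y]
        S = np.stack([s0, s1, s2])
        codes = np.argmin(S, axis=0)
        score = int(np.take_along_axis(N, codes[None, :], axis=0).sum())

        side_v = frozenset(
            backbone_labels[i]
            for i in range(n)
            if node_dist[node_idx[v], i] < node_dist[node_idx[u], i]
        )
        side_u = all_leaves - side_v
        if outgroup is not None and outgroup in all_leaves:
            sister = side_v if outgroup not in side_v else side_u
        else:
            sister = min(side_v, side_u, key=lambda s: (len(s), tuple(sorted(s))))
        key = (-score, len(sister), tuple(sorted(sister)))
        if best is None or key < best[0]:
            best = (key, sister, score)

    _, sister, score = best
    support = None
    if compute_support and n >= 3:
        attached = attach_polyploid(backbone, sister, polyploid_taxon)
        try:
            support = branch_quartet_support(
                gene_trees, attached, frozenset(sister | {polyploid_taxon})
            )
        except (TreeError, ValueError):
            support = None
    return PlacementResult(
        attachment_edge=frozenset(sister),
        sister_group=frozenset(sister),
        support=support,
        n_gene_trees=len(gene_trees),
    )


# --- attachment and branch support ---------------------------------------


def attach_polyploid(
    backbone: Tree, edge_side: frozenset[str] | set[str], polyploid_taxon: str
) -> Tree:
    """Return a new (unrooted) tree with the polyploid attached on the
    backbone edge identified by the leaf set on one of its sides."""
    edge_side = frozenset(edge_side)
    all_leaves = frozenset(backbone.leaf_labels)
    adj, elen = backbone.adjacency()
    node_idx, node_dist = _node_leaf_distances(backbone, sorted(all_leaves))
    labels = sorted(all_leaves)
    for u, v in _edge_list(backbone):
        side_v = frozenset(
            labels[i]
            for i in range(len(labels))
            if node_dist[node_idx[v], i] < node_dist[node_idx[u], i]
        )
        if side_v == edge_side or (all_leaves - side_v) == edge_side:
            from .trees import _orient

            m = Node()
            left = _orient(u, v, adj, elen)
            right = _orient(v, u, adj, elen)
            half = elen[frozenset((id(u), id(v)))] / 2.0
            left.length = half
            right.length = half
            poly = Node(polyploid_taxon, 1.0)
            m.add(left)
            m.add(right)
            m.add(poly)
            return Tree(m)
    raise TreeError(f"no backbone edge with side {sorted(edge_side)}")


def _edge_components(tree: Tree, focal_side: frozenset[str]):
    """The four leaf-set clades induced by the endpoints of an internal
    edge, given the leaf set on one side of it."""
    all_leaves = frozenset(tree.leaf_labels)
    labels = sorted(all_leaves)
    adj, _ = tree.adjacency()
    node_idx, node_dist = _node_leaf_distances(tree, labels)

    for u, v in _edge_list(tree):
        side_v = frozenset(
            labels[i]
            for i in range(len(labels))
            if node_dist[node_idx[v], i] < node_dist[node_idx[u], i]
        )
        if side_v == focal_side:
            pass
        elif (all_leaves - side_v) == focal_side:
            u, v = v, u
            side_v = all_leaves - side_v
        else:
            continue
        if len(side_v) < 2 or len(all_leaves - side_v) < 2:
            raise ValueError("focal branch is not internal")

        def components(center: Node, away: Node) -> list[frozenset[str]]:
            comps = []
            for w in adj[center]:
                if w is away:
                    continue
                comp = frozenset(
                    labels[i]
                    for i in range(len(labels))
                    if node_dist[node_idx[w], i] < node_dist[node_idx[center], i]
                )
                comps.append(comp)
            return comps

        cv = components(v, u)  # on the focal side
        cu = components(u, v)
        if len(cv) != 2 or len(cu) != 2:
            raise ValueError("focal branch endpoints must be bifurcating")
        return cv[0], cv[1], cu[0], cu[1]
    raise TreeError(f"no internal edge with side {sorted(focal_side)}")


def branch_quartet_support(
    gene_trees: Sequence[Tree],
    species_tree: Tree,
    focal_branch: frozenset[str] | set[str],
    per_tree_average: bool = True,
    max_quartets: int = 2000,
    seed: int = 0,
) -> BranchSupport:
    """q1/q2/q3 quartet support around an internal species-tree branch.

    Quartets draw one leaf from each of the four clades induced by the
    branch's endpoints; q1 is the fraction matching the species-tree
    topology, averaged per gene tree and then over trees (set
    ``per_tree_average=False`` to pool raw counts instead).
    """
    A, B, C_, D_ = _edge_components(species_tree, frozenset(focal_branch))
    quartets = list(itertools.product(sorted(A), sorted(B), sorted(C_), sorted(D_)))
    if len(quartets) > max_quartets:
        rng = np.random.default_rng(seed)
        sel = rng.choice(len(quartets), size=max_quartets, replace=False)
        quartets = [quartets[i] for i in np.sort(sel)]

    per_tree = []
    pooled = np.zeros(3)
    for tree in gene_trees:
        present = set(tree.leaf_labels)
        usable = [q for q in quartets if present.issuperset(q)]
        if not usable:
            continue
        labels = sorted({l for q in usable for l in q})
        Dg, _ = topo_distance_matrix(tree, labels)
        pos = {l: i for i, l in enumerate(labels)}
        counts = np.zeros(3)
        for a, b, c, d in usable:
            ia, ib, ic, idd = pos[a], pos[b], pos[c], pos[d]
            k = _four_point(
                Dg[ia, ib] + Dg[ic, idd],
                Dg[ia, ic] + Dg[ib, idd],
                Dg[ia, idd] + Dg[ib, ic],
            )
            if k >= 0:
                counts[k] += 1
        if counts.sum() > 0:
            per_tree.append(counts / counts.sum())
            pooled += counts
    if not per_tree:
        return BranchSupport(float("nan"), float("nan"), float("nan"))
    if per_tree_average:
        q = np.mean(per_tree, axis=0)
    else:
        q = pooled / pooled.sum()
    return BranchSupport(float(q[0]), float(q[1]), float(q[2]))


# --- pairing frequencies --------------------------------------------------


def pairing_frequencies(
    gene_trees: Sequence[Tree],
    polyploid_taxon: str,
    outgroup: str | None = None,
) -> dict[frozenset[str], float]:
    """Frequency with which the polyploid pairs with each taxon or group
    of taxa across individual gene trees.

    Each gene tree is rooted at the outgroup (midpoint fallback, with a
    warning); the polyploid's sister set is the remainder of the minimal
    clade containing it.  Multi-taxon sisters are tallied as groups.
    """
    tallies: dict[frozenset[str], int] = {}
    total = 0
    warned = False
    for tree in gene_trees:
        present = set(tree.leaf_labels)
        if polyploid_taxon not in present:
            continue
        if outgroup is not None and outgroup in present and outgroup != polyploid_taxon:
            rooted = root_with_outgroup(tree, outgroup)
        else:
            if not warned:
                logger.warning(
                    "no outgroup available; falling back to midpoint rooting"
                )
                warned = True
            rooted = midpoint_root(tree)
        leaf = rooted.find_leaf(polyploid_taxon)
        parent = leaf.parent
        if parent is None:
            continue
        sister = frozenset(rooted.leafset(parent) - {polyploid_taxon})
        if not sister:
            continue
        tallies[sister] = tallies.get(sister, 0) + 1
        total += 1
    if total == 0:
        return {}
    return {k: v / total for k, v in tallies.items()}
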