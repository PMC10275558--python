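"""Per-locus alignment filtering and distance-based gene-tree inference.

Gene trees are inferred by neighbor joining on Kimura two-parameter
(K2P) distances, with optional column-bootstrap supports and contraction
of weakly supported branches into polytomies.  The downstream placement
step consumes only gene-tree topologies, for which NJ is statistically
consistent in the regimes simulated here; an external tree file (e.g.
maximum-likelihood trees) can be substituted at the CLI level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .iupac import POPCOUNT, LocusAlignment
from .trees import Node, Tree, contract_low_support, internal_edge_supports

__all__ = [
    "FilterReport",
    "PairwiseComparableError",
    "count_parsimony_informative",
    "gap_ambiguity_fraction",
    "filter_alignments",
    "k2p_distance_matrix",
    "neighbor_joining",
    "attach_by_parsimony",
    "bootstrap_and_contract",
    "infer_gene_tree",
]

FILTER_REASONS = (
    "ok",
    "too_few_informative",
    "too_gappy",
    "duplicate_sequences",
    "inference_failed",
)


class PairwiseComparableError(ValueError):
    """A pair of rows shares no unambiguous columns."""


@dataclass(frozen=True)
class FilterReport:
    locus_id: str
    kept: bool
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in FILTER_REASONS:
            raise ValueError(f"unknown reason {self.reason!r}")
        if self.kept != (self.reason == "ok"):
            raise ValueError("kept must be True exactly when reason == 'ok'")


# bit mask -> base index (A=0, C=1, G=2, T=3), -1 for anything ambiguous
_BASE_IDX = np.full(16, -1, dtype=np.int8)
for _i, _b in enumerate((1, 2, 4, 8)):
    _BASE_IDX[_b] = _i
_IS_PURINE = np.array([True, False, True, False])  # A, C, G, T


def _base_index_matrix(msa: LocusAlignment) -> np.ndarray:
    return _BASE_IDX[msa.matrix]


def count_parsimony_informative(msa: LocusAlignment) -> int:
    """Number of parsimony-informative columns.

    A column is informative when at least two distinct unambiguous
    residues each occur in at least two rows; ambiguity codes, masks and
    gaps are treated as missing data.
    """
    M = _base_index_matrix(msa)
    if M.size == 0:
        return 0
    counts = np.stack([(M == b).sum(axis=0) for b in range(4)])
    return int(((counts >= 2).sum(axis=0) >= 2).sum())


def gap_ambiguity_fraction(msa: LocusAlignment) -> float:
    """Fraction of residues that are gaps, masks or ambiguity codes."""
    M = msa.matrix
    if M.size == 0:
        return 0.0
    return float((POPCOUNT[M] != 1).mean())


def filter_alignments(
    msas: Iterable[LocusAlignment],
    min_informative: int = 100,
    max_gap_fraction: float = 0.5,
) -> list[FilterReport]:
    """Apply the per-locus quality filters.

    A locus is discarded when it has fewer than ``min_informative``
    parsimony-informative sites, more than ``max_gap_fraction`` of gaps
    and ambiguities, or two identical rows (which make distances and
    topology degenerate).
    """
    if min_informative < 0 or not (0 <= max_gap_fraction <= 1):
        raise ValueError("thresholds out of range")
    reports = []
    for msa in msas:
        if count_parsimony_informative(msa) < min_informative:
            reports.append(FilterReport(msa.locus_id, False, "too_few_informative"))
        elif gap_ambiguity_fraction(msa) > max_gap_fraction:
            reports.append(FilterReport(msa.locus_id, False, "too_gappy"))
        elif len({s.residues for s in msa.sequences}) < len(msa.sequences):
            reports.append(FilterReport(msa.locus_id, False, "duplicate_sequences"))
        else:
            reports.append(FilterReport(msa.locus_id, True, "ok"))
    return reports


# --- K2P distances -------------------------------------------------------


def _k2p_from_counts(P: float, Q: float, ceiling: float) -> float:
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return ceiling
    d = -0.5 * math.log(w1 * math.sqrt(w2))
    return min(max(d, 0.0), ceiling)


def k2p_distance_matrix(
    msa: LocusAlignment,
    max_distance: float = 5.0,
) -> tuple[np.ndarray, list[str]]:
    """Kimura two-parameter distances over unambiguous shared columns.

    Columns where either row carries an ambiguity code or mask are
    excluded pairwise; saturated pairs are capped at ``max_distance``.
    A pair with no comparable columns raises
    :class:`PairwiseComparableError` naming the pair.
    """
    labels = msa.taxa
    M = _base_index_matrix(msa)
    n = len(labels)
    D = np.zeros((n, n), dtype=float)
    valid = M >= 0
    purine = np.zeros_like(valid)
    purine[valid] = _IS_PURINE[M[valid]]
    for i in range(n):
        for j in range(i + 1, n):
            comp = valid[i] & valid[j]
            nc = int(comp.sum())
            if nc == 0:
                raise PairwiseComparableError(
                    f"locus {msa.locus_id}: no comparable columns between "
                    f"{labels[i]!r} and {labels[j]!r}"
                )
            diff = comp & (M[i] != M[j])
            transitions = int((diff & (purine[i] == purine[j])).sum())
            transversions = int(diff.sum()) - transitions
            D[i, j] = D[j, i] = _k2p_from_counts(
                transitions / nc, transversions / nc, max_distance
            )
    return D, labels


# --- neighbor joining ----------------------------------------------------


def neighbor_joining(D: np.ndarray, labels: Sequence[str]) -> Tree:
    """Standard neighbor joining (Saitou & Nei / Studier & Keppler).

    Deterministic: on ties in the Q criterion the lowest-index pair
    (row-major order) is merged.  Negative branch lengths are clamped to
    zero.  Returns an unrooted tree (trifurcating root).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n) or n != len(labels):
        raise ValueError("matrix and labels are inconsistent")
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")

    nodes: list[Node] = [Node(label=l) for l in labels]
    D = D.copy()
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        flat = Q[iu]
        k = int(np.argmin(flat))  # first occurrence = lowest-index pair
        i, j = int(iu[0][k]), int(iu[1][k])

        dij = D[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        new = Node()
        a, b = nodes[i], nodes[j]
        a.length = max(li, 0.0)
        b.length = max(lj, 0.0)
        new.add(a)
        new.add(b)

        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        keep = [x for x in range(m) if x not in (i, j)]
        D = np.vstack([D[keep][:, keep], dnew[keep][None, :]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[x] for x in keep] + [new]

    # final three-taxon star via the three-point formula
    root = Node()
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lens = (
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    )
    for node, length in zip(nodes, lens):
        node.length = max(length, 0.0)
        root.add(node)
    return Tree(root)


# --- parsimony insertion of the focal row --------------------------------
#
# The polarized tetraploid row is a deliberate chimera of two subgenomes;
# global distance agglomeration averages its conflicting quartet signal
# and tends to attach it one node too basally.  Site-level parsimony
# resolves the conflict, so the focal row is placed by minimising a
# Fitch insertion score over the edges of the NJ tree built from the
# remaining rows.  IUPAC ambiguity codes enter the Fitch sets directly;
# masked sites are free (compatible with any state).


def _fitch_union_intersect(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    inter = a & b
    return np.where(inter > 0, inter, a | b).astype(np.uint8)


def attach_by_parsimony(tree: Tree, msa: LocusAlignment, taxon: str) -> Tree:
    """Insert ``taxon`` into ``tree`` on the edge minimising its Fitch
    parsimony insertion score over the alignment.

    ``tree`` must cover all of the alignment's taxa except ``taxon``.
    Ties are broken toward the smallest clade below the edge, then
    lexicographically.  Returns a new tree; branch lengths around the
    insertion point are split evenly and the new pendant edge has unit
    length (downstream placement uses topology only)."""
    if taxon not in msa.taxa:
        raise ValueError(f"{taxon!r} not in alignment")
    leaf_bits = {t: msa.row_bits(t) for t in tree.leaf_labels}
    return _attach_parsimony_core(tree, leaf_bits, msa.row_bits(taxon), taxon)


def _attach_parsimony_core(
    tree: Tree,
    leaf_bits_raw: dict[str, np.ndarray],
    target_raw: np.ndarray,
    taxon: str,
) -> Tree:
    L = target_raw.size
    leaf_bits: dict[str, np.ndarray] = {}
    for t, v in leaf_bits_raw.items():
        v = v.copy()
        v[v == 0] = 15
        leaf_bits[t] = v

    down: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            down[id(node)] = leaf_bits[node.label]
        else:
            acc = None
            for c in node.children:
                acc = down[id(c)] if acc is None else _fitch_union_intersect(acc, down[id(c)])
            down[id(node)] = acc
    up: dict[int, np.ndarray] = {id(tree.root): np.full(L, 15, dtype=np.uint8)}
    for node in tree.preorder():
        for c in node.children:
            acc = up[id(node)]
            for s in node.children:
                if s is not c:
                    acc = _fitch_union_intersect(acc, down[id(s)])
            up[id(c)] = acc

    target = target_raw.copy()
    target[target == 0] = 15
    best: tuple[tuple, Node] | None = None
    for node in tree.preorder():
        if node.parent is None:
            continue
        edge_states = _fitch_union_intersect(down[id(node)], up[id(node)])
        cost = int(((edge_states & target) == 0).sum())
        clade = tree.leafset(node)
        key = (cost, len(clade), tuple(sorted(clade)))
        if best is None or key < best[0]:
            best = (key, node)
    assert best is not None

    out = tree.copy()
    # locate the matching node in the copy by its clade
    clade = tree.leafset(best[1])
    chosen = None
    for node in out.preorder():
        if node.parent is not None and out.leafset(node) == clade:
            chosen = node
            break
    parent = chosen.parent
    idx = parent.children.index(chosen)
    joint = Node()
    half = (chosen.length or 1.0) / 2.0
    joint.length = half
    chosen.length = half
    parent.children[idx] = joint
    joint.parent = parent
    joint.add(chosen)
    joint.add(Node(taxon, 1.0))
    return out


# --- bootstrap and contraction -------------------------------------------


def _pair_category_matrix(msa: LocusAlignment) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Per pair, per column category: 0 incomparable, 1 match,
    2 transition, 3 transversion."""
    M = _base_index_matrix(msa)
    n = M.shape[0]
    valid = M >= 0
    purine = np.zeros_like(valid)
    purine[valid] = _IS_PURINE[M[valid]]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    C = np.zeros((len(pairs), M.shape[1]), dtype=np.uint8)
    for p, (i, j) in enumerate(pairs):
        comp = valid[i] & valid[j]
        same = comp & (M[i] == M[j])
        diff = comp & ~same
        ti = diff & (purine[i] == purine[j])
        row = C[p]
        row[same] = 1
        row[ti] = 2
        row[diff & ~ti] = 3
    return C, pairs


def _single_tree(msa: LocusAlignment, focal_taxon: str | None, max_distance: float) -> Tree:
    """One gene-tree estimate: NJ over all rows, or NJ over the
    non-focal rows plus parsimony insertion of the focal row."""
    if focal_taxon is not None and focal_taxon in msa.taxa:
        rest = msa.drop_taxa([focal_taxon])
        D, labels = k2p_distance_matrix(rest, max_distance=max_distance)
        return attach_by_parsimony(neighbor_joining(D, labels), msa, focal_taxon)
    D, labels = k2p_distance_matrix(msa, max_distance=max_distance)
    return neighbor_joining(D, labels)


def _tree_bipartitions(tree: Tree, all_leaves: frozenset, anchor: str) -> set:
    out = set()
    for node in tree.preorder():
        if node.parent is None or node.is_leaf:
            continue
        side = tree.leafset(node)
        if anchor in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(side)
    return out


def bootstrap_and_contract(
    msa: LocusAlignment,
    replicates: int = 200,
    support_threshold: float = 30.0,
    seed: int | None = None,
    max_distance: float = 5.0,
    focal_taxon: str | None = None,
) -> Tree:
    """NJ tree with column-bootstrap supports; branches with support
    <= ``support_threshold`` (percent) collapsed into polytomies.

    Support of an internal branch is the percentage of column-resampled
    replicates whose re-estimated tree contains the same bipartition.
    Seeded and reproducible.  With ``focal_taxon`` the focal row is
    attached by parsimony insertion in the base tree and in every
    replicate.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    base = _single_tree(msa, focal_taxon, max_distance)
    labels = msa.taxa
    all_leaves = frozenset(labels)
    anchor = min(all_leaves)
    targets = {side: 0 for side in internal_edge_supports(base) if side}
    if not targets:
        return base

    L = msa.column_count
    rng = np.random.default_rng(seed)

    if focal_taxon is None or focal_taxon not in msa.taxa:
        # fast path: K2P recomputed from per-column category counts
        C, pairs = _pair_category_matrix(msa)
        is_match = (C == 1).astype(np.float64)
        is_ti = (C == 2).astype(np.float64)
        is_tv = (C == 3).astype(np.float64)
        n = len(labels)
        for _ in range(replicates):
            w = np.bincount(rng.integers(0, L, size=L), minlength=L).astype(np.float64)
            nm, nti, ntv = is_match @ w, is_ti @ w, is_tv @ w
            nc = nm + nti + ntv
            Db = np.zeros((n, n))
            for p, (i, j) in enumerate(pairs):
                if nc[p] == 0:
                    d = max_distance
                else:
                    d = _k2p_from_counts(nti[p] / nc[p], ntv[p] / nc[p], max_distance)
                Db[i, j] = Db[j, i] = d
            rep = neighbor_joining(Db, labels)
            for side in _tree_bipartitions(rep, all_leaves, anchor) & targets.keys():
                targets[side] += 1
    else:
        rest_labels = [t for t in labels if t != focal_taxon]
        M = msa.matrix
        rest_rows = {t: i for i, t in enumerate(labels)}
        for _ in range(replicates):
            cols = rng.integers(0, L, size=L)
            sub = M[:, cols]
            # distances among the non-focal rows on resampled columns
            Mi = _BASE_IDX[sub]
            n = len(rest_labels)
            valid = Mi >= 0
            purine = np.zeros_like(valid)
            purine[valid] = _IS_PURINE[Mi[valid]]
            Db = np.zeros((n, n))
            for a in range(n):
                ia = rest_rows[rest_labels[a]]
                for b in range(a + 1, n):
                    ib = rest_rows[rest_labels[b]]
                    comp = valid[ia] & valid[ib]
                    nc = int(comp.sum())
                    if nc == 0:
                        Db[a, b] = Db[b, a] = max_distance
                        continue
                    diff = comp & (Mi[ia] != Mi[ib])
                    ti = int((diff & (purine[ia] == purine[ib])).sum())
                    Db[a, b] = Db[b, a] = _k2p_from_counts(
                        ti / nc, (int(diff.sum()) - ti) / nc, max_distance
                    )
            rep_tree = neighbor_joining(Db, rest_labels)
            leaf_bits = {t: sub[rest_rows[t]] for t in rest_labels}
            rep = _attach_parsimony_core(
                rep_tree, leaf_bits, sub[rest_rows[focal_taxon]], focal_taxon
            )
            for side in _tree_bipartitions(rep, all_leaves, anchor) & targets.keys():
                targets[side] += 1

    for node in base.preorder():
        if node.parent is None or node.is_leaf:
            continue
        side = base.leafset(node)
        if anchor in side:
            side = all_leaves - side
        if side in targets:
            node.support = 100.0 * targets[side] / replicates
    return contract_low_support(base, support_threshold)


def infer_gene_tree(
    msa: LocusAlignment,
    bootstrap_replicates: int = 0,
    support_threshold: float = 30.0,
    seed: int | None = None,
    max_distance: float = 5.0,
    focal_taxon: str | None = None,
) -> Tree:
    """Infer one gene tree.

    Plain inference when ``bootstrap_replicates`` is 0, otherwise with
    bootstrap supports and low-support contraction.  ``focal_taxon``
    (the polarized tetraploid) is attached by Fitch parsimony insertion
    onto the NJ tree of the remaining rows: the polarized row mixes the
    signal of two subgenomes and global distance agglomeration tends to
    attach it too basally, which site-level parsimony resolves."""
    if bootstrap_replicates > 0:
        return bootstrap_and_contract(
            msa,
            replicates=bootstrap_replicates,
            support_threshold=support_threshold,
            seed=seed,
            max_distance=max_distance,
            focal_taxon=focal_taxon,
        )
    return _single_tree(msa, focal_taxon, max_distance)
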