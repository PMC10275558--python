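"""Backbone estimation, quartet restriction, quartet placement (with a
brute-force oracle), branch quartet support, and pairing frequencies."""

import itertools

import numpy as np
import pytest

from polarphase.placement import (
    attach_polyploid,
    average_distance_backbone,
    branch_quartet_support,
    pairing_frequencies,
    place_by_quartets,
    quartet_topology,
)
from polarphase.trees import Tree, bipartitions, tree_from_newick


def T(newick):
    return tree_from_newick(newick)


# --- quartet restriction ---------------------------------------------------


def test_quartet_topology_direct_restriction():
    tree = T("((a,b),(c,d));")
    assert quartet_topology(tree, "abcd") == frozenset(
        {frozenset("ab"), frozenset("cd")}
    )


def test_quartet_topology_star_unresolved():
    assert quartet_topology(T("(a,b,c,d);"), "abcd") is None


def test_quartet_topology_caterpillar():
    tree = T("(((a,c),b),d);")
    assert quartet_topology(tree, "abcd") == frozenset(
        {frozenset("ac"), frozenset("bd")}
    )


def test_quartet_topology_embedded_in_larger_tree():
    tree = T("(((a,e),(b,f)),((c,g),d));")
    assert quartet_topology(tree, "abcd") == frozenset(
        {frozenset("ab"), frozenset("cd")}
    )


# --- backbone --------------------------------------------------------------


def test_backbone_identical_gene_trees():
    trees = [T("((a,b),(c,d),e);") for _ in range(5)]
    backbone = average_distance_backbone(trees)
    assert bipartitions(backbone) == bipartitions(trees[0])


def test_backbone_majority_vote_two_to_one():
    trees = [T("((a,b),(c,d));"), T("((a,b),(c,d));"), T("((a,c),(b,d));")]
    backbone = average_distance_backbone(trees)
    assert frozenset({"c", "d"}) in bipartitions(backbone) or frozenset(
        {"a", "b"}
    ) in bipartitions(backbone)


def test_backbone_requires_cooccurring_taxa():
    with pytest.raises(ValueError):
        average_distance_backbone([T("((a,b),(c,d));"), T("((e,f),(g,h));")])


# --- placement --------------------------------------------------------------


BACKBONE5 = "((A,B),(C,D),E);"


def _random_binary_newick(labels, rng):
    items = list(labels)
    rng.shuffle(items)
    while len(items) > 3:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        merged = f"({items[i]},{items[j]})"
        items = [x for k, x in enumerate(items) if k not in (i, j)] + [merged]
    return f"({items[0]},{items[1]},{items[2]});"


def _oracle_place(backbone, gene_trees, poly):
    """Exhaustive, independent evaluation of the quartet objective: for
    every edge, attach the polyploid, and count agreeing gene-tree
    quartets via bipartition separation."""
    labels = sorted(backbone.leaf_labels)

    def quartet_split(tree, quartet):
        # independent induced-topology routine: a pairing holds iff some
        # internal edge separates the two pairs
        all_leaves = frozenset(tree.leaf_labels)
        for side in bipartitions(tree):
            for pair in itertools.combinations(quartet, 2):
                rest = tuple(x for x in quartet if x not in pair)
                if (set(pair) <= side and not set(rest) & side) or (
                    set(rest) <= side and not set(pair) & side
                ):
                    return frozenset({frozenset(pair), frozenset(rest)})
        return None

    candidate_edges = set()
    all_leaves = frozenset(labels)
    for side in bipartitions(backbone):
        candidate_edges.add(side)
    for leaf in labels:
        candidate_edges.add(frozenset({leaf}))
    candidate_edges.add(all_leaves - frozenset({min(labels)}))  # root-adjacent dup

    scores = {}
    for edge_side in candidate_edges:
        if len(edge_side) >= len(labels):
            continue
        try:
            attached = attach_polyploid(backbone, edge_side, poly)
        except Exception:
            continue
        score = 0
        for gt in gene_trees:
            for triple in itertools.combinations(labels, 3):
                q = (poly,) + triple
                gq = quartet_split(gt, q)
                aq = quartet_split(attached, q)
                if gq is not None and gq == aq:
                    score += 1
        sister = min(edge_side, all_leaves - edge_side, key=lambda s: (len(s), tuple(sorted(s))))
        key = (-score, len(sister), tuple(sorted(sister)))
        prev = scores.get(frozenset(sister))
        if prev is None or key < prev:
            scores[frozenset(sister)] = key
    return min(scores.items(), key=lambda kv: kv[1])


def test_place_unanimous_signal():
    backbone = T(BACKBONE5)
    gene_trees = [T("((P,B),((A,E),(C,D)));") for _ in range(4)]
    result = place_by_quartets(backbone, gene_trees, "P")
    assert result.sister_group == frozenset({"B"})


def test_place_majority_two_to_one():
    backbone = T(BACKBONE5)
    gene_trees = [
        T("((P,B),((A,E),(C,D)));"),
        T("((P,B),((A,E),(C,D)));"),
        T("((P,C),((A,E),(B,D)));"),
    ]
    result = place_by_quartets(backbone, gene_trees, "P")
    assert result.sister_group == frozenset({"B"})


def test_place_matches_exhaustive_oracle_small_n():
    rng = np.random.default_rng(23)
    for n in (5, 6, 7):
        labels = [f"x{i}" for i in range(n)]
        for trial in range(4):
            backbone = T(_random_binary_newick(labels, rng))
            gene_trees = [
                T(_random_binary_newick(labels + ["P"], rng)) for _ in range(3)
            ]
            result = place_by_quartets(backbone, gene_trees, "P", compute_support=False)
            oracle_sister, _ = _oracle_place(backbone, gene_trees, "P")
            assert result.sister_group == oracle_sister


def test_place_invariant_to_gene_tree_leaf_order():
    backbone = T(BACKBONE5)
    g1 = T("((P,B),((A,E),(C,D)));")
    g2 = T("(((E,A),(D,C)),(B,P));")  # same topology, permuted writing
    r1 = place_by_quartets(backbone, [g1], "P")
    r2 = place_by_quartets(backbone, [g2], "P")
    assert r1.sister_group == r2.sister_group


def test_place_skips_gene_trees_without_polyploid():
    backbone = T(BACKBONE5)
    gene_trees = [T("((P,B),((A,E),(C,D)));"), T("((A,B),(C,D),E);")]
    result = place_by_quartets(backbone, gene_trees, "P")
    assert result.n_gene_trees == 1
    with pytest.raises(ValueError):
        place_by_quartets(backbone, [T("((A,B),(C,D),E);")], "P")


# --- branch quartet support --------------------------------------------------


def test_branch_support_congruent_trees():
    sp = T("((a,b),(c,d));")
    gts = [T("((a,b),(c,d));")] * 5
    s = branch_quartet_support(gts, sp, frozenset({"a", "b"}))
    assert (s.q1, s.q2, s.q3) == (1.0, 0.0, 0.0)


def test_branch_support_eight_of_ten():
    sp = T("((a,b),(c,d));")
    gts = [T("((a,b),(c,d));")] * 8 + [T("((a,c),(b,d));")] * 2
    s = branch_quartet_support(gts, sp, frozenset({"a", "b"}))
    assert s.q1 == pytest.approx(0.8)
    assert s.q1 + s.q2 + s.q3 == pytest.approx(1.0)


def test_branch_support_msc_closed_form():
    """Quartet support around an internal branch of t coalescent units
    approaches 1 - (2/3)exp(-t) under the multispecies coalescent."""
    from polarphase.simulate import SimulationConfig, sample_gene_trees
    from polarphase.trees import Node

    t_cu = 1.0
    # ultrametric 4-species tree: (A,B) split at 1, +t to ABC, root at 3
    a, b, c, d = (Node(x) for x in "ABCD")
    ab = Node()
    for leaf in (a, b):
        ab.add(leaf).length = 1.0
    abc = Node()
    abc.add(ab).length = t_cu
    abc.add(c).length = 1.0 + t_cu
    root = Node()
    root.add(abc).length = 3.0 - (1.0 + t_cu)
    root.add(d).length = 3.0
    species = Tree(root)

    cfg = SimulationConfig(
        n_species=4, individuals_per_species=1, n_loci=2000, ils_level="moderate", seed=31
    )
    gts = sample_gene_trees(species, cfg, np.random.default_rng(31))
    sp_with_tips = T("((A_0,B_0),(C_0,D_0));")
    s = branch_quartet_support(gts, sp_with_tips, frozenset({"A_0", "B_0"}))
    expected = 1.0 - (2.0 / 3.0) * np.exp(-t_cu)
    assert s.q1 == pytest.approx(expected, abs=0.03)
    assert s.q2 == pytest.approx((1 - expected) / 2, abs=0.03)


# --- pairing frequencies ------------------------------------------------------


def test_pairing_frequencies_simple_tally():
    gts = [T("(((P,B),(A,C)),OUT);")] * 7 + [T("(((P,C),(A,B)),OUT);")] * 3
    freqs = pairing_frequencies(gts, "P", outgroup="OUT")
    assert freqs[frozenset({"B"})] == pytest.approx(0.7)
    assert freqs[frozenset({"C"})] == pytest.approx(0.3)
    assert sum(freqs.values()) == pytest.approx(1.0)


def test_pairing_frequencies_multi_taxon_sister():
    gts = [T("((P,(X,Y)),(A,OUT));")] * 4
    freqs = pairing_frequencies(gts, "P", outgroup="OUT")
    assert freqs == {frozenset({"X", "Y"}): 1.0}


def test_pairing_frequencies_midpoint_fallback():
    gts = [T("((P:1,B:1):1,(A:1,C:5):1);")]
    freqs = pairing_frequencies(gts, "P", outgroup=None)
    assert freqs == {frozenset({"B"}): 1.0}


# --- attachment ----------------------------------------------------------------


def test_attach_polyploid_creates_expected_split():
    backbone = T(BACKBONE5)
    attached = attach_polyploid(backbone, {"C", "D"}, "P")
    assert frozenset({"P", "C", "D"}) in bipartitions(attached) or frozenset(
        {"A", "B", "E"}
    ) in bipartitions(attached)
    assert sorted(attached.leaf_labels) == ["A", "B", "C", "D", "E", "P"]
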