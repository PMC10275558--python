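"""Alignment filters, K2P distances, neighbor joining, parsimony
insertion of the focal row, and bootstrap contraction."""

import math

import dendropy
import numpy as np
import pytest

from polarphase.genetrees import (
    FilterReport,
    PairwiseComparableError,
    attach_by_parsimony,
    bootstrap_and_contract,
    count_parsimony_informative,
    filter_alignments,
    gap_ambiguity_fraction,
    infer_gene_tree,
    k2p_distance_matrix,
    neighbor_joining,
)
from polarphase.iupac import AlignedSequence, LocusAlignment
from polarphase.trees import Tree, bipartitions, root_with_outgroup, weighted_distance_matrix


def _msa(rows, locus="l"):
    return LocusAlignment(locus, [AlignedSequence(t, r) for t, r in rows])


def _columns_msa(columns):
    """Build an alignment from a list of per-column residue tuples."""
    n = len(columns[0])
    rows = ["".join(col[i] for col in columns) for i in range(n)]
    return _msa([(f"t{i}", r) for i, r in enumerate(rows)])


# --- parsimony-informative sites ---------------------------------------


def test_informative_column_definitions():
    assert count_parsimony_informative(_columns_msa(["AAGG"])) == 1
    assert count_parsimony_informative(_columns_msa(["AAAG"])) == 0  # singleton
    # ambiguity codes count as missing: RRAA has only one unambiguous pair
    toy = _columns_msa(["AAGG", "AAAG", "ACGT", "RRAA", "AAAA"])
    assert count_parsimony_informative(toy) == 1


# --- filters -------------------------------------------------------------


def _informative_block(n_informative, n_total=150):
    # singleton columns keep the four rows pairwise distinct without
    # adding parsimony-informative sites
    cols = (
        ["AAGG"] * n_informative
        + ["TAAA", "ATAA", "AATA", "AAAT"]
        + ["AAAA"] * (n_total - n_informative - 4)
    )
    return _columns_msa(cols)


def test_filter_min_informative_boundary():
    r99 = filter_alignments([_informative_block(99)])[0]
    r100 = filter_alignments([_informative_block(100)])[0]
    assert (r99.kept, r99.reason) == (False, "too_few_informative")
    assert (r100.kept, r100.reason) == (True, "ok")


def test_filter_duplicates_and_gaps():
    dup = _msa([("a", "ACGT" * 50), ("b", "ACGT" * 50), ("c", "AATT" * 50)])
    rep = filter_alignments([dup], min_informative=0)[0]
    assert rep.reason == "duplicate_sequences"

    gappy = _msa([("a", "AC" + "N" * 98), ("b", "AG" + "-" * 98)])
    rep = filter_alignments([gappy], min_informative=0)[0]
    assert rep.reason == "too_gappy"
    assert gap_ambiguity_fraction(gappy) == pytest.approx(0.98)


def test_filter_report_consistency_enforced():
    with pytest.raises(ValueError):
        FilterReport("x", True, "too_gappy")


# --- K2P ------------------------------------------------------------------


def test_k2p_identical_is_zero():
    D, _ = k2p_distance_matrix(_msa([("a", "ACGTACGT"), ("b", "ACGTACGT"), ("c", "ACGTAAAA")]))
    assert D[0, 1] == 0.0
    assert np.allclose(D, D.T) and np.all(np.diag(D) == 0)


def test_k2p_closed_form_single_transversion():
    # P=0, Q=1/4: d = -0.5*ln((1-2P-Q)*sqrt(1-2Q))
    expected = -0.5 * math.log((1 - 0.25) * math.sqrt(1 - 0.5))
    D, _ = k2p_distance_matrix(_msa([("a", "ACGT"), ("b", "ACGA"), ("c", "ACGT")]))
    assert D[0, 1] == pytest.approx(expected, abs=1e-9)
    assert D[0, 1] == pytest.approx(0.3171, abs=1e-3)


def test_k2p_no_comparable_columns_error():
    with pytest.raises(PairwiseComparableError):
        k2p_distance_matrix(_msa([("a", "AANN"), ("b", "NNTT"), ("c", "ACGT")]))


def test_k2p_consistent_on_simulated_pair():
    from polarphase.simulate import SimulationConfig, evolve_sequences
    from polarphase.trees import Node

    root = Node()
    for lab in ("a", "b"):
        root.add(Node(lab, 0.05))
    tree = Tree(root)
    cfg = SimulationConfig(fixed_length=10_000, seed=5)
    tips = evolve_sequences(tree, cfg, np.random.default_rng(5))
    D, _ = k2p_distance_matrix(
        _msa([("a", tips["a"]), ("b", tips["b"]), ("c", tips["a"])])
    )
    assert D[0, 1] == pytest.approx(0.1, abs=0.02)


# --- neighbor joining ------------------------------------------------------


ADDITIVE_D = np.array(
    [
        [0, 3, 5, 6],
        [3, 0, 6, 7],
        [5, 6, 0, 7],
        [6, 7, 7, 0],
    ],
    dtype=float,
)


def test_nj_recovers_additive_split_and_lengths():
    tree = neighbor_joining(ADDITIVE_D, list("ABCD"))
    assert bipartitions(tree) == frozenset({frozenset({"C", "D"})})
    W, labels = weighted_distance_matrix(tree, list("ABCD"))
    assert np.allclose(W, ADDITIVE_D)


def test_nj_three_taxa_three_point_formula():
    D = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], dtype=float)
    tree = neighbor_joining(D, list("ABC"))
    lengths = {n.label: n.length for n in tree.leaves()}
    assert lengths == {"A": 1.0, "B": 2.0, "C": 4.0}


def test_nj_requires_three_taxa():
    with pytest.raises(ValueError):
        neighbor_joining(np.zeros((2, 2)), ["a", "b"])


def _random_binary_tree(labels, rng):
    from polarphase.trees import Node

    nodes = [Node(l, float(rng.uniform(0.5, 2.0))) for l in labels]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(None, float(rng.uniform(0.5, 2.0)))
        parent.add(nodes[i])
        parent.add(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = Node()
    for n in nodes:
        root.add(n)
    return Tree(root)


def test_nj_recovers_random_additive_topologies():
    rng = np.random.default_rng(17)
    for n in (5, 6, 8):
        for _ in range(10):
            labels = [f"x{i}" for i in range(n)]
            true = _random_binary_tree(labels, rng)
            D, _ = weighted_distance_matrix(true, labels)
            est = neighbor_joining(D, labels)
            assert bipartitions(est) == bipartitions(true)


def test_nj_agrees_with_dendropy_oracle():
    """Independent check: dendropy's NJ on the same additive matrix."""
    labels = list("ABCD")
    pdm_csv = "," + ",".join(labels) + "\n"
    for i, l in enumerate(labels):
        pdm_csv += l + "," + ",".join(str(ADDITIVE_D[i, j]) for j in range(4)) + "\n"
    import io

    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
        io.StringIO(pdm_csv), delimiter=","
    )
    dtree = pdm.nj_tree()
    dsets = {
        frozenset(l.taxon.label for l in e.head_node.leaf_iter())
        for e in dtree.preorder_edge_iter()
        if e.head_node.parent_node is not None
    }
    assert frozenset({"C", "D"}) in dsets or frozenset({"A", "B"}) in dsets
    ours = bipartitions(neighbor_joining(ADDITIVE_D, labels))
    assert ours == frozenset({frozenset({"C", "D"})})


# --- parsimony insertion ---------------------------------------------------


def test_attach_by_parsimony_places_clean_taxon_at_its_sister():
    # x shares b's privately derived states: insertion must land on b's
    # pendant edge (cost 0 there, >=1 on every other edge)
    rows = [
        ("a", "AAAAAAAAGGGGA"),
        ("b", "CCCCAAAAGGGGA"),
        ("c", "AAAACCCCGGGGA"),
        ("d", "AAAACCCCCCCCA"),
        ("x", "CCCCAAAAGGGGG"),
    ]
    msa = _msa(rows)
    D, labels = k2p_distance_matrix(msa.drop_taxa(["x"]))
    tree = neighbor_joining(D, labels)
    full = attach_by_parsimony(tree, msa, "x")
    rooted = root_with_outgroup(full, "d")
    leaf = rooted.find_leaf("x")
    assert rooted.leafset(leaf.parent) == {"x", "b"}


# --- bootstrap and contraction ---------------------------------------------


def _clean_four_taxon_msa(n_cols=60):
    # every column supports ab|cd
    cols = ["AAGG", "CCTT", "GGAA"] * (n_cols // 3)
    return _columns_msa(cols)


def test_bootstrap_unanimous_data_full_support():
    msa = _clean_four_taxon_msa()
    tree = bootstrap_and_contract(msa, replicates=50, seed=1)
    sup = [n.support for n in tree.preorder() if n.parent is not None and not n.is_leaf]
    assert sup and all(s == 100.0 for s in sup)
    assert bipartitions(tree) == frozenset({frozenset({"t2", "t3"})})


def test_bootstrap_noise_data_contracts_to_polytomies():
    # iid random columns: no bipartition has real support, so some
    # internal branches fall at or below the 30% threshold
    rng = np.random.default_rng(2)
    rows = ["".join(rng.choice(list("ACGT"), size=200)) for _ in range(8)]
    msa = _msa([(f"t{i}", r) for i, r in enumerate(rows)])
    tree = bootstrap_and_contract(msa, replicates=100, seed=3)
    assert len(bipartitions(tree)) < 5  # 8-taxon binary tree would have 5


def test_bootstrap_deterministic_given_seed():
    msa = _clean_four_taxon_msa()
    t1 = bootstrap_and_contract(msa, replicates=30, seed=9)
    t2 = bootstrap_and_contract(msa, replicates=30, seed=9)
    assert t1.newick() == t2.newick()


def test_infer_gene_tree_focal_matches_bootstrap_focal_topology():
    msa = _msa(
        [
            ("a", "AAAAAAAAGGGG"),
            ("b", "CCCCAAAAGGGG"),
            ("c", "CCCCCCCCGGGG"),
            ("d", "CCCCCCCCCCCC"),
            ("x", "CCCCAAAAGGGA"),
        ]
    )
    plain = infer_gene_tree(msa, focal_taxon="x")
    boot = infer_gene_tree(msa, bootstrap_replicates=30, seed=4, focal_taxon="x")
    assert bipartitions(plain) >= bipartitions(boot)  # contraction only removes edges
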