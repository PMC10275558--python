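"""Reference selection, convergence detection, disambiguation of
nested vs sister parents, and the full iterative search on no-ILS
fixtures."""

import numpy as np
import pytest

from polarphase.placement import BranchSupport, PlacementResult
from polarphase.search import (
    DataError,
    SearchConfig,
    SearchState,
    detect_convergence,
    next_reference,
    run_search,
)
from polarphase.simulate import (
    NoIlsReplicate,
    SimulationConfig,
    _truth_set,
    equalize_branches,
    evolve_sequences,
    make_no_ils_replicate,
)
from polarphase.iupac import AlignedSequence, LocusAlignment, consensus_from_sequences
from polarphase.trees import tree_from_newick

CFG = SearchConfig(compute_support=False)


def _placement(*sister):
    s = frozenset(sister)
    return PlacementResult(s, s, None, 1)


def _states(sisters, refs=None):
    refs = refs or ["r"] * len(sisters)
    return [
        SearchState(i + 1, refs[i], _placement(*s)) for i, s in enumerate(sisters)
    ]


# --- next_reference ----------------------------------------------------------


def test_next_reference_singleton():
    rng = np.random.default_rng(0)
    assert next_reference(_placement("B"), rng) == "B"


def test_next_reference_multi_deterministic_and_excludes_previous():
    picks = {next_reference(_placement("X", "Y"), np.random.default_rng(7)) for _ in range(3)}
    assert len(picks) == 1 and picks <= {"X", "Y"}
    # the immediately preceding reference is excluded from the pick
    for seed in range(10):
        rng = np.random.default_rng(seed)
        assert next_reference(_placement("X", "Y"), rng, exclude="X") == "Y"


def test_next_reference_empty_sister_is_error():
    with pytest.raises(RuntimeError):
        next_reference(PlacementResult(frozenset(), frozenset(), None, 1), np.random.default_rng(0))


# --- detect_convergence -------------------------------------------------------


def test_detect_bimodal_two_cycle():
    states = _states([["16"], ["10"], ["16"], ["10"]])
    assert detect_convergence(states) == "bimodal"


def test_detect_unimodal_repeat():
    states = _states([["7"], ["7"]], refs=["3", "7"])
    assert detect_convergence(states) == "unimodal"


def test_detect_none_insufficient_evidence():
    assert detect_convergence(_states([["4"], ["9"]])) == "none"
    assert detect_convergence(_states([["4"]])) == "none"
    assert detect_convergence(_states([["4"], ["9"], ["4"]])) == "none"


# --- fixtures -----------------------------------------------------------------


def _fixture_from_newick(newick, parent_a, parent_b, seed=5, length=8000):
    """A single-locus no-ILS replicate on a hand-specified species tree."""
    from polarphase.simulate import NO_ILS_BRANCH_SUBS

    tree = equalize_branches(tree_from_newick(newick))
    sim_tree = tree.copy()
    for node in sim_tree.preorder():
        if node.length is not None:
            node.length = NO_ILS_BRANCH_SUBS
    cfg = SimulationConfig(
        n_species=len(tree.leaf_labels) - 1,
        individuals_per_species=1,
        fixed_length=length,
        ils_level="none",
        seed=seed,
    )
    tips = evolve_sequences(sim_tree, cfg, np.random.default_rng(seed))
    rep = NoIlsReplicate(
        species_tree=tree,
        haplotypes={l: tips[l] for l in sim_tree.leaf_labels},
        admissible=[],
        outgroup="OUT",
        tetraploid_name="TET",
        seed=seed,
    )
    return rep, rep.msa_for(parent_a, parent_b), _truth_set(tree, parent_a, parent_b)


DISTINCT_TREE = "(((((S1,S2),S3),((S4,S5),S6)),((S7,S8),(S9,S10))),OUT);"


def test_search_converges_in_two_iterations_from_parent_sister():
    # parents S1 (sister S2) and S4 (sister S5); initial reference = S2
    rep, msa, truth = _fixture_from_newick(DISTINCT_TREE, "S1", "S4")
    trace = run_search([msa], "TET", initial_reference="S2", seed=1, outgroup="OUT", config=CFG)
    assert trace.mode == "bimodal" and trace.converged
    assert trace.converged_at == 2
    assert set(trace.parent_calls) == truth == {frozenset({"S2"}), frozenset({"S5"})}


def test_search_converges_from_arbitrary_reference():
    rep, msa, truth = _fixture_from_newick(DISTINCT_TREE, "S1", "S4")
    trace = run_search([msa], "TET", initial_reference="S9", seed=1, outgroup="OUT", config=CFG)
    assert trace.converged and trace.converged_at <= 4
    assert set(trace.parent_calls) == truth


def test_search_trace_deterministic():
    rep = make_no_ils_replicate(77)
    a, b, ref = rep.admissible[0]
    msa = rep.msa_for(a, b)
    t1 = run_search([msa], "TET", initial_reference=ref, seed=9, outgroup="OUT", config=CFG)
    t2 = run_search([msa], "TET", initial_reference=ref, seed=9, outgroup="OUT", config=CFG)
    assert t1.references == t2.references
    assert t1.sisters == t2.sisters
    assert t1.parent_calls == t2.parent_calls


def test_search_backbone_excludes_polyploid_and_is_reused():
    rep = make_no_ils_replicate(78)
    a, b, ref = rep.admissible[0]
    trace = run_search([rep.msa_for(a, b)], "TET", initial_reference=ref, seed=2, outgroup="OUT", config=CFG)
    assert "TET" not in set(trace.backbone.leaf_labels)


NESTED_TREE = "(((P1,((P2,S4),S3)),(((S5,S6),(S7,S8)),(S9,S10))),OUT);"
SISTER_TREE = "((((P1,P2),S3),(((S5,S6),(S7,S8)),(S9,S10))),OUT);"


def test_nested_parents_both_positions_recovered():
    # nested pairs may resolve by bimodal alternation between the outer
    # and inner positions, or by unimodal disambiguation; either way the
    # two calls must be the nested pair of positions
    rep, msa, truth = _fixture_from_newick(NESTED_TREE, "P1", "P2")
    trace = run_search([msa], "TET", initial_reference="S9", seed=3, outgroup="OUT", config=CFG)
    assert trace.converged
    assert set(trace.parent_calls) == truth == {frozenset({"S3", "S4"}), frozenset({"S4"})}


def test_disambiguate_unimodal_unit_contract():
    from polarphase.search import disambiguate_unimodal

    backbone = tree_from_newick("(((S3,S4),(S5,S6)),((S7,S8),OUT));")
    position = frozenset({"S3", "S4"})

    # the distant reference must maximise topological distance from the
    # identified position (S7, S8 and OUT are all 4 edges away)
    seen = {}

    def moves(ref):
        seen["ref"] = ref
        return _placement("S4")

    kind, ref, placement = disambiguate_unimodal(
        position, backbone, moves, np.random.default_rng(0)
    )
    assert kind == "nested" and placement.sister_group == frozenset({"S4"})
    assert ref in {"S7", "S8", "OUT"}

    kind2, ref2, _ = disambiguate_unimodal(
        position, backbone, lambda r: _placement("S3", "S4"), np.random.default_rng(0)
    )
    assert kind2 == "sister_parents" and ref2 == ref  # same seeded tie-break


def test_unimodal_sister_parents_position_unmoved():
    rep, msa, truth = _fixture_from_newick(SISTER_TREE, "P1", "P2")
    trace = run_search([msa], "TET", initial_reference="S9", seed=3, outgroup="OUT", config=CFG)
    assert trace.initial_mode == "unimodal"
    assert trace.disambiguation == "sister_parents"
    assert set(trace.parent_calls) == truth == {frozenset({"S3"})}


def test_search_rejects_bad_inputs():
    rep, msa, _ = _fixture_from_newick(DISTINCT_TREE, "S1", "S4")
    with pytest.raises(ValueError):
        run_search([msa], "TET", initial_reference="TET", seed=0, config=CFG)
    with pytest.raises(ValueError):
        run_search([msa], "nope", seed=0, config=CFG)


def test_search_all_loci_filtered_is_data_error():
    rows = [
        AlignedSequence("TET", "ACGTACGT", "tetraploid"),
        AlignedSequence("A", "ACGTACGA"),
        AlignedSequence("B", "ACGAACGA"),
        AlignedSequence("C", "ACGAACGT"),
    ]
    msa = LocusAlignment("tiny", rows)
    with pytest.raises(DataError):
        run_search([msa], "TET", initial_reference="A", seed=0, config=CFG)
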