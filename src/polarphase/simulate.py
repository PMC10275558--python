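"""Synthetic benchmarks for the polarization protocol.

The generator emulates the evaluation design of the protocol: a random
species tree over 16 species plus an outgroup, gene trees drawn under
the multispecies coalescent at a controlled level of incomplete lineage
sorting (ILS), HKY sequences per locus, two haploid individuals per
species collapsed into diploid IUPAC consensus rows, and a tetraploid
built as the IUPAC merge of one haplotype from each of two parent
species -- whose rows are then removed from the MSA.

ILS levels are calibrated by the resulting mean normalized
Robinson-Foulds (nRF) distance between gene trees and the species tree:
``moderate`` targets ~0.2-0.35 and ``high`` ~0.5-0.7, matching the
discordance regimes of standard coalescent-based supertree benchmarks.
The knob is the species-tree height in coalescent units
(:data:`ILS_TREE_HEIGHT`).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import msprime
import numpy as np
from scipy.linalg import expm

from .iupac import AlignedSequence, LocusAlignment, consensus_from_sequences
from .placement import PlacementResult
from .search import SearchConfig, SearchTrace, run_search
from .trees import Node, Tree, robinson_foulds

__all__ = [
    "SimulationConfig",
    "Replicate",
    "NoIlsReplicate",
    "EvaluationSummary",
    "sample_species_tree",
    "equalize_branches",
    "sample_gene_trees",
    "evolve_sequences",
    "assemble_polyploid_msa",
    "make_replicate",
    "make_no_ils_replicate",
    "truth_positions",
    "classify_parent_pair",
    "evaluate_protocol",
    "mean_nrf",
    "run_no_ils_benchmark",
    "run_ils_benchmark",
]

#: Species-tree height (coalescent units) per ILS level; shorter trees
#: leave less time for lineages to sort, raising gene-tree discordance.
#: Calibrated so the mean normalized gene-tree/species-tree RF distance
#: lands near 0.2-0.35 (moderate) and 0.5-0.7 (high).
ILS_TREE_HEIGHT = {"none": 12.0, "moderate": 12.0, "high": 3.0}

#: Root-to-tip depth of the ingroup species tree in substitutions per
#: site, held constant across ILS levels (ILS and divergence are
#: controlled independently: the coalescent-unit height above sets
#: discordance, this sets sequence divergence).
SPECIES_TREE_HEIGHT_SUBS = 0.08

#: Branch length, in substitutions per site, of the unit-length branches
#: of the equalized no-ILS species trees.
NO_ILS_BRANCH_SUBS = 0.02

_HKY_KAPPA = 2.0
_HKY_FREQS = np.array([0.3, 0.2, 0.2, 0.3])  # A, C, G, T
_REF_NE = 10_000  # arbitrary scaling population size for msprime
# haploid lineages (ploidy=1) coalesce at rate 1/N per generation, so one
# coalescent unit is N generations
_GEN_PER_CU = float(_REF_NE)
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated replicate set."""

    n_species: int = 16
    outgroup_name: str = "OUT"
    individuals_per_species: int = 2
    n_loci: int = 1200
    locus_length_mean: float = 1500.0
    locus_length_sd: float = 150.0
    fixed_length: int | None = None
    ils_level: str = "moderate"  # none | moderate | high
    speciation_depth: str = "recent"  # recent | ancient
    seed: int = 0
    tetraploid_name: str = "TET"

    def __post_init__(self) -> None:
        if self.ils_level not in ILS_TREE_HEIGHT:
            raise ValueError(f"unknown ils_level {self.ils_level!r}")
        if self.speciation_depth not in ("recent", "ancient"):
            raise ValueError(f"unknown speciation_depth {self.speciation_depth!r}")
        if min(self.n_species, self.individuals_per_species, self.n_loci) < 1:
            raise ValueError("counts must be positive")


@dataclass
class Replicate:
    """One simulated data set with its truth annotations."""

    species_tree: Tree  # coalescent-unit branch lengths, rooted, with outgroup
    parent_a: str
    parent_b: str
    msas: list[LocusAlignment]  # tetraploid inserted, parents removed
    config: SimulationConfig
    seed: int


# --- species trees -------------------------------------------------------


def _species_names(n: int) -> list[str]:
    return [f"S{i + 1:02d}" for i in range(n)]


def sample_species_tree(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> Tree:
    """Random ultrametric species tree over ``n_species`` plus the
    outgroup, in coalescent units.

    The ingroup topology and node heights follow a pure-birth (Yule)
    process rescaled so the ingroup root sits at the height implied by
    the ILS level; the outgroup attaches above it.  ``speciation_depth`` warps
    node heights (``ancient`` pushes splits toward the root, stretching
    pendant branches)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    names = _species_names(config.n_species)

    # forward pure-birth (Yule) process; the reconstructed-tree root
    # splits at time zero, times run toward the present
    root = Node()
    split_time: dict[int, float] = {id(root): 0.0}
    active = [root.add(Node()), root.add(Node())]
    t = 0.0
    while len(active) < config.n_species:
        k = len(active)
        t += rng.exponential(1.0 / k)
        node = active.pop(int(rng.integers(k)))
        split_time[id(node)] = t
        active.extend([node.add(Node()), node.add(Node())])
    t_end = t + rng.exponential(1.0 / config.n_species)
    # leaves are exchangeable: assign labels by a random permutation so
    # every labeled topology is reachable
    for name, leaf in zip((names[i] for i in rng.permutation(len(names))), active):
        leaf.label = name
    for node in Tree(root).preorder():
        if node.parent is None:
            continue
        end = split_time[id(node)] if node.children else t_end
        node.length = end - split_time[id(node.parent)]
    ingroup, height = root, t_end

    target = ILS_TREE_HEIGHT[config.ils_level]
    scale = target / height
    for node in Tree(ingroup).preorder():
        if node.length is not None:
            node.length *= scale

    if config.speciation_depth == "ancient":
        _warp_heights(ingroup, target, gamma=0.3)

    root = Node()
    root.add(ingroup)
    ingroup.length = 0.5 * target
    out = Node(label=config.outgroup_name, length=1.5 * target)
    root.add(out)
    return Tree(root)


def _node_heights(root: Node) -> dict[int, float]:
    """Height above the leaves for every node of an ultrametric clade."""
    heights: dict[int, float] = {}

    def depth(node: Node) -> float:
        if node.is_leaf:
            heights[id(node)] = 0.0
            return 0.0
        h = max(depth(c) + c.length for c in node.children)
        heights[id(node)] = h
        return h

    depth(root)
    return heights


def _warp_heights(root: Node, total: float, gamma: float) -> None:
    """Remap node heights h -> total*(h/total)**gamma in place (gamma<1
    pushes internal nodes rootward: older speciation events)."""
    heights = _node_heights(root)
    warped = {k: total * (h / total) ** gamma if h > 0 else 0.0 for k, h in heights.items()}
    stack = [root]
    while stack:
        node = stack.pop()
        for c in node.children:
            c.length = warped[id(node)] - warped[id(c)]
            stack.append(c)


def equalize_branches(tree: Tree) -> Tree:
    """Copy with every branch length set to one unit; removes short
    internal branches (quasi-polytomies) while keeping the topology."""
    out = tree.copy()
    for node in out.preorder():
        if node.parent is not None:
            node.length = 1.0
    return out


# --- gene trees under the MSC --------------------------------------------


def _demography_from_species_tree(tree: Tree) -> msprime.Demography:
    dem = msprime.Demography()
    heights = _node_heights(tree.root)
    counter = itertools.count()
    names: dict[int, str] = {}

    for node in tree.postorder():
        if node.is_leaf:
            names[id(node)] = node.label
            dem.add_population(name=node.label, initial_size=_REF_NE)
        else:
            name = f"anc{next(counter)}"
            names[id(node)] = name
            dem.add_population(name=name, initial_size=_REF_NE)
    for node in tree.preorder():
        if node.is_leaf:
            continue
        dem.add_population_split(
            time=heights[id(node)] * _GEN_PER_CU,
            derived=[names[id(c)] for c in node.children],
            ancestral=names[id(node)],
        )
    dem.sort_events()
    return dem


def _tskit_to_tree(ts, mu: float, tip_names: dict[int, str]) -> Tree:
    t = ts.first()
    root_id = t.root

    def convert(u: int) -> Node:
        node = Node(label=tip_names.get(u))
        for v in t.children(u):
            child = convert(v)
            child.length = (t.time(u) - t.time(v)) * mu
            node.add(child)
        return node

    return Tree(convert(root_id))


def sample_gene_trees(
    species_tree: Tree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    n_loci: int | None = None,
) -> list[Tree]:
    """One gene tree per locus, ``individuals_per_species`` tips per
    species, branch lengths in substitutions per site.

    ``ils_level='none'`` bypasses the coalescent: every gene tree is the
    species tree with zero-length duplicated tips."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_loci = n_loci if n_loci is not None else config.n_loci
    k = config.individuals_per_species

    subs_per_cu = SPECIES_TREE_HEIGHT_SUBS / ILS_TREE_HEIGHT[config.ils_level]
    if config.ils_level == "none":
        template = species_tree.copy()
        # coalescent units -> substitutions/site
        for node in template.preorder():
            if node.length is not None:
                node.length *= subs_per_cu
        # replace each species leaf by k identical zero-length tips
        for leaf in template.leaves():
            sp = leaf.label
            leaf.label = None
            for m in range(k):
                leaf.add(Node(label=f"{sp}_{m}", length=0.0))
        return [template.copy() for _ in range(n_loci)]

    dem = _demography_from_species_tree(species_tree)
    species = [l for l in species_tree.leaf_labels]
    mu = subs_per_cu / _GEN_PER_CU
    seed = int(rng.integers(1, 2**31 - 1))
    reps = msprime.sim_ancestry(
        samples={sp: k for sp in species},
        demography=dem,
        ploidy=1,
        num_replicates=n_loci,
        random_seed=seed,
    )
    trees = []
    for ts in reps:
        tip_names: dict[int, str] = {}
        per_sp: dict[str, int] = {}
        for u in ts.samples():
            sp = ts.population(ts.node(u).population).metadata["name"]
            m = per_sp.get(sp, 0)
            per_sp[sp] = m + 1
            tip_names[u] = f"{sp}_{m}"
        trees.append(_tskit_to_tree(ts, mu, tip_names))
    return trees


# --- sequence evolution ---------------------------------------------------


def _hky_rate_matrix(kappa: float = _HKY_KAPPA, freqs: np.ndarray = _HKY_FREQS) -> np.ndarray:
    Q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = freqs[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    # normalise to one expected substitution per site per unit time
    rate = -(freqs * np.diag(Q)).sum()
    return Q / rate


_Q_NORM = _hky_rate_matrix()


def evolve_sequences(
    gene_tree: Tree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> dict[str, str]:
    """Simulate one locus of HKY sequence evolution along a gene tree
    (branch lengths in substitutions per site); returns tip sequences.

    Locus length is N(mean, sd) truncated at 300 bp, or the configured
    fixed length; no indels."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if config.fixed_length is not None:
        L = int(config.fixed_length)
    else:
        L = max(300, int(round(rng.normal(config.locus_length_mean, config.locus_length_sd))))

    states: dict[int, np.ndarray] = {}
    root_seq = rng.choice(4, size=L, p=_HKY_FREQS)
    states[id(gene_tree.root)] = root_seq
    out: dict[str, str] = {}
    pmat_cache: dict[float, np.ndarray] = {}
    for node in gene_tree.preorder():
        if node.parent is None:
            seq = states[id(node)]
        else:
            bl = float(node.length or 0.0)
            parent_seq = states[id(node.parent)]
            if bl <= 0.0:
                seq = parent_seq
            else:
                P = pmat_cache.get(bl)
                if P is None:
                    P = expm(_Q_NORM * bl)
                    pmat_cache[bl] = P
                cum = P.cumsum(axis=1)
                u = rng.random(L)
                seq = (u[:, None] > cum[parent_seq]).sum(axis=1)
            states[id(node)] = seq
        if node.is_leaf:
            out[node.label] = "".join(_BASES[states[id(node)]])
    return out


# --- MSA assembly ----------------------------------------------------------


def assemble_polyploid_msa(
    tip_sequences: dict[str, str],
    species: Sequence[str],
    parent_a: str,
    parent_b: str,
    locus_id: str,
    individuals_per_species: int = 2,
    tetraploid_name: str = "TET",
) -> LocusAlignment:
    """Collapse individuals to diploid IUPAC consensi, build the
    tetraploid as the IUPAC merge of one haplotype from each parent, and
    drop the parental rows."""
    for p in (parent_a, parent_b):
        if f"{p}_0" not in tip_sequences:
            raise ValueError(f"missing haplotypes for parent {p!r}")
    rows = []
    for sp in species:
        if sp in (parent_a, parent_b):
            continue
        haps = [tip_sequences[f"{sp}_{m}"] for m in range(individuals_per_species)]
        if len(haps) == 1:
            rows.append(AlignedSequence(sp, haps[0], "diploid"))
        else:
            rows.append(AlignedSequence(sp, consensus_from_sequences(*haps), "diploid"))
    tetr = consensus_from_sequences(
        tip_sequences[f"{parent_a}_0"], tip_sequences[f"{parent_b}_0"]
    )
    rows.append(AlignedSequence(tetraploid_name, tetr, "tetraploid"))
    return LocusAlignment(locus_id, rows)


def make_replicate(config: SimulationConfig) -> Replicate:
    """One full simulated replicate: species tree, random parental pair,
    per-locus MSAs with the tetraploid inserted and parents removed."""
    rng = np.random.default_rng(config.seed)
    species_tree = sample_species_tree(config, rng)
    ingroup = [l for l in species_tree.leaf_labels if l != config.outgroup_name]
    ia, ib = rng.choice(len(ingroup), size=2, replace=False)
    parent_a, parent_b = sorted((ingroup[ia], ingroup[ib]))
    gene_trees = sample_gene_trees(species_tree, config, rng)
    species = list(species_tree.leaf_labels)
    msas = []
    for i, gt in enumerate(gene_trees):
        tips = evolve_sequences(gt, config, rng)
        msas.append(
            assemble_polyploid_msa(
                tips,
                species,
                parent_a,
                parent_b,
                locus_id=f"locus{i:04d}",
                individuals_per_species=config.individuals_per_species,
                tetraploid_name=config.tetraploid_name,
            )
        )
    return Replicate(species_tree, parent_a, parent_b, msas, config, config.seed)


# --- truth annotations ------------------------------------------------------


def _sibling_leafset(tree: Tree, taxon: str) -> frozenset[str]:
    leaf = tree.find_leaf(taxon)
    parent = leaf.parent
    if parent is None:
        raise ValueError(f"{taxon!r} is the root")
    return frozenset(tree.leafset(parent) - {taxon})


def truth_positions(
    tree: Tree, parent_a: str, parent_b: str
) -> tuple[frozenset[str], frozenset[str]]:
    """The phylogenetic positions of the two parents once both are
    removed from the tree: for each parent, the leaf set of the closest
    enclosing sibling clade that survives the removal."""
    parents = {parent_a, parent_b}

    def position(taxon: str) -> frozenset[str]:
        node = tree.find_leaf(taxon)
        while node.parent is not None:
            parent = node.parent
            sib = frozenset(tree.leafset(parent) - tree.leafset(node)) - parents
            if sib:
                return sib
            node = parent
        raise ValueError("no surviving sibling clade")

    return position(parent_a), position(parent_b)


def classify_parent_pair(tree: Tree, parent_a: str, parent_b: str) -> str:
    """'sister', 'nested' or 'distinct' topology of the parental pair."""
    sa = _sibling_leafset(tree, parent_a)
    sb = _sibling_leafset(tree, parent_b)
    if sa == {parent_b} or sb == {parent_a}:
        return "sister"
    if parent_b in sa or parent_a in sb:
        return "nested"
    return "distinct"


# --- the no-ILS, no-polytomy benchmark --------------------------------------


@dataclass
class NoIlsReplicate:
    """Single-locus no-ILS replicate with its admissible permutations.

    Holds one 20 kb haplotype per species on an equalized-branch-length
    species tree; the MSA for a given parental pair is materialised on
    demand (the tetraploid row depends on the pair)."""

    species_tree: Tree  # equalized branch lengths (units)
    haplotypes: dict[str, str]
    admissible: list[tuple[str, str, str]]  # (parent_a, parent_b, reference)
    outgroup: str
    tetraploid_name: str
    seed: int

    def msa_for(self, parent_a: str, parent_b: str) -> LocusAlignment:
        rows = [
            AlignedSequence(sp, seq, "diploid")
            for sp, seq in self.haplotypes.items()
            if sp not in (parent_a, parent_b)
        ]
        tetr = consensus_from_sequences(
            self.haplotypes[parent_a], self.haplotypes[parent_b]
        )
        rows.append(AlignedSequence(self.tetraploid_name, tetr, "tetraploid"))
        return LocusAlignment(f"noils{self.seed}", rows)


def admissible_permutations(
    tree: Tree, outgroup: str, tetraploid_name: str = "TET"
) -> list[tuple[str, str, str]]:
    """All (parent_a, parent_b, reference) permutations in which each
    parent has a singleton sister species and the parents are neither
    sister nor nested; the reference ranges over every remaining taxon."""
    species = [l for l in tree.leaf_labels if l != outgroup]
    perms = []
    for a, b in itertools.combinations(sorted(species), 2):
        if classify_parent_pair(tree, a, b) != "distinct":
            continue
        sa = _sibling_leafset(tree, a)
        sb = _sibling_leafset(tree, b)
        if len(sa) != 1 or len(sb) != 1:
            continue
        others = [t for t in tree.leaf_labels if t not in (a, b)]
        perms.extend((a, b, r) for r in sorted(others))
    return perms


def make_no_ils_replicate(
    seed: int,
    n_species: int = 16,
    length: int = 20_000,
    outgroup_name: str = "OUT",
    tetraploid_name: str = "TET",
) -> NoIlsReplicate:
    """Equalized-branch species tree, one 20 kb no-ILS locus, and the
    enumeration of admissible {parentA, parentB, reference} permutations."""
    config = SimulationConfig(
        n_species=n_species,
        individuals_per_species=1,
        n_loci=1,
        fixed_length=length,
        ils_level="none",
        outgroup_name=outgroup_name,
        tetraploid_name=tetraploid_name,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    tree = equalize_branches(sample_species_tree(config, rng))
    # unit branches -> substitutions/site for sequence evolution
    sim_tree = tree.copy()
    for node in sim_tree.preorder():
        if node.length is not None:
            node.length = NO_ILS_BRANCH_SUBS
    tips = evolve_sequences(sim_tree, config, rng)
    haplotypes = {lab: tips[lab] for lab in sim_tree.leaf_labels}
    admissible = admissible_permutations(tree, outgroup_name, tetraploid_name)
    return NoIlsReplicate(
        species_tree=tree,
        haplotypes=haplotypes,
        admissible=admissible,
        outgroup=outgroup_name,
        tetraploid_name=tetraploid_name,
        seed=seed,
    )


# --- evaluation --------------------------------------------------------------


@dataclass
class EvaluationSummary:
    """Accuracy accounting over a set of searches against known truth."""

    n: int
    accuracy_by_iteration: dict[int, float]  # cumulative both-parents-correct
    convergence_by_iteration: dict[int, float]  # cumulative convergence
    final_accuracy: float
    unimodal_fraction: float
    short_branch_failure_fraction: float | None


def _truth_set(tree: Tree, parent_a: str, parent_b: str) -> set[frozenset[str]]:
    pa, pb = truth_positions(tree, parent_a, parent_b)
    return {pa, pb}


def trace_correct_by(trace: SearchTrace, truth: set[frozenset[str]], k: int) -> bool:
    """Whether both parental positions had been identified by iteration
    ``k``: two consecutive placements (or a unimodal position plus its
    disambiguation) matching the truth positions."""
    sisters = trace.sisters
    for m in range(1, min(k, len(sisters))):
        if {sisters[m - 1], sisters[m]} == truth:
            return True
    if trace.disambiguation is not None and trace.states and trace.states[-1].iteration <= k:
        if truth == set(trace.parent_calls) or (
            len(truth) == 1 and trace.parent_calls and set(trace.parent_calls) == truth
        ):
            return True
    return False


def min_internal_branch(tree: Tree) -> float:
    vals = [
        node.length
        for node in tree.preorder()
        if node.parent is not None and not node.is_leaf and node.length is not None
    ]
    return min(vals) if vals else float("inf")


def evaluate_protocol(
    records: Sequence[tuple[Tree, str, str, SearchTrace]],
    max_iteration: int = 10,
    short_branch_threshold: float = 0.25,
) -> EvaluationSummary:
    """Score searches against truth.

    Each record is (species tree, parent_a, parent_b, trace).  A parent
    call is correct when it names the parent's position -- the sibling
    clade surviving the parents' removal.  Failures are cross-tabulated
    with the presence of very short internal branches (coalescent
    units) in the species tree."""
    n = len(records)
    acc = {}
    conv = {}
    final_correct = 0
    unimodal = 0
    fail_short = 0
    failures = 0
    for tree, pa, pb, trace in records:
        truth = _truth_set(tree, pa, pb)
        ok = set(trace.parent_calls) == truth and trace.converged
        if ok:
            final_correct += 1
        else:
            failures += 1
            if min_internal_branch(tree) < short_branch_threshold:
                fail_short += 1
        if trace.initial_mode == "unimodal":
            unimodal += 1
    for k in range(1, max_iteration + 1):
        acc[k] = sum(
            trace_correct_by(tr, _truth_set(t, a, b), k) for t, a, b, tr in records
        ) / n
        conv[k] = sum(
            1
            for _, _, _, tr in records
            if tr.converged and tr.converged_at is not None and tr.converged_at <= k
        ) / n
    return EvaluationSummary(
        n=n,
        accuracy_by_iteration=acc,
        convergence_by_iteration=conv,
        final_accuracy=final_correct / n,
        unimodal_fraction=unimodal / n,
        short_branch_failure_fraction=(fail_short / failures) if failures else None,
    )


def mean_nrf(gene_trees: Sequence[Tree], species_tree: Tree) -> float:
    """Mean normalized RF distance between gene trees (individual tips
    collapsed to species) and the species tree."""
    vals = []
    sp_labels = set(species_tree.leaf_labels)
    for gt in gene_trees:
        collapsed = _collapse_individuals(gt)
        if set(collapsed.leaf_labels) != sp_labels:
            raise ValueError("gene tree species do not match the species tree")
        vals.append(robinson_foulds(collapsed, species_tree, normalized=True))
    return float(np.mean(vals))


def _collapse_individuals(gene_tree: Tree) -> Tree:
    """Keep one tip per species (tip '_0') and relabel to species names."""
    keep = {}
    for label in gene_tree.leaf_labels:
        sp, _, idx = label.rpartition("_")
        if idx == "0":
            keep[label] = sp
    out = gene_tree.copy()
    # prune leaves not kept
    changed = True
    while changed:
        changed = False
        for node in list(out.postorder()):
            if node.is_leaf and node.label not in keep and node.parent is not None:
                node.parent.children.remove(node)
                changed = True
            elif not node.is_leaf and not node.children and node.parent is not None:
                node.parent.children.remove(node)
                changed = True
            elif not node.is_leaf and len(node.children) == 1 and node.parent is not None:
                child = node.children[0]
                child.length = (child.length or 0) + (node.length or 0)
                idx = node.parent.children.index(node)
                node.parent.children[idx] = child
                child.parent = node.parent
                changed = True
    while not out.root.is_leaf and len(out.root.children) == 1:
        out.root = out.root.children[0]
        out.root.parent = None
        out.root.length = None
    for leaf in out.leaves():
        leaf.label = keep.get(leaf.label, leaf.label)
    return out


# --- benchmark drivers -------------------------------------------------------


def run_no_ils_benchmark(
    seed: int,
    n_replicates: int = 10,
    max_permutations: int = 50,
    search_config: SearchConfig | None = None,
) -> dict:
    """The no-ILS, no-polytomy accuracy experiment at desk scale.

    For each replicate, enumerates admissible {parentA, parentB,
    reference} permutations (subsampled to ``max_permutations``), runs
    the full search for each, and scores first-iteration parental
    identification, both-parents-correct at convergence, and whether the
    polarized tetraploid's top identity match is a parental sister."""
    from .polarize import identity_ranking, polarize_alignment

    cfg = search_config or SearchConfig(compute_support=False)
    rng = np.random.default_rng(seed)
    first_hits = 0
    both_correct = 0
    top_identity = 0
    total = 0
    for r in range(n_replicates):
        rep = make_no_ils_replicate(int(rng.integers(2**31 - 1)))
        perms = rep.admissible
        if len(perms) > max_permutations:
            sel = rng.choice(len(perms), size=max_permutations, replace=False)
            perms = [perms[i] for i in np.sort(sel)]
        for a, b, ref in perms:
            msa = rep.msa_for(a, b)
            truth = _truth_set(rep.species_tree, a, b)
            trace = run_search(
                [msa],
                rep.tetraploid_name,
                initial_reference=ref,
                seed=int(rng.integers(2**31 - 1)),
                outgroup=rep.outgroup,
                config=cfg,
            )
            total += 1
            if trace.sisters and trace.sisters[0] in truth:
                first_hits += 1
            if trace.converged and set(trace.parent_calls) == truth:
                both_correct += 1
            # identity ranking of the first-iteration polarized sequence
            res, _ = polarize_alignment(msa, rep.tetraploid_name, ref)
            ranking = identity_ranking([msa], {msa.locus_id: res.polarized}, rep.tetraploid_name)
            top_taxon = ranking[0][0]
            parent_sisters = set().union(*truth)
            if top_taxon in parent_sisters:
                top_identity += 1
    return {
        "n": total,
        "first_iteration_rate": first_hits / total if total else float("nan"),
        "converged_both_correct_rate": both_correct / total if total else float("nan"),
        "top_identity_rate": top_identity / total if total else float("nan"),
    }


def run_ils_benchmark(
    ils_level: str,
    seed: int,
    n_replicates: int = 20,
    n_loci: int = 200,
    search_config: SearchConfig | None = None,
    max_iterations: int = 10,
) -> dict:
    """The unconstrained-ILS accuracy experiment at desk scale.

    Each replicate draws a fresh species tree and a uniformly random
    parental pair (sister and nested pairs included), simulates MSC gene
    trees and sequences, and runs the iterative search with a random
    initial reference."""
    cfg = search_config or SearchConfig(compute_support=False)
    rng = np.random.default_rng(seed)
    records = []
    for r in range(n_replicates):
        config = SimulationConfig(
            ils_level=ils_level,
            n_loci=n_loci,
            seed=int(rng.integers(2**31 - 1)),
        )
        rep = make_replicate(config)
        trace = run_search(
            rep.msas,
            config.tetraploid_name,
            initial_reference=None,
            max_iterations=max_iterations,
            seed=int(rng.integers(2**31 - 1)),
            outgroup=config.outgroup_name,
            config=cfg,
        )
        records.append((rep.species_tree, rep.parent_a, rep.parent_b, trace))
    summary = evaluate_protocol(records, max_iteration=max_iterations)
    return {
        "n": summary.n,
        "accuracy_by_iteration": summary.accuracy_by_iteration,
        "accuracy_iter3": summary.accuracy_by_iteration.get(3, float("nan")),
        "convergence_by_iteration": summary.convergence_by_iteration,
        "final_accuracy": summary.final_accuracy,
        "unimodal_fraction": summary.unimodal_fraction,
        "short_branch_failure_fraction": summary.short_branch_failure_fraction,
        "records": records,
    }
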