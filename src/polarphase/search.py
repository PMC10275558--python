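"""The iterative polarize -> infer -> place loop.

Each iteration polarizes the tetraploid against the current reference
taxon, re-infers the gene trees, and places the polarized sequence on a
fixed backbone.  The reference for the next iteration is the polyploid's
closest relative from the current placement.  Once the placement
alternates between two positions (one full two-cycle observed) the
search has reached its bimodal equilibrium and the two alternating
sister groups are the parental positions.  A search that keeps returning
to a single position (unimodal convergence) is disambiguated with one
extra iteration polarized against a phylogenetically distant reference:
if the placement moves, the parents were nested and the new position is
the second parent's; if it stays, the parents are sister species.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .genetrees import filter_alignments, infer_gene_tree
from .iupac import LocusAlignment, trim_masked_columns
from .placement import (
    PlacementResult,
    attach_polyploid,
    average_distance_backbone,
    pairing_frequencies,
    place_by_quartets,
)
from .polarize import polarize_alignment
from .trees import Tree, topo_distance_matrix

__all__ = [
    "SearchConfig",
    "SearchState",
    "SearchTrace",
    "DataError",
    "next_reference",
    "detect_convergence",
    "disambiguate_unimodal",
    "run_search",
]

logger = logging.getLogger(__name__)


class DataError(RuntimeError):
    """The input data cannot sustain the search (e.g. every locus was
    discarded by the alignment filters)."""


@dataclass
class SearchConfig:
    """Tunable knobs of the search pipeline."""

    max_masked: int = 2  # masked-column trimming threshold
    min_informative: int = 100
    max_gap_fraction: float = 0.5
    bootstrap_replicates: int = 0  # 0 = plain NJ gene trees, no contraction
    support_threshold: float = 30.0
    max_distance: float = 5.0  # K2P saturation ceiling
    parsimony_insertion: bool = True  # focal row attached by Fitch score
    compute_support: bool = True
    compute_pairing: bool = False


@dataclass(frozen=True)
class SearchState:
    iteration: int
    reference_taxon: str
    placement: PlacementResult
    pairing: dict[frozenset[str], float] | None = None


@dataclass
class SearchTrace:
    states: list[SearchState]
    mode: str  # bimodal | unimodal | none
    parent_calls: list[frozenset[str]]
    converged: bool
    converged_at: int | None
    seed: int
    initial_mode: str | None = None  # convergence mode before disambiguation
    disambiguation: str | None = None  # nested | sister_parents
    backbone: Tree | None = field(default=None, repr=False)

    @property
    def sisters(self) -> list[frozenset[str]]:
        return [s.placement.sister_group for s in self.states]

    @property
    def references(self) -> list[str]:
        return [s.reference_taxon for s in self.states]


def next_reference(
    placement: PlacementResult,
    rng: np.random.Generator,
    exclude: str | None = None,
) -> str:
    """The reference for the next iteration: the polyploid's closest
    relative; a seeded uniform pick when the sister group has several
    members (excluding the immediately preceding reference)."""
    sister = sorted(placement.sister_group)
    if not sister:
        raise RuntimeError("placement has an empty sister group")
    if len(sister) == 1:
        return sister[0]
    candidates = [t for t in sister if t != exclude] or sister
    return candidates[int(rng.integers(len(candidates)))]


def detect_convergence(states: Sequence[SearchState]) -> str:
    """Classify the current state sequence.

    bimodal: one full two-cycle of sister groups observed (the last four
    placements alternate between two distinct sets); unimodal: the last
    two placements coincide; none: anything else.
    """
    if len(states) < 2:
        return "none"
    s = [st.placement.sister_group for st in states]
    if s[-1] == s[-2]:
        return "unimodal"
    if len(s) >= 4 and s[-1] == s[-3] and s[-2] == s[-4] and s[-1] != s[-2]:
        return "bimodal"
    return "none"


def _converged_at(sisters: Sequence[frozenset[str]]) -> int:
    """Earliest iteration (1-based) by which the two alternating parental
    positions had both been visited and the alternation held from then on."""
    n = len(sisters)
    for start in range(2, n + 1):
        if all(sisters[m] == sisters[m - 2] for m in range(start, n)):
            return start
    return n


def _attachment_distances(backbone: Tree, sister_group: frozenset[str]) -> dict[str, float]:
    """Topological distance from the attachment point implied by a sister
    group to every backbone leaf."""
    labels = sorted(backbone.leaf_labels)
    D, _ = topo_distance_matrix(backbone, labels)
    inside = [i for i, l in enumerate(labels) if l in sister_group]
    if not inside:
        raise ValueError("sister group not on backbone")
    # distance to the clade = min over its members; +0 constant offsets
    # do not change the argmax
    return {
        l: float(min(D[i, j] for j in inside))
        for i, l in enumerate(labels)
        if l not in sister_group
    }


def disambiguate_unimodal(
    sister_group: frozenset[str],
    backbone: Tree,
    run_iteration: Callable[[str], PlacementResult],
    rng: np.random.Generator,
) -> tuple[str, str, PlacementResult]:
    """Resolve nested-parents vs sister-parents after unimodal convergence.

    Picks the backbone taxon phylogenetically furthest from the single
    identified parental position (ties broken by a seeded pick), reruns
    one iteration with it as the reference, and classifies the outcome.
    Returns (classification, reference used, new placement).
    """
    dist = _attachment_distances(backbone, sister_group)
    dmax = max(dist.values())
    ties = sorted(t for t, d in dist.items() if d == dmax)
    ref = ties[int(rng.integers(len(ties)))] if len(ties) > 1 else ties[0]
    placement = run_iteration(ref)
    if placement.sister_group != sister_group:
        return "nested", ref, placement
    return "sister_parents", ref, placement


def _locus_seed(seed: int, reference: str, locus_id: str) -> int:
    return zlib.crc32(f"{seed}:{reference}:{locus_id}".encode()) & 0x7FFFFFFF


def run_search(
    msas: Sequence[LocusAlignment],
    polyploid_taxon: str,
    initial_reference: str | None = None,
    max_iterations: int = 10,
    seed: int = 0,
    outgroup: str | None = None,
    config: SearchConfig | None = None,
) -> SearchTrace:
    """Run the full iterative parental-position search.

    The backbone is estimated once, from the unpolarized non-focal taxa,
    and is identical across iterations; only the polarized polyploid's
    placement moves.  Gene trees are cached per reference taxon so that
    a two-cycle revisiting a reference costs nothing.
    """
    cfg = config or SearchConfig()
    msas = [trim_masked_columns(m, cfg.max_masked) for m in msas]
    if not msas:
        raise DataError("no input alignments")
    for m in msas:
        if polyploid_taxon not in m:
            raise ValueError(f"polyploid {polyploid_taxon!r} missing from locus {m.locus_id}")
    taxa = [t for t in msas[0].taxa if t != polyploid_taxon]
    if len(taxa) < 3:
        raise ValueError("need at least 4 taxa (including the polyploid)")
    rng = np.random.default_rng(seed)

    # backbone from the unpolarized non-focal taxa, computed once
    backbone_msas = [m.drop_taxa([polyploid_taxon]) for m in msas]
    kept = [
        m
        for m, rep in zip(
            backbone_msas,
            filter_alignments(backbone_msas, cfg.min_informative, cfg.max_gap_fraction),
        )
        if rep.kept
    ]
    if not kept:
        raise DataError("all loci discarded while estimating the backbone")
    backbone_trees = [
        infer_gene_tree(
            m,
            bootstrap_replicates=cfg.bootstrap_replicates,
            support_threshold=cfg.support_threshold,
            seed=_locus_seed(seed, "<backbone>", m.locus_id),
            max_distance=cfg.max_distance,
        )
        for m in kept
    ]
    backbone = average_distance_backbone(backbone_trees)

    cache: dict[str, tuple[PlacementResult, dict | None]] = {}

    def run_iteration(reference: str) -> PlacementResult:
        if reference in cache:
            return cache[reference][0]
        polarized = [polarize_alignment(m, polyploid_taxon, reference)[1] for m in msas]
        reports = filter_alignments(polarized, cfg.min_informative, cfg.max_gap_fraction)
        kept_pol = [m for m, rep in zip(polarized, reports) if rep.kept]
        if not kept_pol:
            raise DataError(
                f"all loci discarded after polarizing against {reference!r}"
            )
        gene_trees = [
            infer_gene_tree(
                m,
                bootstrap_replicates=cfg.bootstrap_replicates,
                support_threshold=cfg.support_threshold,
                seed=_locus_seed(seed, reference, m.locus_id),
                max_distance=cfg.max_distance,
                focal_taxon=polyploid_taxon if cfg.parsimony_insertion else None,
            )
            for m in kept_pol
        ]
        placement = place_by_quartets(
            backbone,
            gene_trees,
            polyploid_taxon,
            outgroup=outgroup,
            compute_support=cfg.compute_support,
            seed=seed,
        )
        pairing = (
            pairing_frequencies(gene_trees, polyploid_taxon, outgroup=outgroup)
            if cfg.compute_pairing
            else None
        )
        cache[reference] = (placement, pairing)
        return placement

    if initial_reference is not None:
        if initial_reference == polyploid_taxon or initial_reference not in taxa:
            raise ValueError(f"invalid initial reference {initial_reference!r}")
        ref = initial_reference
    else:
        ref = sorted(taxa)[int(rng.integers(len(taxa)))]

    states: list[SearchState] = []
    trace = SearchTrace(
        states=states,
        mode="none",
        parent_calls=[],
        converged=False,
        converged_at=None,
        seed=seed,
        backbone=backbone,
    )

    for iteration in range(1, max_iterations + 1):
        placement = run_iteration(ref)
        states.append(
            SearchState(iteration, ref, placement, cache[ref][1])
        )
        logger.info(
            "iteration %d: reference=%s -> sister=%s",
            iteration,
            ref,
            sorted(placement.sister_group),
        )
        mode = detect_convergence(states)
        if mode == "bimodal":
            trace.mode = "bimodal"
            trace.initial_mode = "bimodal"
            trace.converged = True
            trace.converged_at = _converged_at(trace.sisters)
            calls = [states[-1].placement.sister_group, states[-2].placement.sister_group]
            trace.parent_calls = sorted(calls, key=lambda s: tuple(sorted(s)))
            return trace
        if mode == "unimodal":
            # conservative: a single chance repeat of a noisy placement
            # must not end the search; the position has to persist over
            # three consecutive iterations before disambiguation
            sisters = trace.sisters
            if len(sisters) < 3 or sisters[-2] != sisters[-3]:
                ref = next_reference(placement, rng, exclude=ref)
                continue
            trace.initial_mode = "unimodal"
            position = placement.sister_group
            kind, dref, extra = disambiguate_unimodal(
                position, backbone, run_iteration, rng
            )
            states.append(
                SearchState(len(states) + 1, dref, extra, cache[dref][1])
            )
            trace.disambiguation = kind
            trace.converged = True
            trace.converged_at = states[-2].iteration
            if kind == "nested":
                trace.mode = "bimodal"
                trace.parent_calls = sorted(
                    [position, extra.sister_group], key=lambda s: tuple(sorted(s))
                )
            else:
                trace.mode = "unimodal"
                trace.parent_calls = [position]
            return trace
        ref = next_reference(placement, rng, exclude=ref)

    trace.mode = detect_convergence(states) if states else "none"
    return trace
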