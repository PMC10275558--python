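"""Alternative-allele polarization of a tetraploid consensus sequence.

Polarizing the allotetraploid against a reference taxon keeps, at every
heterozygous site, the alleles *not* present in the reference.  When the
reference coincides with (or is close to) one parental lineage this
masks that subgenome's signal, so the polarized sequence resembles the
other parent.  The site-wise rules:

* masked in the polyploid or the reference -> masked;
* fixed in the polyploid -> unchanged;
* polyploid alleles a subset of the reference's -> unchanged (removing
  them all would leave no allele);
* otherwise -> set difference (polyploid minus reference).

Only the focal tetraploid row is ever polarized; diploid and
autopolyploid rows pass through untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .iupac import (
    POPCOUNT,
    AlleleSet,
    LocusAlignment,
    MASKED,
    UnknownTaxonError,
    bits_to_seq,
    identity_counts,
    seq_to_bits,
)

__all__ = [
    "PolarizationResult",
    "polarize_site",
    "polarize_bits",
    "polarize_alignment",
    "identity_ranking",
]


@dataclass(frozen=True)
class PolarizationResult:
    """Per-locus accounting of one polarization pass."""

    locus_id: str
    polarized: str
    n_changed_sites: int
    n_masked_sites: int
    reference_taxon: str


def polarize_site(poly: AlleleSet, ref: AlleleSet) -> AlleleSet:
    """Apply the site-wise polarization rules to one column."""
    if poly.masked or ref.masked:
        return MASKED
    if len(poly.alleles) == 1:
        return poly
    if poly.alleles <= ref.alleles:
        return poly
    return AlleleSet(poly.alleles - ref.alleles)


# 16x16 lookup over (polyploid bits, reference bits); precomputed once so
# whole rows polarize with a single fancy-indexing pass.
_PAIR_LUT = np.zeros((16, 16), dtype=np.uint8)
for _p in range(16):
    for _r in range(16):
        if _p == 0 or _r == 0:
            _PAIR_LUT[_p, _r] = 0
        elif POPCOUNT[_p] == 1 or (_p & ~_r & 0xF) == 0:
            _PAIR_LUT[_p, _r] = _p
        else:
            _PAIR_LUT[_p, _r] = _p & ~_r & 0xF


def polarize_bits(poly: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Vectorised polarization of a bit-mask row against a reference row."""
    return _PAIR_LUT[poly, ref]


def polarize_alignment(
    msa: LocusAlignment,
    polyploid_taxon: str,
    reference_taxon: str,
) -> tuple[PolarizationResult, LocusAlignment]:
    """Polarize the tetraploid row of one locus against a reference taxon.

    Returns the per-locus accounting and a copy of the alignment in which
    the tetraploid row has been replaced by its polarized version; every
    other row is byte-identical to the input.
    """
    if polyploid_taxon == reference_taxon:
        raise ValueError("polyploid and reference taxa must differ")
    for taxon in (polyploid_taxon, reference_taxon):
        if taxon not in msa:
            raise UnknownTaxonError(taxon)
    poly = msa.row_bits(polyploid_taxon)
    ref = msa.row_bits(reference_taxon)
    out = polarize_bits(poly, ref)
    result = PolarizationResult(
        locus_id=msa.locus_id,
        polarized=bits_to_seq(out),
        n_changed_sites=int((out != poly).sum()),
        n_masked_sites=int((out == 0).sum()),
        reference_taxon=reference_taxon,
    )
    return result, msa.with_row(polyploid_taxon, result.polarized)


def identity_ranking(
    msas: Sequence[LocusAlignment],
    polarized: Mapping[str, str],
    polyploid_taxon: str,
    ambiguity_tolerant: bool = True,
) -> list[tuple[str, float]]:
    """Rank every non-focal taxon by cumulative identity to the polarized
    tetraploid.

    Comparable columns are pooled across loci before dividing, so long
    loci weigh more than short ones.  Taxa with no comparable columns are
    reported with NaN identity and ranked last.
    """
    matches: dict[str, int] = {}
    comparable: dict[str, int] = {}
    for msa in msas:
        if msa.locus_id not in polarized:
            continue
        pol = seq_to_bits(polarized[msa.locus_id])
        if pol.size != msa.column_count:
            raise ValueError(
                f"locus {msa.locus_id}: polarized length {pol.size} != "
                f"column count {msa.column_count}"
            )
        for seq in msa.sequences:
            if seq.taxon == polyploid_taxon:
                continue
            m, c = identity_counts(pol, msa.row_bits(seq.taxon), ambiguity_tolerant)
            matches[seq.taxon] = matches.get(seq.taxon, 0) + m
            comparable[seq.taxon] = comparable.get(seq.taxon, 0) + c

    ranked: list[tuple[str, float]] = []
    for taxon in matches:
        c = comparable[taxon]
        ranked.append((taxon, matches[taxon] / c if c else float("nan")))
    ranked.sort(key=lambda tv: (math.isnan(tv[1]), -(tv[1] if not math.isnan(tv[1]) else 0.0), tv[0]))
    return ranked
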