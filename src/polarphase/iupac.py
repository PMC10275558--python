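"""Allele-set algebra over the IUPAC nucleotide alphabet.

Every residue in a multiple-sequence alignment (MSA) is interpreted as a
set of alleles drawn from {A, C, G, T}.  Ambiguity codes (R, Y, S, W, K,
M, B, D, H, V) denote multi-allele sets, as produced when a diploid (or
tetraploid) genotype is collapsed to a single consensus row.  ``N`` marks
a masked site (failed variant, no coverage, deletion) and carries no
allele information; gaps (``-``) are treated identically to ``N``
because indel masking is applied upstream of this package.

Internally, allele sets are bit masks (A=1, C=2, G=4, T=8; masked=0) so
that column-wise operations over whole alignments vectorise with numpy.
The scalar :class:`AlleleSet` API is the readable, single-site view of
the same algebra.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AlleleSet",
    "AlignedSequence",
    "LocusAlignment",
    "InvalidSymbolError",
    "AlignmentError",
    "UnknownTaxonError",
    "decode_iupac",
    "encode_alleles",
    "consensus_from_sequences",
    "trim_masked_columns",
    "pairwise_identity",
    "identity_counts",
    "seq_to_bits",
    "bits_to_seq",
    "read_locus_fasta",
    "write_locus_fasta",
    "read_taxon_map",
]


class InvalidSymbolError(ValueError):
    """A residue outside the 16-letter IUPAC+gap alphabet."""


class AlignmentError(ValueError):
    """Sequences that should be aligned have incompatible lengths."""


class UnknownTaxonError(KeyError):
    """A taxon identifier not present in the alignment."""


# --- bit-mask encoding -------------------------------------------------

_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}

#: IUPAC letter -> allele bit mask.  N and - are masked (0 bits).
CODE_TO_BITS: dict[str, int] = {
    "A": 1, "C": 2, "G": 4, "T": 8,
    "M": 1 | 2, "R": 1 | 4, "W": 1 | 8, "S": 2 | 4, "Y": 2 | 8, "K": 4 | 8,
    "V": 1 | 2 | 4, "H": 1 | 2 | 8, "D": 1 | 4 | 8, "B": 2 | 4 | 8,
    "N": 0, "-": 0,
}

#: bit mask -> IUPAC letter.  The empty set and the 4-fold degenerate
#: set both map to N (no information about which allele is present).
BITS_TO_CODE = {bits: code for code, bits in CODE_TO_BITS.items() if code != "-"}
BITS_TO_CODE[0] = "N"
BITS_TO_CODE[15] = "N"

ALPHABET = frozenset(CODE_TO_BITS)

_SEQ_LUT = np.full(256, 255, dtype=np.uint8)
for _c, _b in CODE_TO_BITS.items():
    _SEQ_LUT[ord(_c)] = _b
    _SEQ_LUT[ord(_c.lower())] = _b

_BITS_TO_CHAR = np.zeros(16, dtype="S1")
for _b in range(16):
    _BITS_TO_CHAR[_b] = BITS_TO_CODE[_b].encode()

POPCOUNT = np.array([bin(i).count("1") for i in range(16)], dtype=np.uint8)


def seq_to_bits(residues: str) -> np.ndarray:
    """Encode a residue string as a uint8 array of allele bit masks."""
    raw = np.frombuffer(residues.encode("ascii"), dtype=np.uint8)
    bits = _SEQ_LUT[raw]
    if (bits == 255).any():
        bad = residues[int(np.argmax(bits == 255))]
        raise InvalidSymbolError(f"invalid residue symbol {bad!r}")
    return bits


def bits_to_seq(bits: np.ndarray) -> str:
    """Decode an array of allele bit masks back into IUPAC letters."""
    return _BITS_TO_CHAR[bits].tobytes().decode("ascii")


# --- scalar allele-set API ---------------------------------------------


@dataclass(frozen=True)
class AlleleSet:
    """A set of alleles at one site, or a masked (information-free) site.

    Invariants: a non-masked set is non-empty and a subset of
    {A, C, G, T}; a masked set carries no alleles.
    """

    alleles: frozenset[str]
    masked: bool = False

    def __post_init__(self) -> None:
        if self.masked:
            object.__setattr__(self, "alleles", frozenset())
        elif not self.alleles:
            raise ValueError("non-masked AlleleSet must contain alleles")
        elif not self.alleles <= frozenset("ACGT"):
            raise ValueError(f"alleles outside ACGT: {self.alleles}")

    @classmethod
    def of(cls, *alleles: str) -> "AlleleSet":
        return cls(frozenset(alleles))

    @classmethod
    def masked_site(cls) -> "AlleleSet":
        return cls(frozenset(), masked=True)

    @property
    def bits(self) -> int:
        return 0 if self.masked else sum(_BASE_BIT[a] for a in self.alleles)


MASKED = AlleleSet.masked_site()


def decode_iupac(code: str) -> AlleleSet:
    """Decode a single IUPAC letter (or gap) into an :class:`AlleleSet`.

    ``N`` and ``-`` decode to a masked set; any character outside the
    16-letter alphabet raises :class:`InvalidSymbolError`.
    """
    if len(code) != 1:
        raise InvalidSymbolError(f"expected single character, got {code!r}")
    bits = CODE_TO_BITS.get(code.upper())
    if bits is None:
        raise InvalidSymbolError(f"invalid residue symbol {code!r}")
    if bits == 0:
        return MASKED
    return AlleleSet(frozenset(a for a, b in _BASE_BIT.items() if b & bits))


def encode_alleles(alleles: AlleleSet) -> str:
    """Encode an :class:`AlleleSet` as its unique IUPAC letter.

    Masked sets encode as ``N``; the full 4-allele set also encodes as
    ``N`` (4-fold degeneracy is indistinguishable from no information).
    """
    if alleles.masked:
        return "N"
    if not alleles.alleles:
        raise ValueError("empty non-masked allele set")
    return BITS_TO_CODE[alleles.bits]


# --- aligned sequences and per-locus alignments ------------------------

PLOIDIES = ("haploid", "diploid", "tetraploid")


@dataclass(frozen=True)
class AlignedSequence:
    """One taxon's row in a locus alignment."""

    taxon: str
    residues: str
    ploidy: str = "diploid"

    def __post_init__(self) -> None:
        if self.ploidy not in PLOIDIES:
            raise ValueError(f"unknown ploidy {self.ploidy!r}")
        seq_to_bits(self.residues)  # validates the alphabet

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class LocusAlignment:
    """One locus's MSA: equal-length IUPAC rows keyed by taxon."""

    locus_id: str
    sequences: list[AlignedSequence]
    _matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise AlignmentError(
                f"locus {self.locus_id}: unequal sequence lengths {sorted(lengths)}"
            )
        taxa = [s.taxon for s in self.sequences]
        if len(set(taxa)) != len(taxa):
            raise AlignmentError(f"locus {self.locus_id}: duplicate taxon ids")
        self._index = {s.taxon: i for i, s in enumerate(self.sequences)}

    # -- accessors

    @property
    def taxa(self) -> list[str]:
        return [s.taxon for s in self.sequences]

    @property
    def column_count(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._index

    def get(self, taxon: str) -> AlignedSequence:
        try:
            return self.sequences[self._index[taxon]]
        except KeyError:
            raise UnknownTaxonError(taxon) from None

    def row_bits(self, taxon: str) -> np.ndarray:
        return self.matrix[self._index[taxon]] if taxon in self._index else self._missing(taxon)

    def _missing(self, taxon: str) -> np.ndarray:
        raise UnknownTaxonError(taxon)

    @property
    def matrix(self) -> np.ndarray:
        """(n_taxa, n_columns) uint8 bit-mask matrix, built lazily."""
        if self._matrix is None:
            if self.sequences:
                self._matrix = np.vstack([seq_to_bits(s.residues) for s in self.sequences])
            else:
                self._matrix = np.zeros((0, 0), dtype=np.uint8)
        return self._matrix

    # -- derived alignments

    def with_row(self, taxon: str, residues: str) -> "LocusAlignment":
        """Return a copy with one taxon's residues replaced."""
        if taxon not in self._index:
            raise UnknownTaxonError(taxon)
        rows = [
            replace(s, residues=residues) if s.taxon == taxon else s
            for s in self.sequences
        ]
        return LocusAlignment(self.locus_id, rows)

    def drop_taxa(self, taxa: Iterable[str]) -> "LocusAlignment":
        drop = set(taxa)
        rows = [s for s in self.sequences if s.taxon not in drop]
        return LocusAlignment(self.locus_id, rows)

    def subset_columns(self, keep: np.ndarray) -> "LocusAlignment":
        """Return a copy retaining the columns where ``keep`` is True."""
        rows = []
        for s in self.sequences:
            arr = np.frombuffer(s.residues.encode("ascii"), dtype=np.uint8)[keep]
            rows.append(replace(s, residues=arr.tobytes().decode("ascii")))
        return LocusAlignment(self.locus_id, rows)


# --- operations ---------------------------------------------------------


def consensus_from_sequences(*haplotypes: str) -> str:
    """Column-wise IUPAC consensus of two or more equal-length haplotypes.

    Each column is the union of the contributing allele sets; a masked
    residue in any input masks the column (conservative, mirroring the
    masking of low-quality calls upstream).
    """
    if len(haplotypes) < 2:
        raise ValueError("consensus requires at least two sequences")
    arrays = [seq_to_bits(h) for h in haplotypes]
    if len({a.size for a in arrays}) > 1:
        raise AlignmentError("consensus inputs have unequal lengths")
    out = arrays[0].copy()
    masked = arrays[0] == 0
    for a in arrays[1:]:
        out |= a
        masked |= a == 0
    out[masked] = 0
    return bits_to_seq(out)


def trim_masked_columns(msa: LocusAlignment, max_masked: int = 2) -> LocusAlignment:
    """Drop columns whose masked-residue count exceeds ``max_masked``.

    The default of 2 follows the MSA-preparation rule of removing
    columns with more than two masked sites.
    """
    if max_masked < 0:
        raise ValueError("max_masked must be >= 0")
    if not msa.sequences:
        return msa
    counts = (msa.matrix == 0).sum(axis=0)
    return msa.subset_columns(counts <= max_masked)


def identity_counts(
    a: str | np.ndarray,
    b: str | np.ndarray,
    ambiguity_tolerant: bool = True,
) -> tuple[int, int]:
    """(matching columns, comparable columns) between two aligned rows.

    Columns where either residue is masked are not comparable.  With
    ``ambiguity_tolerant`` a column matches when the allele sets
    intersect; otherwise the residues must be identical.
    """
    x = seq_to_bits(a) if isinstance(a, str) else a
    y = seq_to_bits(b) if isinstance(b, str) else b
    if x.size != y.size:
        raise AlignmentError("pairwise identity requires equal lengths")
    comparable = (x > 0) & (y > 0)
    if ambiguity_tolerant:
        match = comparable & ((x & y) > 0)
    else:
        match = comparable & (x == y)
    return int(match.sum()), int(comparable.sum())


def pairwise_identity(
    a: str | np.ndarray,
    b: str | np.ndarray,
    ambiguity_tolerant: bool = True,
) -> float:
    """Fraction of comparable columns that match; NaN if none comparable."""
    matches, comparable = identity_counts(a, b, ambiguity_tolerant)
    if comparable == 0:
        return float("nan")
    return matches / comparable


# --- file interfaces -----------------------------------------------------


def read_taxon_map(path: str | Path) -> dict[str, str]:
    """Read a ``taxon<TAB>ploidy`` map."""
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            taxon, ploidy = row[0].strip(), row[1].strip().lower()
            if ploidy not in PLOIDIES:
                raise ValueError(f"unknown ploidy {ploidy!r} for taxon {taxon!r}")
            out[taxon] = ploidy
    return out


def read_locus_fasta(
    path: str | Path,
    taxon_map: Mapping[str, str] | None = None,
    locus_id: str | None = None,
) -> LocusAlignment:
    """Read one locus's multi-FASTA into a :class:`LocusAlignment`.

    The taxon id is the first whitespace-delimited token of each header;
    ploidy defaults to diploid unless overridden by ``taxon_map``.
    """
    path = Path(path)
    rows = []
    for rec in SeqIO.parse(str(path), "fasta"):
        taxon = rec.id
        ploidy = (taxon_map or {}).get(taxon, "diploid")
        rows.append(AlignedSequence(taxon, str(rec.seq).upper(), ploidy))
    return LocusAlignment(locus_id or path.stem, rows)


def write_locus_fasta(msa: LocusAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s.residues), id=s.taxon, description="")
        for s in msa.sequences
    ]
    SeqIO.write(records, str(path), "fasta")
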