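# Methods

## The problem and the model

An allotetraploid carries two subgenomes inherited from two different
parental species. When high-throughput reads are collapsed into a single
IUPAC-coded consensus row per species, the tetraploid's heterozygous
sites record, to a first approximation, the nucleotide differences
between its two parental lineages. *Genomic polarization* exploits this:
given a reference taxon from the same MSA, every heterozygous site of
the tetraploid is replaced by the alleles *not* present in the
reference. If the reference is (close to) parent *A*, the polarized row
resembles parent *B*, and vice versa. Placing the polarized row on the
phylogeny of the non-focal taxa therefore reveals one parental position
per iteration; alternating the reference drives the search into a
two-cycle (the *bimodal equilibrium*) whose two alternating sister
groups are the positions of the two parents.

Site-wise polarization rules (allele sets under IUPAC coding):

1. masked (`N`/`-`) in the polyploid or the reference → masked;
2. fixed in the polyploid → unchanged;
3. polyploid alleles ⊆ reference alleles → unchanged;
4. otherwise → polyploid ∖ reference.

Rule 3 is the only total extension of the published rule set: plain set
difference would produce an empty allele set whenever the polyploid's
alleles are a strict subset of the reference's. Sets with more than two
alleles polarize by the same set difference. Only the focal tetraploid
row is ever polarized.

## Pipeline

Each iteration runs: polarize every locus → filter loci (<100
parsimony-informative sites, >50% gaps/ambiguities, duplicate rows) →
infer one gene tree per locus → place the polarized row on the fixed
backbone by quartet agreement → pick the next reference (the closest
relative from the placement; a seeded uniform draw within multi-taxon
sister groups, excluding the immediately preceding reference).

**Backbone.** The species tree over the non-focal taxa is estimated
once, by neighbor joining on internode (edge-count) distances averaged
over gene trees — a procedure consistent under the multispecies
coalescent — and reused across iterations; only the placement moves.

**Gene trees.** Distances are Kimura two-parameter over columns where
both rows are unambiguous (pairwise deletion), capped at 5.0
substitutions/site for saturated pairs; trees come from standard
neighbor joining with deterministic lowest-index tie-breaks and negative
branch lengths clamped to zero. The polarized row itself is *not* part
of the NJ agglomeration: it is a deliberate chimera of two subgenomes,
and global distance methods average its conflicting signal, typically
attaching it one node too basally (~3% of no-ILS permutations, where
maximum-likelihood inference attaches it correctly). Instead the focal
row is inserted afterwards on the edge that minimises a Fitch parsimony
insertion score computed from preliminary state sets (IUPAC ambiguity
enters the state sets directly; masked sites are compatible with every
state). This hybrid keeps the package self-contained and restores the
site-level resolution that the published protocol obtains from
maximum-likelihood gene trees. It can be disabled
(`SearchConfig(parsimony_insertion=False)`).

**Bootstrap and contraction.** `bootstrap_and_contract` resamples
columns (default 200 replicates), scores each internal bipartition, and
collapses branches at ≤30% support into polytomies; unresolved quartets
then count toward no placement alternative. The iterative search runs
with `bootstrap_replicates=0` by default: NJ bootstrap supports are not
comparable to the ultrafast-bootstrap supports the threshold was devised
for, quartet-averaged placement already integrates over gene-tree noise,
and the search loop must stay desk-scale. Contraction remains available
through `SearchConfig(bootstrap_replicates=...)`.

**Placement.** For every backbone edge, the score is the number of
gene-tree quartets {polyploid, x, y, z} whose induced topology matches
the topology obtained by attaching the polyploid on that edge. Induced
quartet topologies are computed by the four-point condition on
edge-count distances (ties → unresolved, counted nowhere). Evaluation is
exhaustive up to 10^6 (gene tree × quartet) pairs, then a seeded uniform
subsample of 10^5. Ties across edges resolve toward the smallest sister
group, then lexicographically. Branch support is reported as q1/q2/q3 —
the frequencies of the three topologies among quartets drawing one leaf
from each of the four clades around the branch — averaged per gene tree
and then over trees (pooled counting is available as an option).

**Convergence.** Bimodal convergence is declared after one full
two-cycle (four placements alternating between two fixed sister groups);
the reported convergence iteration is the earliest from which the
alternation held. `detect_convergence` flags a unimodal state after two
identical consecutive placements, but the search treats the first such
repeat as provisional — under incomplete lineage sorting a noisy
placement can repeat by chance — and only classifies the run as
unimodal once the position has persisted over three consecutive
iterations. Unimodal convergence is then always disambiguated: one
extra iteration is run
with the reference chosen to maximise topological distance from the
identified position (seeded tie-break). If the placement moves, the
parents were nested and the new position is the second parent's; if it
stays, the parents are sister species occupying a single surviving
position. Nested pairs can also resolve without the extra step, by
bimodal alternation between the outer and inner positions.

## The synthetic benchmark

The generator reproduces the statistical structure of the protocol's
evaluation rather than any real data set:

* **Species trees.** Pure-birth (Yule) topology over 16 species, node
  heights rescaled so the ingroup root sits at a height (coalescent
  units) set by the ILS level; leaf labels randomly permuted; an
  outgroup attaches at 1.5× the ingroup height. `ancient` speciation
  warps node heights rootward (h → H·(h/H)^0.3), lengthening pendant
  branches; `recent` (default) leaves the coalescent-shaped heights.
* **ILS calibration.** Discordance and divergence are controlled
  independently. The ingroup height is 12 coalescent units for
  `moderate` and 3 for `high`, calibrated once so the mean normalized
  Robinson–Foulds distance between true gene trees and the species tree
  falls in 0.2–0.35 (moderate) and 0.5–0.7 (high) — the regimes of
  standard coalescent supertree benchmarks. Root-to-tip divergence is
  held at 0.08 substitutions/site for every level, enough for ~150–400
  parsimony-informative sites in a 1500 bp locus so the 100-site filter
  keeps nearly all loci.
* **Gene trees.** msprime simulates the multispecies coalescent on a
  per-species-tree demography (one population per branch, splits at the
  node heights, two haploid samples per species); `none` bypasses the
  coalescent entirely and returns the species tree with duplicated
  zero-length tips.
* **Sequences.** HKY (κ=2, base frequencies 0.3/0.2/0.2/0.3) evolved
  site-independently along each gene tree; locus lengths N(1500, 150)
  truncated at 300 bp, or fixed (20,000 bp in the no-ILS set); no
  indels, no rate heterogeneity.
* **Polyploid assembly.** Per species, the two haplotypes collapse to a
  diploid IUPAC consensus row; the tetraploid is the IUPAC merge of one
  haplotype from each parent (a fully homozygous, disomic
  neo-allopolyploid); the parental rows are then removed. Its
  heterozygous-site count therefore equals the Hamming distance between
  the two sampled parental haplotypes.
* **No-ILS, no-polytomy set.** Branch lengths are equalized (all 1 unit,
  0.02 substitutions/site for sequence simulation), one 20 kb locus per
  replicate, and the admissible {parentA, parentB, reference}
  permutations are enumerated: each parent must have a singleton sister
  species, and sister or nested parental pairs are excluded; the
  reference ranges over every remaining taxon including the outgroup.

What the generator does **not** emulate: read mapping and variant
calling (rows are error-free), indels and alignment uncertainty,
post-hybridization exchange between subgenomes (homoeologous
recombination, gene flow), rate variation across sites and loci, and
unsampled parental lineages. Passing benchmarks therefore demonstrate
the protocol's intrinsic behaviour under the coalescent, not robustness
to upstream bioinformatic noise.

## Truth and scoring

Parents are removed from the MSAs, so a parent call is correct when it
names the parent's *position*: the leaf set of the closest enclosing
sibling clade that survives the removal of both parents. Sister parents
share one surviving position; nested parents yield one position
contained in the other's sibling clade. "Both parents correct by
iteration k" means two consecutive placements within the first k
iterations (or a unimodal position plus its disambiguation) match the
two truth positions. Failed replicates are cross-tabulated against the
presence of very short internal branches (<0.25 coalescent units) in the
species tree, the known hard case for quartet-based placement.

## Problem sizes and numerics

The shipped benchmarks run at desk scale: 10 no-ILS replicates with at
most 50 admissible permutations each, and 20 replicates × 200 loci per
ILS scenario. These sizes give binomial standard errors of roughly 5
percentage points on the ILS accuracies, which is the tolerance the
acceptance checks apply. All randomness flows from explicit integer
seeds (numpy `default_rng`; per-locus seeds derived by CRC so results
are independent of caching order); the same configuration and seed
reproduce byte-identical replicates and traces. Degenerate inputs are
handled explicitly: pairs with no comparable columns raise an error
naming the pair (inside bootstrap replicates they fall back to the
distance ceiling), empty filtered locus sets raise a data error rather
than returning a partial result, and identity ranking reports taxa with
no comparable columns as NaN, ranked last.

## Known limitations

* Only one focal tetraploid per run; higher ploidies and polyploid
  parents are out of scope.
* The fixed-backbone design assumes the non-focal taxa alone determine
  the species tree; very short internal branches near the parental
  positions remain the dominant failure mode, as in the published
  evaluation.
* The Fitch insertion score uses preliminary state sets (a standard
  approximation); it is exact for the placement ranking in the regimes
  tested but is not a full parsimony rescoring.
* Unimodal classification requires a position persisting over three
  iterations; a genuinely unimodal run therefore spends one extra
  (usually cached) iteration before disambiguation, and "by iteration
  3" accuracy counts nested pairs resolved via disambiguation one
  iteration later than a purely bimodal run would be.
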