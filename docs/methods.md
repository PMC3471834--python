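# Methods

## Scope and overall design

`pansym` is a pipeline for comparative genomics of clades that mix
free-living and endosymbiotic bacteria. Its stages are deliberately
self-contained: orthology inference uses k-mer similarity and an in-repo
Markov clustering rather than external BLAST/OrthoMCL binaries; the
phylogeny is distance-based (neighbor joining over Poisson-corrected
distances) rather than maximum likelihood; the rearrangement stage
implements the exact Hannenhalli–Pevzner signed reversal distance and a
greedy MGR-style tree search in pure Python. These are methodological
substitutes chosen for reproducibility and testability, adequate for
topology- and count-level conclusions; they are not reimplementations of
any particular external tool's scoring.

## Synthetic clades (`synthdata`)

The generator produces a clade of `n_free_living` strains (FL1..),
`n_endosymbiont` endosymbionts (ES1..; the last is the most reduced,
"obligate-like" lineage) and an optional outgroup, on the fixed topology
`(((ES…)SYM, FL1)SYMFL, (FL2, FL3…)FLC)` with the outgroup basal. No
generative model for such data is established in the field; all simulator
choices below are explicit stand-ins designed to create recoverable signal,
and are documented as such.

**Gene content.** Families come in four kinds: a single-copy core
(`n_single_copy_core`, present exactly once in every strain — the basis for
the phylogeny and the gene orders), further core families (present in all
free-living strains and the outgroup), an accessory set shared by the
free-living strains only, and per-strain specific tails. Endosymbiont `e`
keeps a non-single-copy core family of COG category `c` with probability
`min(1, retention_fraction[e] · m_e[c] / m̄_e)`, where `m_e` are
per-category retention multipliers and `m̄_e` their expectation under the
base COG profile — so the average keep rate equals `retention_fraction[e]`
while the per-category bias creates the retained/reduced deltas the
profile stage is meant to recover. Defaults: fractions (0.75, 0.35) for a
facultative/obligate pair; multipliers for the obligate lineage follow the
empirical ratio pattern of a deeply reduced insect endosymbiont
(information processing J strongly enriched; regulation K, signal
transduction T and motility N strongly depleted), with the facultative
lineage given the square root of each value (a milder version of the same
bias). The base COG profile is a generic gammaproteobacterial composition
over the 20 single-letter categories; 10% of families carry no COG label
(unassigned genes are excluded from profile totals downstream).

**Sequences.** Each family has a random root protein of `protein_length`
residues (default 100). Along each branch, substitutions follow a Poisson
process with the branch's expected substitutions/site; each event replaces
a uniformly chosen site with a uniform choice among the 19 alternative
residues. There are no indels, so family sequences are pre-aligned by
construction. This matches the Poisson-corrected distance used by the
phylogeny stage and keeps closed-form expectations: the probability two
sequences separated by total rate r differ at a site is
(19/20)·(1 − e^(−20r/19)), ≈ r for small r. Default rates: 0.02/branch,
0.03 for the facultative endosymbiont, 0.12 for the obligate one (the
accelerated branch), 0.08 for the outgroup.

**Gene orders.** The single-copy-core order starts as the identity at the
root; each branch applies its configured number of inversions, each
reversing a uniformly chosen contiguous segment (endpoints recorded
1-based inclusive in the truth record). Defaults confine inversions to the
endosymbiotic branches (6 facultative, 5 obligate, 3 on their shared stem;
free-living strains stay perfectly syntenic) and keep the total below a
quarter of the order length, the sparse regime in which the true count is
identifiable from the reversal distance. Shared non-single-copy families
are anchored once to an ancestral slot immediately after one single-copy
gene and ride along with it through inversions (emulating physical
linkage), so their positions stay consistent across strains; strain-private
families are interleaved at random slots. Duplicated copies (probability
`duplication_rate` per free-living strain and non-single-copy family)
are lightly perturbed copies of the strain's own gene; the obligate
endosymbiont is left without redundancy, and single-copy-core families are
never duplicated so gene orders stay well defined.

**Scale.** Defaults (300 core / 150 accessory / ~200 specific families,
60-gene single-copy core, 100-residue proteins) are a deliberately scaled-
down version of a five-genome bacterial clade, chosen so the whole pipeline
runs in seconds while keeping every statistic in its informative regime
(thousands of supermatrix columns, hundreds of families per profile).

All randomness flows from the single config seed through named substreams
(family roster, sequences, orders, tables, retention), so fixtures are
byte-reproducible and stages can be toggled without perturbing one another.

## Orthology (`orthology`)

Similarity between proteins is the Jaccard index of their k-mer sets
(k = 3 by default); a containment coverage — shared k-mers over the k-mer
count of the shorter sequence — acts as a match-length cut-off (default
0.70, configurable; the pipeline's demo configuration uses 0.35 with a
Jaccard threshold of 0.10, chosen from the expected k-mer survival
(1 − p)^k at up to ~25% pairwise divergence, while unrelated proteins score
< 0.02). Edges passing both thresholds enter MCL: per connected component,
self-loops are added at each node's maximum incident weight, columns are
normalized, and expansion (matrix self-composition) alternates with
inflation (entrywise power 1.5, renormalization) until the walk matrix is
stable to 1e-6 (capped iterations produce a warning and the current hard
clustering). Attractor rows define clusters; a node attracted by several
systems joins the one holding the lexicographically smallest member, for
determinism. Genes without qualifying edges are singletons — first-class
members of the pan-genome.

"Duplicated genes" of a strain are, by default, all members of families
with ≥2 members from that strain, as a percentage of the strain's genes;
the alternative convention (copies beyond the first) is available via
`beyond_first=True`. Family/COG consistency is reported as the fraction of
annotated members sharing the modal category; families with no annotated
member are flagged not-assessable rather than counted.

## Pan-genome (`pangenome`)

Every family (and singleton) belongs to exactly one subspace: the subset of
strains among its members. Summary fractions use clustered families plus
singletons as the denominator. Subspace keys are canonical frozen sets;
table output orders subsets by binary mask over the canonical strain order
for stable diffs. `subspace_fraction` counts families whose strain set
contains a required subset (so the full-set case reduces to the core
fraction); `subspace_query` supports include/exclude intersections;
fractions are reported to two decimals.

## Functional profiles (`cogprofiles`)

Profiles count COG-assigned CDSs per unit; relative profiles divide by the
unit's assigned total. Core and pan-genome units are tallied per family
using the modal member label (alphabetical tie-break). Divergence from the
free-living average is reported in percentage points. The six-level
retained/reduced scale uses thresholds at 0, ±2 and ±5 points; since
strictly inequality-based wording leaves the boundary values unassigned,
boundaries are deterministically assigned to the higher-magnitude class and
Δ = 0 counts as moderately reduced — the classification is total and
monotone. Kruskal–Wallis tests use the tie-corrected rank statistic
(scipy), with df = groups − 1; the all-tied degenerate case, where the tie
correction denominator vanishes, is defined as H = 0, p = 1 (no evidence
against the null). Two-way hierarchical clustering defaults to Euclidean
distance with complete linkage (the common default of heatmap tooling),
both configurable; single-category matrices skip column clustering.

## Phylogeny (`phylogeny`)

The single-copy core is the family set with exactly one member in every
strain (outgroup included when required). Concatenation requires equal
sequence lengths within a family — alignment is out of scope because the
simulator emits gap-free alignments; an optional filter drops columns
containing unknown residues (X). Distances are Poisson-corrected,
d = −ln(1 − p); saturation (p = 1) is an error. Trees come from
scikit-bio's neighbor joining (exact on additive matrices; tiny negative
branch lengths from noise are clamped to zero), rooted at the midpoint of
the outgroup's terminal edge when an outgroup is given. Bootstrap support
resamples supermatrix columns with replacement and counts, per original
split, the percentage of replicate NJ trees containing it; splits are
compared as canonical bipartitions (the side not containing the
alphabetically first taxon), making rooted and unrooted trees comparable.

## Rearrangements (`rearrange`)

Gene orders are signed permutations over the single-copy core, encoded by
sorting each strain's core genes by (contig, start); the sign is + when the
strand matches the reference strain's strand for that family, and family
ids are renumbered so the reference is the identity. Circular genomes are
canonically linearized (rotate/reflect so gene 1 is first and positive) and
then treated as linear with end caps — an approximation of circular
reversal distance, adequate for convention-fixed fixtures.

The reversal distance uses the Hannenhalli–Pevzner formula
d = (n+1) − c + h + f on the breakpoint graph: elements map to ordered
vertex pairs, black edges join adjacent positions, gray edges join
consecutive values; c counts alternating cycles. A gray edge is oriented
when its endpoints' positions share parity; components group cycles whose
gray chords interleave; a component is unoriented when nontrivial and free
of oriented edges. Hurdles are unoriented components whose occurrences are
contiguous in the circular scan restricted to unoriented components; a
fortress requires an odd number of hurdles, all of them superhurdles
(each protecting a doubly-occurring non-hurdle neighbour). Correctness is
guaranteed empirically rather than by proof: the test suite checks the
implementation against a breadth-first-search oracle exhaustively for all
signed permutations up to n = 6 and on random n = 7 cases (during
development the agreement was verified over the entire n = 7 space).

Sorting scenarios are found greedily (any reversal lowering the distance by
one; first (i, j) in lexicographic order), guaranteeing optimal length.
The MGR-style tree steinerizes a fixed or NJ-derived unrooted topology:
internal nodes start at their nearest leaf and are repeatedly replaced by a
greedy median of their three neighbours — hill-climbing on the summed
reversal distance, with candidate reversals restricted to segments whose
cut points are breakpoints relative to at least one neighbour, ties broken
by smallest segment, and a configurable move budget (exceeding it sets a
non-convergence flag). Edge lengths are exact pairwise reversal distances,
so the reported total is always an upper-bound-consistent tree length even
when the heuristic stops early. Synteny runs are maximal blocks of
consecutive genes conserved in order and relative orientation, exported
with 1-based coordinates for plotting.

## What the synthetic data does and does not show

Passing tests demonstrate that each stage recovers the generator's ground
truth in its intended regime: family recovery at ≤0.1 substitutions/site
per branch, topology and acceleration recovery at ≥5000 supermatrix
columns, inversion-count recovery in the sparse regime (k ≤ n/4), and
retained/reduced calls for multiplier biases of 4× / 0.25×. Real data
differ in ways the generator does not emulate: indels and alignment
uncertainty, horizontal transfer, unequal gene lengths, pseudogenes,
mobile-element sequences (element activity is represented only by inversion
counts), multi-replicon genomes, and annotation noise in COG labels.
Results on real genomes therefore depend on upstream alignment and
annotation quality in ways these tests cannot certify.

## Numerical choices and degenerate inputs

- Fractions are rounded to 2 decimals at the reporting boundary only.
- MCL convergence: max-norm change < 1e-6, ≤200 iterations; attractor
  threshold 1e-8.
- Zero-divergence bootstrap matrices yield an arbitrary resolved topology;
  supports are still reported in [0, 100] and flag the lack of signal.
- `kruskal_wallis` rejects empty groups; `relative_profile` rejects units
  with zero assigned genes; `poisson_distance` rejects saturated pairs;
  `encode_orders` rejects strains missing (or duplicating) a core gene.
- Bootstrap and simulation randomness derive from explicit integer seeds;
  repeated runs are bit-reproducible.
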