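# Methods

## Scope and model

`mitoarchitect` quantifies the repeat and rearrangement architecture of
small circular genomes. All coordinates are internally 0-based half-open on
the deposited strand; GenBank I/O converts to and from the 1-based inclusive
convention, and features wrapping the origin of a circular genome are held
as one feature with two intervals. Coordinate arithmetic on circular
genomes is modulo the genome length; windows, repeats and gene adjacencies
may cross the origin.

## Small inverted repeats

A candidate hit consists of a left stem arm of length *s*, a loop of *g*
unpaired bases, and a right arm that is the reverse complement of the left
arm up to *m* mismatched base pairs. Defaults follow the EMBOSS-palindrome
parameter conventions: 6 ≤ *s* ≤ 100 (the "maximum length of palindrome"
is read as maximum stem length, matching that program's semantics),
0 ≤ *g* ≤ 10, *m* ≤ 1. N never pairs; a pair involving N counts as a
mismatch, and a classifying window containing N yields the class
`ambiguous`, excluded from type tables.

Only **maximal** hits are reported: a hit such that neither extending both
arms outward by one base nor extending them inward (consuming two loop
bases) stays within the mismatch, loop ≥ 0 and stem ≤ 100 budgets. When an
extension is possible only by spending a mismatch, the longer hit is what
the scanner reports, because the shorter one is by definition not maximal.
Overlapping maximal hits at different centers are all reported; one hit is
emitted per distinct maximal span.

The scan walks antidiagonals of the implicit self-comparison matrix: every
hit with loop midpoint at center *c* is a run of consecutive base pairs
`(c−1−d, c+d)` (even loops) or `(c−1−d, c+1+d)` (odd loops), so for each
center and each admissible innermost depth one cumulative-sum pass yields
the unique maximal outward extension, vectorised across all centers.
Circular genomes are scanned on a tiled copy of the sequence with one
center per circular position; hits whose total span would exceed the
genome length are dropped. Correctness is established against a
brute-force enumerator (every (arm end, loop, stem) triple, maximality
checked literally) that shares no code with the scanner.

Post-detection, hits with stem strictly longer than loop are selected;
each is classified by the six left-arm bases adjacent to the loop, read
5′→3′ on the deposited strand. The left-arm convention is a deliberate
choice: type tables listing both `AAAAAA` and `TTTTTT` as distinct
families only make sense if classification is arm- and strand-specific.
Note that for perfect hits the class is invariant under reverse
complementing the genome (the new left arm is the reverse complement of
the old right arm, which equals the old left arm); only hits whose
mismatch falls inside the classifying window can change class. A family
observed at least 10 times in one genome (after the stem > loop filter) is
a "repeat" type; the threshold is applied after filtering. Region tallies
assign each hit to coding or intergenic when its whole span (arms + loop)
lies in one class, and to the class of its midpoint base otherwise.

Detection runs on the deposited strand only. Scanning both strands would
double-count: every inverted repeat on one strand corresponds to one on
the other.

## Tandem repeats

A simplified seeded detector sharing the classic Tandem Repeats Finder
weights: match +2, mismatch −7, indel −7, minimum alignment score 50,
maximum period 500, consensus acceptance at ≥ 80% identity. Candidate
periods come from exact 8-mer recurrences at distance ≤ 500; candidate
arrays are extended by offset self-similarity with short error-run
tolerance and trimmed to the maximum-scoring contiguous stretch
(local-alignment boundary semantics), then scored by a banded global
alignment of the array against itself shifted by one period — for a
perfect array of length *n*, score = 2·(*n* − *p*). Overlapping reports of
one array are merged to the highest-scoring (then smallest) period.
Reported scores are self-consistent: recomputing the offset alignment for
any report reproduces its score. The probabilistic model of the original
tool (match/indel probability percentiles) is *not* reproduced; this
module shares only the scoring weights, so published per-genome tandem
counts are not expected to be matched cell-for-cell.

## GC profiles, dotplots, p-distances

GC is profiled in 100-bp windows at a 10-bp step, anchored at position 0
of the deposited sequence, wrapping the origin on circular genomes
(⌈L/step⌉ windows); the fraction is (G+C)/(non-N bases) and an all-N
window is emitted as missing. Dotplots use ungapped windows of length 50
scored +5/−4 (the standard DNA full matrix) against a threshold of 100;
only window/threshold are conventionally published, the matrix values are
this package's fixed choice. p-distances operate on given alignments with
pairwise deletion: each pair is compared over columns where neither row
has a gap or missing character (`-.?N`); zero comparable sites yields a
missing distance.

## Gene orders and sections

A gene order is a signed circular sequence of gene units at the annotated
fragment granularity (fragmented genes contribute one unit per fragment).
ORFs of unknown function and introns are excluded by default: they count
as coding for the region partition (they are gene-like features) but are
too volatile to anchor order comparisons.

An adjacency is canonical under signed reversal: `(+a,+b)` and `(−b,−a)`
are the same adjacency. Two units link iff they are adjacent with the same
canonical adjacency in *every* analysed genome containing both; a unit
present in only one genome is a singleton section by fiat. Connected
components of the link relation are sections; each component is validated
to be a simple chain (otherwise it is demoted to singletons with a
warning), ordered by walking its adjacencies, and oriented so that the
first genome containing it reads it forward. A fully conserved circle
collapses to a single section with a declared arbitrary break at the first
unit of the first genome. Labels A, B, C… follow the position of each
section's first member in the first input genome. Merging is invariant to
input order and to rotation of any circular order, and adding a genome can
only split sections (refinement monotonicity) — both properties are
tested.

Breakpoint distance counts canonical adjacencies of one order absent from
the other, restricted to shared units; it is a semimetric that is zero
exactly on cyclic-signed-equivalent orders. Rearrangements are mapped onto
a given Newick tree by all-or-none consensus: an adjacency present in
every tip below an edge and in no other tip is a gain on that edge, and
conversely a loss. This is a descriptive change list, not an ancestral
reconstruction — ancestral gene orders are deliberately not inferred. On
an effectively unrooted 3-taxon tree a pendant-edge event is also visible
from the complementary edge; with ≥ 4 tips and a proper outgroup each
planted event localises to its true edge, which the simulation tests
assert.

## Summary statistics

Cohort tables report per-column means and the **population** standard
deviation (divisor *n*). This convention was verified numerically: the
published dispersion of the 14-genome characteristics table matches
divisor-*n* exactly (e.g. the intergenic-size column gives 4,615.16, where
divisor-(n−1) would give 4,789.37). Printed-style rounding is integers for
sizes/counts and two decimals for percentages. Group comparisons are
one-tailed: Welch's t with Welch–Satterthwaite degrees of freedom
(scipy), and Mann–Whitney U with exact enumeration when the pooled sample
is ≤ 12 without ties, else the tie-corrected normal approximation. Both
groups constant and equal is reported as p = 0.5 (no evidence either
way). The published coding/intergenic split depends on annotation choices
(whether unknown ORFs and tRNAs count as coding) that the source tables do
not fully pin down, so per-accession coding/intergenic totals are treated
as convention-dependent rather than exact targets.

## Synthetic data

The generator emulates the statistical structure of placozoan-like
mitogenomes: a circular genome of configurable length (default 30 kb,
within the observed 20–45 kb range) and GC (default 0.41, the cohort
mean), carrying 12 protein-coding genes, two rRNAs with a fragmented large
subunit, 24 tRNAs, optional unknown ORFs, and group I / II introns
fragmenting cox1 and the large rRNA. Background sequence is i.i.d. per
base at the configured GC — no codon structure, no dinucleotide bias, no
mutational history. Consequently, passing recovery tests demonstrates
detector correctness under the stated parameters, not performance on real
compositional heterogeneity; conversely the detectors make no assumption
the generator would satisfy trivially.

Planted elements are spaced ≥ 150 bp apart (a fixture constraint so that
detected hits cannot interact or merge, not a detector assumption) and
placed inside their intended region class via slot pools with 75-bp
margins, which guarantees the spacing even across the shortest (70 bp
tRNA) genes. Hairpins are built as arm + loop + reverse-complement arm
with non-pairing flanking bases and non-pairing loop ends. A hairpin
carrying exactly the detector's mismatch budget is then maximal by
construction and is recovered at its exact coordinates with its planted
family — the generator plants one mismatch by default for this reason. A
hairpin planted with fewer mismatches leaves extension budget, so the
detector legitimately reports a longer containing hit; such plants are
still recovered (family and position), just not coordinate-exact. Planted
tandem arrays get phase-breaking boundary guards so their spans are exact.

Tree-guided evolution applies inversions and translocations to a segment
list (sequence fragments move and flip together with their annotations),
composing events along each root-to-tip path. Plans must be
non-interacting — every broken adjacency is a root adjacency and no event
recreates one — which the function validates; the expected section
partition is then the root order cut at every broken adjacency. Events
conserve genome length and gene content.

## Numerical and engineering choices

- All randomness flows through seeded generators; analysis stages are
  fully deterministic and reruns produce byte-identical tables (checked).
- Hit ordering: left-arm start ascending, then stem descending, then loop;
  wrapped duplicates are removed by (start mod L, stem, loop).
- The tandem banded alignment uses band max(8, |Δlen|+2); copy number
  below 1.9 is rejected (an array needs ~2 copies).
- Degenerate inputs: empty feature sets partition to all-intergenic; a
  single genome skips the gene-order stage with a notice; fewer than two
  shared units make breakpoint distance an error rather than a guess.
- Problem sizes in the test and acceptance runs (100 oracle sequences up
  to 2 kb, 12 × 45 kb genomes with 540 planted hairpins, a 14-tip
  simulated cohort, 200 random permutations) were chosen as the smallest
  sets that exercise every code path with comfortable statistical margin.

## Known limitations

- The tandem detector is not a reimplementation of the published
  probabilistic tool; counts on real genomes will differ in borderline
  and highly diverged arrays.
- Exact-coordinate hairpin recovery is only guaranteed for plants carrying
  the full mismatch budget (see above); this is a property of maximality,
  not a detector defect.
- Edge mapping reports consensus differences, not parsimony
  reconstructions; polytomies are flagged, not resolved.
- De novo annotation, alignment construction and tree inference are out of
  scope: annotations, alignments and trees are consumed as given.
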