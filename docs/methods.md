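# Methods

This note records the models and procedures implemented in `contextscan`,
the defaults and why they were chosen, and what the synthetic benchmarks do
and do not demonstrate.

## Gene-neighborhood model

A genome is a set of replicons carrying genes with 1-based inclusive
coordinates; the intergenic distance between consecutive genes is
`next.start − prev.end − 1`, which is negative for overlapping genes.
Overlaps are permitted and flagged, never silently removed: nested and
overlapping genes are common in prokaryotic annotations and a neighborhood
walk that dropped them would bias against compact operons.

A neighborhood is the window of `window` genes on each side of an anchor
(default window 2), truncated at replicon ends. Validity filtering trims
outward from the anchor and stops at the first neighbor that (a) lies more
than `max_gap_nt` nucleotides from the previously retained gene (default 50,
*inclusive* — a gap of exactly 50 passes, and negative gaps always pass), or
(b) is on the opposite strand from the anchor when co-directionality is
required. Trimming rather than whole-neighborhood rejection is the default
because a valid operon core should not be discarded for a distant stray
neighbor; `reject_on_fail` provides the stricter alternative. The strand
comparison is against the anchor, not a window majority, for operon
semantics and determinism.

Conservation is assessed by pooling the proteins of all candidate
neighborhoods, clustering them into families, and linking two neighborhoods
when their anchors share a family *and* they share at least one additional
flanking family; groups are the transitive closure of that relation. Flank
order (synteny) is deliberately not required — real conserved neighborhoods
show flank rearrangement. A group is reported only when its member taxa
span at least `min_phyla` phyla (default 2): presence in a single phylum is
compatible with vertical inheritance of one ancestral locus and carries no
contextual signal. Paralogous neighborhoods from one taxon may share a
group; the phylum count is over distinct phyla.

## Sequence clustering

The linkage criterion mirrors the classic length-coverage/score-density
contract: two sequences are linked iff

* coverage = aligned residue pairs / length of the longer sequence ≥ L, and
* score density = alignment score / (2 × alignment columns) ≥ S,

with the score from a global BLOSUM62 alignment with affine gaps (open 11,
extend 1). BLOSUM62 entries are half-bit log-odds, so dividing by two
expresses the density in bits per aligned column. Clusters are connected
components (single linkage), so the result is order-independent and
monotone: lowering L or S can only merge, never split. The original tool's
internal normalization is not published; the definition above is this
package's own, and the numeric thresholds are calibrated for it. Presets:

* near-identical (L = 0.9, S = 1.89): links sequences down to roughly 75%
  identity (a self-alignment averages ≈ 2.8 bits/column);
* family detection (L = 0.6, S = 0.8): links homologs to roughly 50%
  identity while unrelated sequences stay below 0 bits/column.

Global (not local) alignment is the v1 default because the synthetic
benchmark contains no domain shuffling; a `local` flag exists. Note that
the *optimal-alignment* identity between unrelated random sequences is
≈ 22%, well above the 5% per-position background — the score density, not
identity, is the discriminative quantity.

## Positional bias

Counts are taken over unique architectures (exact label-sequence equality)
with ≥ 2 domains; a lone domain is trivially both terminal and single-domain
architectures are excluded. Each occurrence is classified N-terminal /
internal / C-terminal. The null is *slot availability*: an occurrence in an
architecture of length k is uniform over its k slots, contributing
(1/k, (k−2)/k, 1/k) to the expectation. This respects the length
composition of the architectures containing the domain; the naive
uniform-thirds null (which overstates internal expectation for short
architectures) is available via a flag. The Pearson χ² statistic is
referred to χ²(2). Under the heterogeneous-slot null the statistic is
slightly conservative (measured type-I ≈ 0.03–0.05 at α = 0.05), because
summing multinomials with unequal probabilities has variance below the
pooled-multinomial value; the test errs toward fewer false positives.
When a domain occurs twice in one architecture both occurrences are
counted; counting architectures instead would discard tandem-repeat signal.

## Entropy and the diversification contrast

Column entropy is H = −Σᵢ Pᵢ log₂ Pᵢ with Pᵢ the fraction of non-gap
residues of type i (0·log 0 ≡ 0); gaps are excluded from the denominator
and columns with > 50% gaps are dropped (both knobs exposed). The contrast
between two families is a two-sided Welch t-test on per-column entropies:
no variance-equality assumption is defensible between a conserved and a
diversifying family. Columns are treated as independent observations — a
known simplification shared by the test's usual application; no
phylogenetic correction is attempted. When both profiles are constant the
Welch statistic degenerates and the implementation returns t = 0, p = 1 for
equal means (and ±∞, 0 otherwise).

## Hypergeometric enrichment

The test asks whether the q trait-positive organisms among k system
carriers exceed chance given m trait-positive and n trait-negative
organisms overall: p = P(X ≥ q), X ~ Hypergeometric(m, n, k), the
`phyper(q−1, lower.tail=FALSE)` convention. Including the observed value is
the conservative standard for enrichment; only over-representation is
tested. Organisms with unknown trait (tri-state NA) are excluded from all
four counts consistently, and an audit record reports how many were
dropped. The tail is summed in log space (log-gamma binomial coefficients
accumulated with `logaddexp` from the deep end), giving relative error
≈ 1e-13 against exact integer summation over the entire m + n ≤ 60 grid and
remaining stable for backgrounds of 10,000 organisms.

## Polydomain score

f(p) = log₂(column total / grand total) over families with nonzero totals;
f̄ is the *unweighted* mean of f(p) over families; PD(o) = Σₚ c(o,p)·(f(p)
− f̄). All-zero family columns are dropped before computing f̄ — their
frequency is undefined (log 0) and their removal provably leaves every
score unchanged. With f and f̄ held fixed, PD is linear in an organism's
counts (exposed via a separate entry point that accepts precomputed
frequencies). The module is agnostic to how families were defined (sequence
clusters, domain assignments, or curated sets).

## Z-score trees

The Z→distance transform is not canonical; the default is d = Z_max − z
with Z_max the largest off-diagonal Z, which is linear, monotone and puts
the most similar pair at distance 0. The reciprocal transform d = 1/z is
available because the two can produce different topologies, as can optional
self-Z normalization (z/√(zᵢᵢzⱼⱼ)) — both modes are exposed rather than
guessed between. UPGMA uses leaf-count-weighted (i.e. true arithmetic-mean)
cluster distances, merge heights d/2, and lexicographic tie-breaking on the
smallest member labels, making trees deterministic across platforms and
input orders. Trees are ultrametric by construction (verified to 1e-9) and
serialize to Newick.

## Synthetic data: what it emulates, what it does not

The generator produces, from a single seed that fully determines every
byte of output:

* taxa over four phyla with a tri-state multicellularity flag (30% positive,
  10% unknown by default);
* one replicon per taxon with 40–60 genes, operon-like strand runs
  (geometric, mean run 3) and intergenic gaps ~ N(120, 80) truncated at
  −30 nt so that slight overlaps occur;
* background proteins of 150–400 random residues, each its own singleton
  family — so any false-positive conserved group is attributable;
* one planted cassette of 3 co-directional genes with internal gaps ≤ 40 nt
  (inside the 50-nt filter), inserted into 6 carriers spanning 3 phyla;
  member proteins are i.i.d. per-site mutants (uniform over the 19
  alternatives, no indels) of family ancestors at divergence 0.1;
* decoy anchor genes — unrelated proteins carrying the anchor domain —
  placed anywhere except inside a cassette block, so recovery precision is
  non-trivially tested;
* a domain planted N-terminal with probability 0.9 in 40 background
  architectures of length 2–4;
* alignments with per-column classes (conserved: one residue; diversified:
  uniform over k residues), count tables with Poisson(1) background and
  planted expansions, block-structured Z matrices and log-uniform hit
  tables.

These defaults are the benchmark's study conditions and are not tuned per
test. What passing the benchmark shows: the filters, grouping logic and
statistics behave correctly when their assumptions hold, with exact
bookkeeping of planted truth. What it does not show: robustness to indels
and domain shuffling (no indels are simulated; clustering uses global
alignment), to annotation errors, to horizontal transfer mimicking
conservation, to phylogenetic non-independence of alignment columns, or to
realistic amino-acid composition (sequences are uniform over 20 letters;
real-database score statistics will differ). Problem sizes in the test and
acceptance runs (12 taxa, ~50 genes each, 20 replicate seeds, 2000-draw
calibration loops, the full m + n ≤ 60 hypergeometric grid, 1000 UPGMA
oracle trials) were chosen to exercise every code path with comfortable
statistical resolution at interactive runtimes.

## Numerical and degenerate-input choices

* Gap threshold comparisons are inclusive (≤) at both the 50-nt distance
  filter and the 50% column-gap filter.
* `pair_score` canonicalizes the sequence pair by string order before
  aligning, so symmetry is exact rather than approximate.
* Entirely gapped alignment columns are undefined for entropy and must be
  excluded upstream (the profile builder does so); an alignment whose every
  column fails the gap filter is an error, not an empty profile.
* Hypergeometric inputs with q at or below the support minimum return
  exactly 1.0.
* An all-zero count table, a zero-length sequence, a χ² category with zero
  expectation but nonzero observation, and a non-symmetric Z matrix are
  errors, not warnings.
* All pipeline randomness flows from one seed; outputs carry no timestamps,
  and JSON is written with sorted keys, so reruns are byte-identical.

## Known limitations

Anchors are selected by domain label or user list — the profile searches
that define anchors in a real study are upstream of this package, which
consumes their tabular outputs. Clustering is O(n²) pairwise alignment and
is meant for neighborhood-scale protein sets, not full databases. The
enrichment module reports raw p-values (no multiple-testing correction
across systems in v1). Maximum-likelihood phylogenetics, alignment
construction and structure searching are out of scope.
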