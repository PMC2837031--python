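# Methods

## Model

Aligned sRNA reads are vertices of a simple undirected graph; an edge joins
two reads on the same chromosome when the number of nucleotides strictly
between their intervals is smaller than the minimum inclusion distance *M*.
Coordinates are GFF-style, 1-based and inclusive at both ends, so for reads
ordered with `start_a <= start_b` the gap is `start_b - end_a - 1`: negative
when the intervals overlap, zero when they abut. The edge rule is a strict
inequality, `gap < M`. Two consequences worth spelling out: abutting reads
connect for any *M* ≥ 1, and at *M* = 0 only strictly overlapping reads
connect. Once an edge exists the distance is discarded — the graph is
unweighted, strand-blind, and has no self-loops. Reads aligning to several
genomic positions appear as several vertices; identical duplicate records
also stay distinct, forming cliques, which is precisely what raises the
clustering coefficient of heavily stacked regions.

For each connected component the clustering coefficient γ is the arithmetic
mean of per-vertex Watts–Strogatz coefficients: with *k* the vertex degree
and *t* the number of edges among its neighbours, the vertex value is
`t / (k(k-1)/2)` for *k* ≥ 2. A component with more than one member read and
γ strictly greater than the cutoff *C* is a locale, spanning the lowest
member start to the highest member end. Components are never merged: two
components closer than *M* cannot exist by component maximality, and near
extents from distinct components stay distinct locales.

## Conventions and numerical choices

- **Degree ≤ 1 vertices.** Their clustering ratio is 0/0. By default they
  contribute 0 to the component mean — the common graph-library convention —
  so a two-read component has γ = 0 and is never called at any *C* > 0. An
  alternative `exclude` convention drops them from the average; both are
  exposed because either reading of "average over the component" is
  defensible, and the choice only matters for components dominated by
  pendant vertices.
- **Strict comparisons.** γ > *C* (a component with γ exactly *C* is
  dropped) and gap < *M*. γ is compared at full float precision and rounded
  to six decimals only in GFF output.
- **Determinism.** Vertex indices follow input file order; components and
  locales are emitted sorted (chromosome, start, end); repeated runs on the
  same input are byte-identical.
- **Graph construction.** A sort-and-sweep per chromosome: reads sorted by
  start; a read stays an edge candidate only while its end is within *M* of
  the current start. This yields exactly the brute-force all-pairs edge set
  (asserted against an independent oracle in the tests) at
  O(n log n + edges) cost.

## Evaluation harness

Scoring is at nucleotide resolution over the whole genome given in a
chromosome-lengths table: TP = nucleotide covered by both a reference locus
and a called locale, FP = locale only, FN = reference only, TN = neither.
Coverage is a set, not a multiset, so TP + TN + FP + FN equals the genome
length exactly — an integer identity the tests assert. Sensitivity is
100·TP/(TP+FN) and specificity 100·TN/(TN+FP); empty denominators raise
`UndefinedMetricError` rather than returning 0, so degenerate inputs fail
loudly. The implementation merges interval unions and sweeps them in sorted
order; it is checked against literal per-nucleotide enumeration.

The positive-control filter removes rRNA/tRNA families and keeps a locus
only when at least `min_hits` (default 5) reads overlap it by ≥ 1 nt —
"overlap" throughout the package means at least one shared nucleotide on the
same chromosome, strand-blind. The filter depends on the read set but not on
(M, C), so it is applied once per dataset, outside the parameter scan.

The parameter scan defaults to the standard grids
M ∈ {5, 10, 20, 30, 50, 75, 100} and C ∈ {0.1, 0.25, 0.4, 0.5, 0.6, 0.75,
0.9} and returns a tidy table (one row per cell: M, C, locale count,
sensitivity, specificity). Reproducibility is measured two ways: the
pairwise proportion of locales in one set overlapping any locale of another
(asymmetric by design — which set is the reference matters when sizes
differ), and counts of exactly coordinate-identical locales across three
sets, per Venn region. Feature-overlap tallies count, per feature type, the
locales hitting ≥ 1 feature and the distinct features hit; nested features
all count.

By default the TN denominator is the whole genome. An optional mask — a set
of chrom/start/end intervals, e.g. the alignable fraction of the genome —
restricts the scoring universe: nucleotides outside the mask are ignored and
the four counts sum to the mask length instead. On real data a whole-genome
denominator inflates specificity (most of the genome is trivially negative);
the mask exists for users who want the stricter universe, but it is off by
default because the whole-genome form is the stated definition.

## Synthetic fixtures

The generator emulates only what the caller consumes: read *coordinates* on
a genome of stated chromosome lengths. Two planted arrangements bracket the
real pile-up spectrum:

- `brick_wall` — reads jittered within a window narrower than the shortest
  read, so every pair overlaps; the component is a clique, γ = 1 exactly.
- `fallen_domino` — reads of one length L per chain, stepped by L − 3, so
  each read overlaps only its chain neighbours (3 nt with the next) and
  next-but-one reads sit L − 6 nt apart; the component is a path (γ = 0)
  for any M ≤ L − 6, i.e. at least up to M = 15 with the default 21–25 nt
  lengths. At larger M the chain acquires chords and γ rises — the same
  M-driven behaviour the method shows on real data.

Defaults: 10 planted locales of 5–12 reads, lengths uniform in 21–25 nt
(typical Dicer products), 200 isolated background reads, and a minimum
separation of 200 nt between items, which must exceed the largest M used
downstream so that planted structures stay in distinct components. Items are
laid left-to-right across chromosomes in a seed-shuffled order with random
slack; a single integer seed drives all randomness and fixture files are
byte-identical across runs.

What the fixtures do **not** emulate: sequence content, expression-level
abundance distributions, multi-mapping ambiguity, degradation-product
smears, or chromosome-scale coverage heterogeneity. Passing tests therefore
demonstrate the correctness of the graph machinery, the calling rule and the
scoring arithmetic — not the biological sensitivity achievable on any real
library, which depends on alignment quality and the completeness of the
positive-control set.

## Problem sizes

The oracle-equivalence suite checks 200 random read sets (most 5–180 reads,
periodic ones at 500) against brute-force all-pairs edges at every
M ∈ {0, …, 120}, union-find components and triple-counted clustering.
Conservation checks run on random genomes up to ~10⁵ nt where literal
per-nucleotide enumeration is cheap. The full 7×7 parameter-scan check uses
a two-chromosome 350 kb genome with 30 planted locales and 300 background
reads. These sizes keep the whole suite under half a minute while exercising
every code path at scales where the independent oracles remain exact.

## Known limitations

- The gap is measured end-to-start (intervening nucleotides). Midpoint- or
  start-based distances would shift edge formation by roughly a read length;
  the oracle in the tests is parameterised on the same formula, so swapping
  the definition is a one-line change in each place.
- Locale extents from different components can in principle interleave on
  the genome (when their reads never come within M); the caller does not
  attempt to resolve or merge such cases.
- No statistical significance is attached to a locale; γ is a descriptive
  geometry score, and thresholding it is the user's modelling decision.
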