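# Methods

## Niche breadth

For taxon *j* in habitat *H* with samples *i = 1..N*, the package computes
Levins' niche breadth

    B_j = 1 / Σ_i P_ij²,   P_ij = n_ij / Σ_i n_ij,

the inverse Simpson concentration of the taxon's read distribution across
the habitat's samples. `P_ij` is normalized per taxon *within* a habitat
(Σ_i P_ij = 1), so `B_j ∈ [1, N]`: 1 when all reads sit in one sample
(specialist), `N` when reads are perfectly even (generalist). An alternative
reading — one global breadth per taxon across all samples of all habitats —
is possible, but normalization "within each habitat" only makes sense for
per-habitat breadths, and per-habitat breadths are what the cross-habitat
criteria below compare; the within-habitat form is therefore used. Breadths
are normalized by the maximum breadth among taxa present in the habitat, so
habitats with different sample numbers are comparable; the maximum maps to
exactly 1.

Breadth is computed on rarefied counts. Rarefaction is a single seeded
multivariate-hypergeometric draw per sample (subsampling without
replacement), by default to the minimum sequencing depth within each
habitat; a fixed global depth is also supported, in which case shallower
samples are dropped with a logged warning (their handling is otherwise
unspecified in common practice). Repeated-draw averaging is deliberately not
implemented: a single reproducible draw keeps every downstream statistic
deterministic under the run seed.

Absence is distinct from minimal breadth: a taxon with zero reads in a
habitat has *no* breadth there, and appears in no per-habitat profile row.
Presence means ≥ `presence_threshold` reads (default 1) in at least one
sample.

Shannon diversity uses the natural log by default (base configurable); the
choice only rescales values and affects no comparison.

## Nonnative classification

A (taxon *j*, habitat *H*) pair is called putative nonnative only when all
three hold:

1. mean relative abundance of *j* in *H* is lower than in some other habitat
   where *j* is present;
2. normalized breadth of *j* in *H* is lower than in some other habitat
   where *j* is present;
3. normalized breadth of *j* in *H* is below the q-quantile (default median)
   of normalized breadths over taxa present in *H*.

Design choices, each genuinely open:

* "Lower than in other habitats" is operationalized as *strictly lower than
  the taxon's maximum over its other habitats* — equivalently, *H* is not
  the taxon's best habitat. Under source–sink logic a taxon should be
  flaggable in every sink, not only in its single worst habitat; requiring
  "lower than all other habitats" would permit at most one nonnative habitat
  per taxon.
* Criterion 3's reference ("other species in the habitat") is a quantile of
  the within-habitat normalized-breadth distribution, exposed as
  `nonnative_quantile`. The median is the default; raising the quantile
  weakly enlarges the flagged set (tested as a monotonicity property).
  Including the focal taxon in the quantile is immaterial at realistic
  richness and keeps the computation vectorizable.
* Normalized (not raw) breadth is used for the cross-habitat comparison,
  because habitats differ in sample number and raw breadths are bounded by
  it.
* Ties fail the strict "lower than" tests (conservative).
* Taxa present in a single habitat are exempt — the cross-habitat criteria
  have no reference — and evaluation against simulator truth likewise
  restricts to pairs whose taxon is detectable in ≥ 2 habitats.

A provable consequence, asserted in tests: a taxon is never nonnative in its
maximum-abundance habitat.

## Removal simulations

Targeted removal deletes every taxon flagged in habitat *H* from all of
*H*'s samples; random removal deletes an equally sized uniform subset
(without replacement) of *H*'s detected-taxon pool, replicated (default
100×) under the run seed. The habitat pool — not the global taxon pool — is
the natural reference for "an equivalent number of taxa", since flagging is
per habitat; the global-pool variant would change the expected richness drop
because habitats share taxa unevenly. Removal never re-rarefies: richness is
count-based and re-normalization would contaminate the comparison with
resampling noise. Closed form used as an oracle: removing a random k-subset
of a pool of size S removes each present taxon with probability k/S, so the
expected per-sample richness drop is r·k/S.

Per habitat, richness is normalized by the maximum observed richness among
its samples, and paired t-tests compare observed vs targeted, observed vs
random (replicate mean) and targeted vs random, with Benjamini–Hochberg
adjustment across the full habitat × comparison family. Degenerate
comparisons (identical vectors, e.g. zero flagged taxa) are reported as
no-difference (t = 0, p = 1); habitats with < 3 samples are skipped with a
warning.

## Functional metrics

Functional richness of a sample is the number of distinct function
identifiers (KO/COG-style) carried by ≥ 1 member with positive abundance;
annotations are presence/absence per genome, not copy number. Members
without annotations are skipped and counted.

Functional redundancy of function *f* is a Rao-type quadratic entropy
restricted to carriers:

    FR(f) = Σ_{i≠j, i,j carry f} p_i p_j d_ij,

where `p` are relative abundances over the *whole* community (so losing
carriers lowers FR rather than renormalizing it away) and `d` is patristic
distance normalized by the tree's maximum pairwise distance, giving
`0 ≤ FR ≤ 1`. FR is 0 with ≤ 1 carrier. This is the standard
"phylogenetic distribution of function carriers" construction and satisfies
the monotone interpretation (more, abundant, distant carriers ⇒ higher
redundancy); redundancy indices in the literature vary in detail, and no
equivalence with any particular published variant is claimed. Redundancy of
a named set (C/N/P/S) is the arithmetic mean of FR over the set's functions,
counting carrier-less functions as 0 so that losing a function's last
carriers is visible in the set average.

## Microdiversity

OTUs are formed by an abundance-sorted greedy centroid pass: sequences in
decreasing total-abundance order (ties by id, never file order) join the
first centroid with global-alignment identity ≥ 0.97, else found a new
centroid. Identity is matches / alignment columns under match 1, mismatch 0,
linear gap −1. An exact banded edit-distance prefilter rejects pairs that
provably cannot reach the threshold (identity ≥ t forces ≤ (1−t)(|a|+|b|)
non-match columns), and an ungapped-identity fast path accepts equal-length
pairs already at threshold; neither shortcut changes any assignment, only
the cost.

Nearest-taxon closeness is `−log d_min` (natural log by default) of a
taxon's minimum distance to any other taxon, from patristic distances when a
tree is available, else 1 − identity. Zero distances are floored at half the
smallest positive distance in the dataset before the log. Closeness is
computed across the full dataset, not within habitats. The occurrence level
of an OTU is the maximum habitat-occurrence count over its members.

Both metrics are compared across occurrence levels with Welch two-sample
t-tests (BH-adjusted), a compact letter display (insert-and-absorb), and a
Spearman rank correlation; levels with < 2 observations stay in summaries
but leave the tests.

## The synthetic generator

`simulate_metacommunity` emulates a landscape of habitats sampled by
amplicon sequencing. Each habitat has exclusive natives (default 250,
per-sample occupancy 0.6) plus shared regional generalists (50, occupancy
0.9); taxon weights are log-normal(0, σ=2), the standard right-skewed
rank-abundance shape. Each native of habitat A colonizes every other habitat
independently with probability m = 0.15; colonists appear in sink samples
with occupancy 0.15 at weight × δ = 0.05 — colonization is habitat-level
first, per-sample second, mirroring the (taxon × habitat) classification
unit. Per-sample counts are one multinomial draw of 10 000 reads over the
present taxa, so column sums equal the depth exactly and low-weight
colonists naturally fall below detection in some samples. Generalists are
"native everywhere" and never carry nonnative labels. The defaults are
chosen as a realistic, clearly signalled source–sink regime (sink abundance
~5% of source, sink occupancy a quarter of native occupancy); no field
estimates of m or δ exist to calibrate against.

`simulate_sequences` gives each lineage a random ancestor (250 nt) and
1 + Poisson(0.8 × occurrence) variants at ≤ 2% divergence — so all variants
of a lineage fall inside one 97% OTU by construction, and variant number
rises with habitat occurrence. The emitted tree has long lineage stems (0.5
substitutions/site) and leaf branches proportional to mutation counts; the
lineage's own taxon id is its first variant, so the tree doubles as the
taxon phylogeny for functional redundancy.

`simulate_function_table` draws ~Poisson(80) background functions per taxon
from a 2000-function universe and defines four disjoint 25-function cycle
sets (C, N, P, S); a configurable fraction (`cycle_exclusive_fraction`,
default 0.5) of each set is carried exclusively by colonist taxa, so
targeted removal demonstrably erodes functional richness and redundancy.

What the generator does **not** emulate: sequencing error and chimeras,
relic DNA, compositional correlations between taxa, temporal dynamics,
within-habitat spatial structure, and realistic phylogenetic signal in
function content. Tests passing on this generator therefore demonstrate
correctness of the statistics and recoverability of a planted source–sink
signal under multinomial sampling noise — not that any particular real
system exhibits that signal.

## Problem sizes and numerics

Default test and acceptance runs use the full default simulation
(4 × 30 samples, ~1050 taxa, depth 10 000) for classification, and smaller
configurations for the alignment- and tree-heavy stages (removal direction:
4 × 12 samples, 80 natives/habitat, depth 3000; microdiversity: ~170
lineages, ~400 variants), sizes at which every property of interest is
strongly powered. The removal-direction scenario raises colonist occupancy
above the pool average (occupancy 0.9 vs native 0.4, δ = 0.3) because the
targeted-worse-than-random direction is a property of flagged-taxon
occupancy, not of classification: the defaults' rare colonists would produce
the opposite direction. Floating-point tolerances: breadth and FR oracles
agree to 1e-12; TSV output uses a fixed `%.10g` format so identical runs are
byte-identical.

## Known limitations

* The three-criterion rule has no abundance floor: a resident detected once
  in a deeply sampled habitat can be flagged if it is broader elsewhere
  (observed as the simulator's few false positives — natives whose own-
  habitat occupancy draw was unluckily sparse).
* Greedy clustering is order-dependent by design (abundance rank), matching
  common practice; it is not a globally optimal partition.
* FR compares only carriers present in the tree; taxa missing from the tree
  are an error, not silently dropped.
* The CLI's microdiversity subcommand takes ASV→lineage occurrence from the
  simulator's truth file; for real data, occurrence counts would come from
  `habitat_occurrence_counts` on the count table, via the Python API.
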