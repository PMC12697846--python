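# habniche

Niche breadth, putative nonnative taxa and microdiversity analysis for
multi-habitat microbiome count data.

## The problem

Microbial communities in connected landscapes — water, sediment, soil, plant
surfaces, animal guts — continually exchange members by dispersal. Taxa
carried into a habitat they are not adapted to (colonists sustained by
source–sink dynamics) are typically rare and patchily distributed there, yet
they can contribute disproportionately to community richness and to the
redundancy of biogeochemical functions. `habniche` provides a tested,
reusable implementation of the statistics needed to find and quantify such
taxa from taxon-by-sample count tables with habitat labels:

* **Levins' niche breadth** per taxon within each habitat,
  `B_j = 1 / Σ_i P_ij²`, where `P_ij` is the proportion of taxon *j*'s reads
  found in sample *i* of the habitat. `B_j` ranges from 1 (specialist,
  single-sample occupancy) to `N` (generalist, perfectly even across the
  habitat's `N` samples); breadths are normalized by the maximum breadth in
  each habitat.
* **Putative nonnative classification**: a taxon is flagged in habitat *H*
  only when (1) its mean relative abundance in *H* is lower than in another
  habitat where it occurs, (2) its normalized breadth in *H* is lower than in
  another habitat, and (3) its normalized breadth is below the within-habitat
  median (configurable quantile) of co-occurring taxa.
* **Targeted-vs-random removal simulations** that compare observed per-sample
  richness against communities stripped of flagged taxa, or of equally many
  random taxa (paired t-tests, Benjamini–Hochberg FDR per habitat).
* **Functional richness and redundancy**: richness as the union of KO/COG
  annotations over present members; redundancy of a function *f* as the
  Rao-type quadratic entropy `FR(f) = Σ_{i≠j carriers of f} p_i p_j d_ij`
  with normalized patristic distances, averaged over named C/N/P/S function
  sets.
* **Microdiversity**: greedy abundance-sorted OTU clustering of ASVs at 97%
  identity, intra-OTU ASV counts, nearest-taxon closeness
  (`−log` nearest phylogenetic distance), and their association with the
  number of habitats a lineage occupies.

A synthetic metacommunity generator (`habniche.simulate`) plants all of these
signals with ground-truth labels, so the entire pipeline is testable without
any external data.

## Worked example

```bash
python examples/01_simulate_and_classify.py
```

simulates the default study conditions (4 habitats × 30 samples, 250 natives
per habitat, 50 shared generalists, dispersal rate 0.15, colonist abundance
discount 0.05, 10 000 reads/sample) and prints:

```
simulated 1050 taxa x 120 samples in 4 habitats; 445 planted colonist (taxon, habitat) pairs
flagged 328 pairs as putative nonnative
precision 0.948, recall 1.000 over 782 evaluable pairs
habitat  n_taxa  n_flagged  flagged_fraction
     H1     383         88          0.229765
     ...
nonnative taxa hold 0.51% of reads but 4.95% of per-sample richness
```

The classifier recovers nearly every detectable planted colonist while
flagging few residents, and the flagged taxa — about a fifth of each
habitat's taxon pool — carry well under 1% of reads but several percent of
per-sample richness, the signature of rare dispersal-derived diversity.
`examples/02`–`04` walk through the removal comparisons, functional metrics
and microdiversity analysis the same way.

The same computations are available from a thin CLI
(`habniche simulate|breadth|classify|removal|funcmetrics|microdiv`, each with
`--config`, `--seed`, `--out-dir`); identical config and seed give
byte-identical outputs.

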