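"""Synthetic multi-habitat metacommunities with planted source-sink structure.

The generator emulates a landscape of connected habitats (e.g. water,
sediment, soil, plant surface, animal gut) sampled by amplicon sequencing:

* each habitat has an exclusive set of **native** taxa plus a pool of
  **regional generalists** shared by all habitats;
* taxon weights follow a log-normal rank-abundance shape;
* each native of habitat A independently becomes a **colonist** of every
  other habitat B with probability ``dispersal_rate``; colonists occur in
  fewer samples (``colonist_occupancy``) at a weight discounted by
  ``colonist_abundance_factor`` — the source-sink signature that the
  nonnative classifier is meant to recover;
* per-sample counts are a single multinomial draw of ``depth`` reads over the
  taxa present in that sample, mimicking fixed sequencing depth.

Companion generators emit sequence variants of each lineage (microdiversity
rising with the lineage's habitat-occurrence count), a phylogeny over all
variants, and taxon-function repertoires with named biogeochemical (C/N/P/S)
function sets, so the full downstream pipeline can be exercised against
ground truth.  All randomness flows from ``SimulationConfig.seed`` through a
single integer-seeded generator; identical configs give identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from habniche.io import CountTable

BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    n_habitats: int = 4
    samples_per_habitat: int = 30
    natives_per_habitat: int = 250
    regional_generalists: int = 50
    native_occupancy: float = 0.6
    generalist_occupancy: float = 0.9
    dispersal_rate: float = 0.15          # m: P(native of A colonizes B)
    colonist_occupancy: float = 0.15
    colonist_abundance_factor: float = 0.05   # delta: sink weight discount
    lognormal_sigma: float = 2.0
    depth: int = 10_000
    function_universe: int = 2000
    functions_per_taxon_mean: float = 80.0
    cycle_set_size: int = 25
    cycle_exclusive_fraction: float = 0.5
    variant_rate_per_occurrence: float = 0.8
    seq_length: int = 250
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "native_occupancy": self.native_occupancy,
            "generalist_occupancy": self.generalist_occupancy,
            "dispersal_rate": self.dispersal_rate,
            "colonist_occupancy": self.colonist_occupancy,
            "colonist_abundance_factor": self.colonist_abundance_factor,
            "cycle_exclusive_fraction": self.cycle_exclusive_fraction,
        }
        for name, v in fracs.items():
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1]")
        if self.n_habitats < 2:
            raise ValueError("need at least two habitats")
        for name in ("samples_per_habitat", "natives_per_habitat", "depth",
                     "function_universe", "seq_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if 4 * self.cycle_set_size > self.function_universe:
            raise ValueError("cycle sets exceed the function universe")


@dataclass
class GroundTruth:
    """Planted labels emitted by the simulator.

    ``nonnative_pairs`` lists every (taxon, habitat) where the taxon is a
    dispersal-derived colonist; ``source_habitat`` maps natives to their home
    habitat (generalists map to None: they are native everywhere and never
    labelled nonnative); ``occurrence_count`` counts habitats colonized or
    inhabited per lineage.
    """

    nonnative_pairs: set = field(default_factory=set)
    source_habitat: dict = field(default_factory=dict)
    lineage_of: dict = field(default_factory=dict)
    occurrence_count: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "nonnative_pairs": sorted(map(list, self.nonnative_pairs)),
            "source_habitat": self.source_habitat,
            "lineage_of": self.lineage_of,
            "occurrence_count": self.occurrence_count,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            nonnative_pairs={tuple(p) for p in raw["nonnative_pairs"]},
            source_habitat=raw["source_habitat"],
            lineage_of=raw["lineage_of"],
            occurrence_count=raw["occurrence_count"],
        )


def _habitat_names(k: int) -> list[str]:
    return [f"H{i + 1}" for i in range(k)]


def simulate_metacommunity(
    config: SimulationConfig,
) -> tuple[CountTable, pd.DataFrame, GroundTruth]:
    """Generate a count table, sample metadata and ground truth.

    Returns ``(table, metadata, truth)``.  Column sums of the table equal
    ``config.depth`` exactly.  Colonists that happen to receive zero reads
    everywhere are still recorded in the truth; evaluation code restricts to
    detectable pairs.
    """
    rng = np.random.default_rng(config.seed)
    habitats = _habitat_names(config.n_habitats)

    natives = {
        hab: [f"{hab}.n{i:04d}" for i in range(config.natives_per_habitat)]
        for hab in habitats
    }
    generalists = [f"gen{i:04d}" for i in range(config.regional_generalists)]
    all_taxa = [t for hab in habitats for t in natives[hab]] + generalists

    weight = {
        t: float(w)
        for t, w in zip(
            all_taxa,
            rng.lognormal(mean=0.0, sigma=config.lognormal_sigma, size=len(all_taxa)),
        )
    }

    truth = GroundTruth()
    for hab in habitats:
        for t in natives[hab]:
            truth.source_habitat[t] = hab
            truth.lineage_of[t] = t
            truth.occurrence_count[t] = 1
    for t in generalists:
        truth.source_habitat[t] = None
        truth.lineage_of[t] = t
        truth.occurrence_count[t] = config.n_habitats

    # habitat-level colonization (source-sink): native of A -> colonist of B
    colonists: dict[str, list[str]] = {hab: [] for hab in habitats}
    for src in habitats:
        for t in natives[src]:
            for dst in habitats:
                if dst == src:
                    continue
                if rng.random() < config.dispersal_rate:
                    colonists[dst].append(t)
                    truth.nonnative_pairs.add((t, dst))
                    truth.occurrence_count[t] += 1

    sample_ids: list[str] = []
    habitat_of: dict[str, str] = {}
    columns: dict[str, np.ndarray] = {}
    index = pd.Index(all_taxa, name="taxon_id")
    pos = {t: i for i, t in enumerate(all_taxa)}

    for hab in habitats:
        members = (
            [(t, weight[t], config.native_occupancy) for t in natives[hab]]
            + [(t, weight[t], config.generalist_occupancy) for t in generalists]
            + [
                (t, weight[t] * config.colonist_abundance_factor,
                 config.colonist_occupancy)
                for t in colonists[hab]
            ]
        )
        for s in range(config.samples_per_habitat):
            sid = f"{hab}.s{s:03d}"
            for attempt in range(2):
                occ = rng.random(len(members))
                present = [
                    (t, w) for (t, w, po), u in zip(members, occ)
                    if u < po and w > 0
                ]
                if present:
                    break
            else:
                raise RuntimeError(f"sample {sid} drew no present taxa twice")
            w = np.array([x[1] for x in present])
            draw = rng.multinomial(config.depth, w / w.sum())
            col = np.zeros(len(all_taxa), dtype=np.int64)
            for (t, _), c in zip(present, draw):
                col[pos[t]] += c
            sample_ids.append(sid)
            habitat_of[sid] = hab
            columns[sid] = col

    counts = pd.DataFrame(columns, index=index)
    table = CountTable(counts, pd.Series(habitat_of, name="habitat"))
    metadata = pd.DataFrame(
        {"sample_id": sample_ids, "habitat": [habitat_of[s] for s in sample_ids]}
    )
    return table, metadata, truth


def simulate_sequences(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[dict[str, str], dendropy.Tree]:
    """Sequence variants per lineage plus a phylogeny over all variants.

    Each lineage gets a random ancestor sequence; variant 0 keeps the lineage
    id itself (the taxon's own ASV) and extra variants — 1 + Poisson(rate x
    occurrence) in total — carry point mutations at <= 2% divergence, so all
    variants of a lineage fall inside one 97%-identity OTU by construction.
    Branch lengths are substitutions per site (mutation count / length);
    lineage stems are long, keeping lineages mutually distant.
    """
    rng = np.random.default_rng(config.seed + 1)
    L = config.seq_length
    max_mut = max(1, int(0.02 * L))

    seqs: dict[str, str] = {}
    lineage_variants: dict[str, list[tuple[str, int]]] = {}
    for lineage in sorted(truth.occurrence_count):
        occ = truth.occurrence_count[lineage]
        ancestor = rng.choice(BASES, size=L)
        n_var = 1 + rng.poisson(config.variant_rate_per_occurrence * occ)
        variants = []
        for v in range(n_var):
            if v == 0:
                vid, k = lineage, 0
                seqs[vid] = "".join(ancestor)
            else:
                vid = f"{lineage}.v{v}"
                k = int(rng.integers(1, max_mut + 1))
                sites = rng.choice(L, size=k, replace=False)
                mutant = ancestor.copy()
                for site in sites:
                    choices = [b for b in "ACGT" if b != mutant[site]]
                    mutant[site] = choices[rng.integers(0, 3)]
                seqs[vid] = "".join(mutant)
            variants.append((vid, k))
        lineage_variants[lineage] = variants

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    for lineage, variants in lineage_variants.items():
        stem = dendropy.Node()
        stem.edge.length = 0.5  # deep separation between lineages
        tree.seed_node.add_child(stem)
        for vid, k in variants:
            leaf = dendropy.Node()
            leaf.taxon = taxa.new_taxon(label=vid)
            leaf.edge.length = k / L
            stem.add_child(leaf)
    return seqs, tree


def simulate_function_table(truth: GroundTruth, config: SimulationConfig):
    """Taxon-function repertoires plus named C/N/P/S function sets.

    Each taxon carries ~Poisson(``functions_per_taxon_mean``) background
    functions.  Of each cycle set, a fraction ``cycle_exclusive_fraction`` is
    carried exclusively by planted nonnative taxa (so targeted removal
    demonstrably erodes functional richness and redundancy); the remainder is
    spread over random taxa.

    Returns ``(FunctionTable, cycle_sets)`` where ``cycle_sets`` maps
    "C"/"N"/"P"/"S" to function-id lists.
    """
    from habniche.functional import FunctionTable

    rng = np.random.default_rng(config.seed + 2)
    universe = [f"F{i:05d}" for i in range(config.function_universe)]
    css = config.cycle_set_size
    cycle_sets = {
        name: universe[i * css:(i + 1) * css]
        for i, name in enumerate(("C", "N", "P", "S"))
    }
    cycle_funcs = [f for s in cycle_sets.values() for f in s]

    nonnative_taxa = sorted({t for t, _ in truth.nonnative_pairs})
    all_taxa = sorted(truth.lineage_of)

    exclusive: set[str] = set()
    for name in ("C", "N", "P", "S"):
        fs = cycle_sets[name]
        n_excl = int(round(config.cycle_exclusive_fraction * len(fs)))
        exclusive.update(fs[:n_excl])

    background_pool = [f for f in universe if f not in exclusive]

    carriers: dict[str, set[str]] = {t: set() for t in all_taxa}
    for t in all_taxa:
        k = min(rng.poisson(config.functions_per_taxon_mean), len(background_pool))
        if k:
            picks = rng.choice(len(background_pool), size=k, replace=False)
            carriers[t].update(background_pool[i] for i in picks)

    for f in cycle_funcs:
        if f in exclusive:
            if not nonnative_taxa:
                continue
            n_c = int(rng.integers(1, min(3, len(nonnative_taxa)) + 1))
            picks = rng.choice(len(nonnative_taxa), size=n_c, replace=False)
            for i in picks:
                carriers[nonnative_taxa[i]].add(f)
        else:
            n_c = int(rng.integers(2, 9))
            picks = rng.choice(len(all_taxa), size=min(n_c, len(all_taxa)),
                               replace=False)
            for i in picks:
                carriers[all_taxa[i]].add(f)

    return FunctionTable({t: fs for t, fs in carriers.items() if fs},
                         function_sets=cycle_sets)
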