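"""Community functional richness and phylogeny-weighted functional redundancy.

Functional richness of a community is the number of distinct functions (KO /
COG identifiers) carried by at least one member with abundance > 0.  The
functional redundancy of a single function f is a Rao-type quadratic entropy
restricted to its carriers,

    FR(f) = sum_{i != j, i,j carry f} p_i p_j d_ij,

with p the members' relative abundances over the WHOLE community and d the
patristic distance normalized by the tree's maximum pairwise distance.  FR is
0 when at most one carrier is present, and grows when a function is held by
several abundant, phylogenetically dispersed members — the configuration that
buffers the function against member loss.  Redundancy of a named function set
(C/N/P/S biogeochemical cycles) is the arithmetic mean of FR over the set,
counting carrier-less functions as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from habniche.classify import flagged_by_habitat
from habniche.io import CountTable
from habniche.phylo import patristic_distance_matrix
from habniche.removal import habitat_pool, random_removal, remove_taxa, targeted_removal
from habniche.stats import bh_adjust, paired_t

logger = logging.getLogger(__name__)


@dataclass
class FunctionTable:
    """Taxon -> set-of-functions incidence plus named function sets."""

    carriers: dict[str, set[str]]
    function_sets: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = self.functions()
        for name, fs in self.function_sets.items():
            unknown = set(fs) - known
            # sets may name functions no genome carries; that is allowed and
            # they contribute FR = 0, but warn so typos surface.
            if unknown:
                logger.warning(
                    "function set %s has %d functions with no carrier",
                    name, len(unknown),
                )

    def functions(self) -> set[str]:
        out: set[str] = set()
        for fs in self.carriers.values():
            out |= fs
        return out

    def carriers_of(self, function: str) -> set[str]:
        if not hasattr(self, "_carrier_index"):
            index: dict[str, set[str]] = {}
            for t, fs in self.carriers.items():
                for f in fs:
                    index.setdefault(f, set()).add(t)
            object.__setattr__(self, "_carrier_index", index)
        return self._carrier_index.get(function, set())

    def to_frame(self) -> pd.DataFrame:
        """Long-format (taxon_id, function_id) frame, sorted."""
        rows = [
            (t, f) for t in sorted(self.carriers) for f in sorted(self.carriers[t])
        ]
        return pd.DataFrame(rows, columns=["taxon_id", "function_id"])


def functional_richness(abundances: pd.Series, ftable: FunctionTable) -> int:
    """Distinct functions carried by members with abundance > 0.

    ``abundances`` is a per-taxon count or relative-abundance vector for one
    sample; members without annotations are skipped (logged once per call).
    """
    members = [t for t, a in abundances.items() if a > 0]
    missing = sum(1 for t in members if t not in ftable.carriers)
    if missing:
        logger.debug("%d community members lack annotations", missing)
    if not members:
        logger.warning("empty community: functional richness 0")
        return 0
    funcs: set[str] = set()
    for t in members:
        funcs |= ftable.carriers.get(t, set())
    return len(funcs)


def functional_redundancy(
    abundances: pd.Series,
    ftable: FunctionTable,
    dist_norm: pd.DataFrame,
    function: str,
) -> float:
    """Rao-type FR(f) = sum_{i!=j carriers} p_i p_j d_ij.

    ``abundances`` are counts or proportions for one sample (normalized here
    over the whole community); ``dist_norm`` is a patristic distance matrix
    already normalized by its maximum.  Carriers missing from the distance
    matrix raise an error naming the taxon.
    """
    total = float(abundances.sum())
    if total <= 0:
        return 0.0
    p = abundances / total
    carriers = sorted(ftable.carriers_of(function) & set(p.index[p > 0]))
    if len(carriers) <= 1:
        return 0.0
    for t in carriers:
        if t not in dist_norm.index:
            raise KeyError(f"carrier {t!r} missing from the distance matrix")
    pc = p[carriers].to_numpy()
    d = dist_norm.loc[carriers, carriers].to_numpy()
    return float(pc @ d @ pc)  # diagonal of d is zero, so i == j drops out


def cycle_redundancy(
    abundances: pd.Series,
    ftable: FunctionTable,
    dist_norm: pd.DataFrame,
    set_name: str,
) -> float:
    """Mean FR over a named function set; carrier-less functions count as 0."""
    if set_name not in ftable.function_sets:
        raise KeyError(f"unknown function set {set_name!r}")
    funcs = ftable.function_sets[set_name]
    if not funcs:
        raise ValueError(f"function set {set_name!r} is empty")
    return float(
        np.mean([functional_redundancy(abundances, ftable, dist_norm, f) for f in funcs])
    )


def normalized_patristic(tree: dendropy.Tree) -> pd.DataFrame:
    """Patristic distances divided by the tree's maximum pairwise distance."""
    d = patristic_distance_matrix(tree)
    dmax = float(d.to_numpy().max())
    if dmax <= 0:
        raise ValueError("tree has no positive pairwise distance")
    return d / dmax


def _per_sample_metrics(
    table: CountTable, ftable: FunctionTable, dist_norm: pd.DataFrame
) -> pd.DataFrame:
    rows = []
    for s in table.sample_ids:
        col = table.counts[s]
        row = {
            "sample_id": s,
            "habitat": table.habitat_of[s],
            "functional_richness": functional_richness(col, ftable),
        }
        for name in ftable.function_sets:
            row[f"FR_{name}"] = cycle_redundancy(col, ftable, dist_norm, name)
        rows.append(row)
    return pd.DataFrame(rows)


def removal_functional_comparison(
    table: CountTable,
    calls: pd.DataFrame,
    ftable: FunctionTable,
    tree: dendropy.Tree,
    replicates: int = 20,
    seed: int = 0,
    presence_threshold: int = 1,
) -> dict[str, pd.DataFrame]:
    """Observed vs targeted vs random functional richness and redundancy.

    Random removal matches the targeted set size per habitat and is averaged
    over replicates.  Returns ``{"per_sample": ..., "stats": ...}``; stats
    hold paired t-tests per habitat x metric x comparison, BH-adjusted.
    """
    dist_norm = normalized_patristic(tree)
    flagged = flagged_by_habitat(calls)
    targeted_table = targeted_removal(table, calls)

    obs = _per_sample_metrics(table, ftable, dist_norm).set_index("sample_id")
    targ = _per_sample_metrics(targeted_table, ftable, dist_norm).set_index("sample_id")

    metrics = ["functional_richness"] + [f"FR_{n}" for n in ftable.function_sets]
    rng = np.random.default_rng(seed)
    rand_acc = {m: pd.Series(0.0, index=obs.index) for m in metrics}
    for hab in table.habitats:
        samples = table.samples_in(hab)
        pool = habitat_pool(table, hab, presence_threshold)
        k = len(set(flagged.get(hab, set())) & set(pool))
        acc = {m: np.zeros(len(samples)) for m in metrics}
        for _ in range(replicates):
            if k:
                removed = set(
                    rng.choice(np.array(pool), size=k, replace=False)
                )
                rep_table = remove_taxa(table, removed, hab)
            else:
                rep_table = table
            rep = _per_sample_metrics(
                CountTable(rep_table.counts[samples], rep_table.habitat_of[samples]),
                ftable,
                dist_norm,
            ).set_index("sample_id")
            for m in metrics:
                acc[m] += rep[m].to_numpy()
        for m in metrics:
            rand_acc[m][samples] = acc[m] / replicates

    per_sample = obs.rename(columns={m: f"observed_{m}" for m in metrics})
    for m in metrics:
        per_sample[f"targeted_{m}"] = targ[m]
        per_sample[f"random_{m}"] = rand_acc[m]
    per_sample = per_sample.reset_index()

    stat_rows = []
    for hab in table.habitats:
        samples = table.samples_in(hab)
        for m in metrics:
            vals = {
                "observed": obs.loc[samples, m].to_numpy(),
                "targeted": targ.loc[samples, m].to_numpy(),
                "random": rand_acc[m][samples].to_numpy(),
            }
            for a, b in (("observed", "targeted"), ("observed", "random"),
                         ("targeted", "random")):
                t, p = paired_t(vals[a], vals[b])
                stat_rows.append(
                    {
                        "habitat": hab,
                        "metric": m,
                        "comparison": f"{a}_vs_{b}",
                        "mean_diff": float(np.mean(vals[a] - vals[b])),
                        "t": t,
                        "p": p,
                    }
                )
    stats = pd.DataFrame(stat_rows)
    stats["p_adj"] = bh_adjust(stats["p"])
    return {"per_sample": per_sample, "stats": stats}
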