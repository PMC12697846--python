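"""Per-habitat niche metrics: Levins breadth, occupancy, abundance, Shannon.

Levins' niche breadth for taxon j over the N samples of one habitat is

    B_j = 1 / sum_i P_ij^2,      P_ij = n_ij / sum_i n_ij,

the inverse Simpson concentration of the taxon's read distribution across
samples.  B_j ranges from 1 (all reads in one sample; specialist) to N
(perfectly even; generalist).  Breadths are normalized by the maximum breadth
within each habitat so habitats with different sample numbers are comparable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from habniche.io import CountTable

PROFILE_COLUMNS = [
    "taxon_id",
    "habitat",
    "mean_rel_abundance",
    "occupancy",
    "breadth",
    "breadth_norm",
]


def taxon_sample_proportions(table: CountTable, habitat: str) -> pd.DataFrame:
    """P_ij per (sample i, taxon j) within one habitat.

    Each detected taxon's counts are normalized across the habitat's samples
    so that its column sums to 1.  Taxa with zero reads in the habitat are
    excluded (breadth is undefined for them, not zero).

    Returns a samples x taxa DataFrame.
    """
    samples = table.samples_in(habitat)
    if not samples:
        raise ValueError(f"habitat {habitat!r} has no samples")
    sub = table.counts[samples]
    totals = sub.sum(axis=1)
    detected = totals > 0
    sub = sub.loc[detected]
    return (sub.div(totals[detected], axis=0)).T


def levins_breadth(proportions) -> float:
    """B = 1 / sum(P^2) for one taxon's per-sample proportions."""
    p = np.asarray(proportions, dtype=float)
    ss = float(np.sum(p**2))
    if ss == 0:
        raise ValueError("breadth undefined for an all-zero distribution")
    return 1.0 / ss


def normalize_breadth(breadths: pd.Series) -> pd.Series:
    """Divide each breadth by the maximum within the habitat (max maps to 1)."""
    if len(breadths) == 0:
        raise ValueError("no present taxa to normalize over")
    return breadths / breadths.max()


def shannon_diversity(counts, base: float | None = None) -> float:
    """Shannon index H' = -sum p ln p over taxa with p > 0.

    ``base=None`` uses the natural log; pass e.g. ``base=10`` otherwise.
    """
    c = np.asarray(counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("Shannon diversity undefined for an empty sample")
    p = c[c > 0] / total
    h = -float(np.sum(p * np.log(p)))
    if base is not None:
        h /= np.log(base)
    return h


def habitat_occurrence_counts(
    table: CountTable, presence_threshold: int = 1
) -> pd.Series:
    """Number of habitats (out of all habitats in the table) where each taxon
    reaches ``presence_threshold`` reads in at least one sample."""
    hits = pd.Series(0, index=table.counts.index, dtype=int)
    for hab in table.habitats:
        sub = table.counts[table.samples_in(hab)]
        hits += (sub >= presence_threshold).any(axis=1).astype(int)
    return hits


def habitat_profiles(
    table: CountTable, presence_threshold: int = 1
) -> pd.DataFrame:
    """Tidy per-(taxon, habitat) statistics for all *present* pairs.

    Columns: taxon_id, habitat, mean_rel_abundance (mean over the habitat's
    samples of within-sample relative abundance), occupancy (fraction of the
    habitat's samples with count >= presence_threshold), breadth (Levins B),
    breadth_norm (B divided by the habitat's maximum B).

    A pair is present when the taxon reaches the presence threshold in at
    least one sample of the habitat; absent pairs get no row.
    """
    rel = table.relative_abundance()
    frames = []
    for hab in table.habitats:
        samples = table.samples_in(hab)
        sub = table.counts[samples]
        present = (sub >= presence_threshold).any(axis=1)
        if not present.any():
            continue
        sub = sub.loc[present]
        totals = sub.sum(axis=1)
        p = sub.div(totals, axis=0)
        breadth = 1.0 / (p**2).sum(axis=1)
        frames.append(
            pd.DataFrame(
                {
                    "taxon_id": sub.index,
                    "habitat": hab,
                    "mean_rel_abundance": rel.loc[present, samples].mean(axis=1).values,
                    "occupancy": (sub >= presence_threshold).mean(axis=1).values,
                    "breadth": breadth.values,
                    "breadth_norm": (breadth / breadth.max()).values,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=PROFILE_COLUMNS)
    return pd.concat(frames, ignore_index=True)
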