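"""Dual-criterion classification of putative nonnative (dispersal-derived)
taxa, and summaries of their contribution to abundance and richness.

A taxon j is called putative nonnative in habitat H only when all of:

1. its mean relative abundance in H is lower than in some other habitat where
   it is present (H is not its best habitat by abundance);
2. its normalized niche breadth in H is lower than in some other habitat
   where it is present;
3. its normalized niche breadth in H is lower than the q-quantile (default:
   median) of normalized breadths of the taxa present in H.

Ties fail the strict "lower than" comparisons; taxa present in a single
habitat are exempt (criteria 1-2 have no reference).  Under source-sink
dynamics such taxa are read as colonists sustained by immigration from a
source habitat rather than self-maintaining residents.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from habniche.io import CountTable

CALL_COLUMNS = [
    "taxon_id",
    "habitat",
    "crit_abundance",
    "crit_breadth_cross",
    "crit_breadth_within",
    "nonnative",
]


def classify_nonnative(profiles: pd.DataFrame, quantile: float = 0.5) -> pd.DataFrame:
    """Apply the three criteria to a tidy profile table.

    Parameters
    ----------
    profiles
        Output of :func:`habniche.niche.habitat_profiles` — one row per
        present (taxon, habitat) pair.
    quantile
        Within-habitat quantile of normalized breadth used as the criterion-3
        reference (0 < q < 1).

    Returns a DataFrame with one row per present pair: the three criterion
    booleans and their conjunction ``nonnative``.
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0,1)")
    df = profiles.sort_values(["taxon_id", "habitat"]).reset_index(drop=True)

    grp = df.groupby("taxon_id")
    n_habs = grp["habitat"].transform("size")
    max_abund = grp["mean_rel_abundance"].transform("max")
    max_bnorm = grp["breadth_norm"].transform("max")
    # strict "<" against the max over *other* habitats reduces to "< group max":
    # if the value equals the group max the other-habitat max cannot exceed it.
    crit_abundance = (df["mean_rel_abundance"] < max_abund) & (n_habs >= 2)
    crit_breadth_cross = (df["breadth_norm"] < max_bnorm) & (n_habs >= 2)

    thresh = df.groupby("habitat")["breadth_norm"].transform(
        lambda b: np.quantile(b, quantile)
    )
    crit_breadth_within = df["breadth_norm"] < thresh

    out = pd.DataFrame(
        {
            "taxon_id": df["taxon_id"],
            "habitat": df["habitat"],
            "crit_abundance": crit_abundance,
            "crit_breadth_cross": crit_breadth_cross,
            "crit_breadth_within": crit_breadth_within,
        }
    )
    out["nonnative"] = (
        out["crit_abundance"] & out["crit_breadth_cross"] & out["crit_breadth_within"]
    )
    return out


def flagged_by_habitat(calls: pd.DataFrame) -> dict[str, set[str]]:
    """Map habitat -> set of taxa flagged nonnative there."""
    out: dict[str, set[str]] = {}
    if calls.empty:
        return out
    for hab, sub in calls[calls["nonnative"]].groupby("habitat"):
        out[str(hab)] = set(sub["taxon_id"])
    return out


def summarize_nonnative(
    table: CountTable, calls: pd.DataFrame, presence_threshold: int = 1
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-habitat and per-sample summaries of the flagged taxa.

    Returns ``(per_habitat, per_sample)``:

    * per habitat: ``flagged_fraction`` — flagged taxa / taxa present in the
      habitat's metacommunity;
    * per sample: ``flagged_abundance`` — summed relative abundance of
      flagged taxa; ``flagged_richness_fraction`` — flagged detected taxa /
      detected taxa.
    """
    unknown = set(calls["taxon_id"]) - set(table.counts.index)
    if unknown:
        raise ValueError(f"calls refer to taxa absent from the table: {sorted(unknown)[:5]}")
    flagged = flagged_by_habitat(calls)
    rel = table.relative_abundance()

    hab_rows = []
    sample_rows = []
    for hab in table.habitats:
        samples = table.samples_in(hab)
        sub = table.counts[samples]
        present = (sub >= presence_threshold).any(axis=1)
        pool = set(sub.index[present])
        f = flagged.get(hab, set()) & pool
        hab_rows.append(
            {
                "habitat": hab,
                "n_taxa": len(pool),
                "n_flagged": len(f),
                "flagged_fraction": len(f) / len(pool) if pool else 0.0,
            }
        )
        for s in samples:
            detected = set(sub.index[sub[s] >= presence_threshold])
            fd = f & detected
            sample_rows.append(
                {
                    "sample_id": s,
                    "habitat": hab,
                    "flagged_abundance": float(rel.loc[sorted(fd), s].sum()) if fd else 0.0,
                    "flagged_richness_fraction": (
                        len(fd) / len(detected) if detected else 0.0
                    ),
                }
            )
    return pd.DataFrame(hab_rows), pd.DataFrame(sample_rows)


def evaluate_against_truth(calls: pd.DataFrame, truth) -> dict[str, float | int | None]:
    """Precision/recall/F1 of the calls against planted ground truth.

    Both the calls and the truth are restricted to the evaluable universe:
    present (taxon, habitat) pairs whose taxon is present in at least two
    habitats (single-habitat taxa can never be classified nonnative, and
    planted colonists that received no reads are undetectable by design).
    """
    n_habs = calls.groupby("taxon_id")["habitat"].transform("size")
    eligible = calls[n_habs >= 2]
    universe = set(zip(eligible["taxon_id"], eligible["habitat"]))
    predicted = set(
        zip(
            eligible.loc[eligible["nonnative"], "taxon_id"],
            eligible.loc[eligible["nonnative"], "habitat"],
        )
    )
    actual = set(map(tuple, truth.nonnative_pairs)) & universe

    tp = len(predicted & actual)
    fp = len(predicted - actual)
    fn = len(actual - predicted)
    if not predicted and not actual:
        return {"precision": None, "recall": None, "f1": None,
                "tp": 0, "fp": 0, "fn": 0, "n_pairs": len(universe)}
    precision = tp / (tp + fp) if (tp + fp) else 0.0
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return {"precision": precision, "recall": recall, "f1": f1,
            "tp": tp, "fp": fp, "fn": fn, "n_pairs": len(universe)}
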