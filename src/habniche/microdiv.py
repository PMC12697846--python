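"""OTU clustering of ASVs and microdiversity statistics.

ASVs (exact sequence variants) are clustered into OTUs by an abundance-sorted
greedy centroid pass at a 97% identity threshold: sequences are visited in
decreasing total-abundance order (ties broken by id) and join the first
existing centroid they match at or above the threshold, else found a new one.
Microdiversity of a lineage is then measured two ways: the number of ASVs in
its OTU, and nearest-taxon closeness, the minus-log of the distance from an
ASV to its closest relative in the dataset.  Both are compared across
habitat-occurrence levels (how many habitats a lineage occupies) with
pairwise t-tests, a compact letter display, and a Spearman rank correlation.
"""

from __future__ import annotations

import itertools

import edlib
import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats as sps

from habniche.stats import bh_adjust, compact_letter_display


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1.0
    a.mismatch_score = 0.0
    a.open_gap_score = -1.0   # linear gap penalty
    a.extend_gap_score = -1.0
    return a


_ALIGNER = _aligner()


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment columns.

    Scoring is match 1, mismatch 0, linear gap penalty -1; identity is
    symmetric and 1.0 for identical sequences.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    if a == b:
        return 1.0
    aln = _ALIGNER.align(a, b)[0]
    counts = aln.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    return counts.identities / columns


def _hamming_identity(a: str, b: str) -> float:
    same = sum(x == y for x, y in zip(a, b))
    return same / len(a)


def greedy_otu_cluster(
    seqs: dict[str, str],
    abundances: dict[str, float],
    threshold: float = 0.97,
) -> pd.DataFrame:
    """Abundance-sorted greedy centroid clustering.

    Returns a DataFrame with columns ``asv``, ``otu`` (centroid id),
    ``is_centroid`` and ``identity`` (to own centroid).  Deterministic:
    ordering is (-abundance, id), never file order.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0,1]")
    order = sorted(seqs, key=lambda i: (-abundances.get(i, 0.0), i))
    centroids: list[str] = []
    rows = []
    equal_length = len({len(s) for s in seqs.values()}) <= 1
    for sid in order:
        seq = seqs[sid]
        assigned = None
        for cid in centroids:
            cseq = seqs[cid]
            if equal_length:
                # ungapped identity is a lower bound under gap penalties;
                # accepting on it never admits a below-threshold pair
                h = _hamming_identity(seq, cseq)
                if h >= threshold:
                    assigned = (cid, pairwise_identity(seq, cseq))
                    break
            # identity >= t forces <= (1-t)(|a|+|b|) non-match columns, hence
            # an edit distance within that bound; a banded check above it is
            # a provably safe rejection and skips the full alignment
            k_max = int((1.0 - threshold) * (len(seq) + len(cseq)))
            if edlib.align(seq, cseq, mode="NW", task="distance",
                           k=k_max)["editDistance"] == -1:
                continue
            ident = pairwise_identity(seq, cseq)
            if ident >= threshold:
                assigned = (cid, ident)
                break
        if assigned is None:
            centroids.append(sid)
            rows.append({"asv": sid, "otu": sid, "is_centroid": True,
                         "identity": 1.0})
        else:
            rows.append({"asv": sid, "otu": assigned[0], "is_centroid": False,
                         "identity": assigned[1]})
    return pd.DataFrame(rows)


def nearest_taxon_closeness(
    dist: pd.DataFrame,
    log_base: float | None = None,
    epsilon: float | None = None,
) -> pd.DataFrame:
    """Nearest-taxon distance and its minus-log ("closeness") per taxon.

    ``dist`` is a symmetric distance matrix (patristic from a tree, or
    1 - identity from sequences).  Zero minimum distances are floored at
    ``epsilon`` (default: half the smallest positive distance in the matrix)
    before the log.  ``log_base=None`` means natural log.
    """
    if dist.shape[0] < 2:
        raise ValueError("nearest-taxon distance needs at least two taxa")
    mat = dist.to_numpy(dtype=float).copy()
    np.fill_diagonal(mat, np.inf)
    dmin = mat.min(axis=1)
    positive = mat[np.isfinite(mat) & (mat > 0)]
    if epsilon is None:
        if positive.size == 0:
            raise ValueError("all pairwise distances are zero; supply epsilon")
        epsilon = float(positive.min()) / 2.0
    floored = np.maximum(dmin, epsilon)
    closeness = -np.log(floored)
    if log_base is not None:
        closeness = closeness / np.log(log_base)
    return pd.DataFrame(
        {"nearest_distance": dmin, "closeness": closeness}, index=dist.index
    )


def microdiversity_by_occurrence(
    values: pd.Series,
    occurrence: pd.Series,
    alpha: float = 0.05,
) -> dict:
    """Compare a microdiversity metric across habitat-occurrence levels.

    ``values`` holds the metric (intra-OTU ASV count per OTU, or closeness
    per ASV); ``occurrence`` the matching occurrence level (1..n_habitats).
    Levels with fewer than two observations are kept in the summary but
    excluded from tests.

    Returns ``summary`` (per-level n/mean/median), ``pairwise`` (two-sample
    t-tests, BH-adjusted), ``letters`` (compact letter display at ``alpha``),
    and ``spearman`` (rho, p over all observations).
    """
    df = pd.DataFrame({"value": values, "occurrence": occurrence}).dropna()
    summary = (
        df.groupby("occurrence")["value"]
        .agg(n="size", mean="mean", median="median", sd="std")
        .reset_index()
    )
    testable = [
        int(lv) for lv, n in df["occurrence"].value_counts().items() if n >= 2
    ]
    testable.sort()
    rows = []
    for a, b in itertools.combinations(testable, 2):
        va = df.loc[df["occurrence"] == a, "value"]
        vb = df.loc[df["occurrence"] == b, "value"]
        if va.var() == 0 and vb.var() == 0:
            t, p = (0.0, 1.0) if va.mean() == vb.mean() else (np.inf, 0.0)
        else:
            t, p = sps.ttest_ind(va, vb, equal_var=False)
        rows.append({"level_a": a, "level_b": b, "t": float(t), "p": float(p)})
    pairwise = pd.DataFrame(rows, columns=["level_a", "level_b", "t", "p"])
    pairwise["p_adj"] = bh_adjust(pairwise["p"]) if len(pairwise) else []
    sig = {
        (int(r.level_a), int(r.level_b))
        for r in pairwise.itertuples()
        if r.p_adj < alpha
    }
    letters = compact_letter_display(testable, sig) if testable else {}
    if df["occurrence"].nunique() > 1 and df["value"].nunique() > 1:
        rho, rho_p = sps.spearmanr(df["occurrence"], df["value"])
    else:
        rho, rho_p = float("nan"), float("nan")
    return {
        "summary": summary,
        "pairwise": pairwise,
        "letters": letters,
        "spearman": {"rho": float(rho), "p": float(rho_p)},
    }


def intra_otu_counts(assignment: pd.DataFrame) -> pd.Series:
    """Member count per OTU from a greedy_otu_cluster assignment."""
    return assignment.groupby("otu")["asv"].size()


def otu_occurrence(
    assignment: pd.DataFrame, asv_occurrence: pd.Series
) -> pd.Series:
    """Occurrence level per OTU: the maximum over its members' levels."""
    df = assignment.join(asv_occurrence.rename("occ"), on="asv")
    return df.groupby("otu")["occ"].max()
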